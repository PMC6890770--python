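"""Simulate a synthetic disease world and inspect its ground truth.

Generates 20 diseases with known heritability, latent co-occurrence vectors
and archetype prevalence shapes, then simulates a diagnosis-event stream and
enrollment table for 1,000 patients.
"""

from phenoherit import synthetic

world = synthetic.generate_world(n_diseases=20, d_lat=6, seed=1)
events, enrollment = synthetic.simulate_events(world, n_patients=1000, seed=2)
estimates = synthetic.synthesize_estimates(world, n_per_disease=3, seed=3)

print("disease truth table (head):")
print(world.diseases.head().to_string(index=False))
print(f"\n{len(events)} diagnosis events for {events['patient_id'].nunique()} patients")
print(f"{len(estimates)} synthetic published-estimate records")
print("\npair truth (head):")
print(world.pair_truth.head().to_string(index=False))

# The truth table is what downstream stages try to recover: h2_true encodes
# a negative dependence on onset age; rg_true/re_true are cosine
# similarities of latent vectors and archetype curves respectively.
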