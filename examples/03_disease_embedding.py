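"""Train a skip-gram disease embedding from diagnosis sequences.

Patient histories (codes ordered by age) act as sentences; diseases that
co-occur in similar contexts end up with nearby 20-dimensional vectors.
"""

from phenoherit import synthetic
from phenoherit.embedding import build_corpus, train_embedding

world = synthetic.generate_world(n_diseases=12, d_lat=2, seed=4, temperature=0.5)
# two orthogonal latent blocks: diseases 0-5 co-occur, diseases 6-11 co-occur
world.latent[:] = 0.0
world.latent[:6, 0] = 3.0
world.latent[6:, 1] = 3.0
events, _ = synthetic.simulate_events(world, n_patients=3000, mean_history_len=3.0, seed=5)

corpus = build_corpus(events)
embedding = train_embedding(corpus, dim=20, window=8, epochs=3, seed=6)

codes = world.codes
within = embedding.cosine(codes[0], codes[1])
between = embedding.cosine(codes[0], codes[7])
print(f"corpus: {len(corpus)} patient sentences, vocabulary {len(corpus.vocabulary)}")
print("per-epoch average cost:", [round(c, 3) for c in embedding.training_meta["epoch_costs"]])
print(f"cosine within co-occurrence block:  {within:.3f}")
print(f"cosine between blocks:              {between:.3f}")

# Diseases sharing a latent co-occurrence block appear in the same patient
# contexts, so their vectors align; the within-block cosine should clearly
# exceed the between-block cosine.
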