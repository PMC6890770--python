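"""Generator sanity: archetype shapes, world truth tables, event streams,
and synthetic estimate tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phenoherit import synthetic
from phenoherit.archetypes import ARCHETYPE_NAMES, N_AGES, default_archetypes
from phenoherit.shapes import jsd


class TestArchetypes:
    @pytest.mark.parametrize("name", ARCHETYPE_NAMES)
    def test_normalized_nonnegative(self, name):
        v = default_archetypes()[name].evaluate()
        assert v.shape == (N_AGES,)
        assert np.all(v >= 0)
        assert np.isclose(v.sum(), 1.0)

    @pytest.mark.parametrize("name", [n for n in ARCHETYPE_NAMES if n != "multimodal"])
    def test_unimodal(self, name):
        v = default_archetypes()[name].evaluate()
        peak = np.argmax(v)
        assert np.all(np.diff(v[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(v[peak:]) <= 1e-12)

    def test_multimodal_has_two_local_maxima(self):
        v = default_archetypes()["multimodal"].evaluate()
        interior = [
            a for a in range(1, N_AGES - 1) if v[a] > v[a - 1] and v[a] >= v[a + 1]
        ]
        assert len(interior) >= 2


class TestGenerateWorld:
    def test_counts_one_disease_per_archetype(self):
        w = synthetic.generate_world(5, 4, seed=1)
        assert sorted(w.diseases["archetype"]) == sorted(ARCHETYPE_NAMES)
        assert len(w.diseases) == 5
        assert len(w.pair_truth) == 10

    def test_rejects_too_few_diseases(self):
        with pytest.raises(ValueError):
            synthetic.generate_world(1, 4, seed=0)

    def test_identical_latents_give_rg_one(self):
        w = synthetic.generate_world(4, 3, seed=2)
        w.latent[1] = w.latent[0]
        w2 = synthetic.SyntheticWorld(
            diseases=w.diseases,
            latent=w.latent,
            archetypes=w.archetypes,
            pair_truth=w.pair_truth,
            seed=w.seed,
        )
        # recompute the pair truth from the modified latents
        from phenoherit.synthetic import _cosine

        assert _cosine(w2.latent[0], w2.latent[1]) == pytest.approx(1.0)

    def test_truth_bounds(self):
        w = synthetic.generate_world(40, 6, seed=3)
        assert w.diseases["h2_true"].between(0, 1).all()
        assert w.pair_truth["rg_true"].between(-1, 1).all()
        assert w.pair_truth["re_true"].between(-1, 1).all()

    def test_onset_h2_anticorrelation(self):
        w = synthetic.generate_world(50, 8, seed=7)
        rho = spearmanr(w.diseases["onset_age_true"], w.diseases["h2_true"]).statistic
        assert rho < 0

    def test_deterministic_truth(self):
        a = synthetic.generate_world(12, 4, seed=5)
        b = synthetic.generate_world(12, 4, seed=5)
        pd.testing.assert_frame_equal(a.diseases, b.diseases)
        pd.testing.assert_frame_equal(a.pair_truth, b.pair_truth)


class TestSimulateEvents:
    def test_rejects_zero_patients(self, small_world):
        with pytest.raises(ValueError):
            synthetic.simulate_events(small_world, 0, seed=1)

    def test_deterministic_streams(self, small_world):
        e1, n1 = synthetic.simulate_events(small_world, 200, seed=4)
        e2, n2 = synthetic.simulate_events(small_world, 200, seed=4)
        assert e1.to_csv(index=False) == e2.to_csv(index=False)
        assert n1.to_csv(index=False) == n2.to_csv(index=False)

    def test_events_within_world(self, small_world, small_events):
        events, enrollment = small_events
        assert events["age"].between(0, 65).all()
        assert set(events["code"]) <= set(small_world.codes)
        # every event stratum is enrolled
        strata = set(map(tuple, enrollment[["sex", "age", "country"]].to_numpy()))
        for _, r in events.iterrows():
            assert (r["sex"], r["age"], r["country"]) in strata

    def test_single_uniform_disease_age_histogram(self):
        # one disease whose curve is uniform -> empirical histogram converges
        from phenoherit.archetypes import CurveArchetype

        w = synthetic.generate_world(2, 2, seed=9, sex_tilt=0.0, sex_bias_range=0.0)
        uniform = np.full(N_AGES, 1.0 / N_AGES)
        # geometric decay with rate 0 is exactly uniform
        w.archetypes["early_L"] = CurveArchetype("early_L", params={"rate": 0.0})
        events, _ = synthetic.simulate_events(w, 50_000, mean_history_len=1.0, seed=10)
        ev = events[events["code"] == "D0000"]
        hist = np.bincount(ev["age"], minlength=N_AGES).astype(float)
        hist /= hist.sum()
        assert jsd(hist, uniform) < 0.01

    def test_cooccurrence_tracks_latent_similarity(self):
        w = synthetic.generate_world(4, 2, seed=1, temperature=0.5)
        w.latent[:] = 0.0
        w.latent[0] = [3.0, 0.0]
        w.latent[1] = [3.0, 0.0]   # identical to disease 0
        w.latent[2] = [0.0, 3.0]   # orthogonal
        w.latent[3] = [0.0, -3.0]
        events, _ = synthetic.simulate_events(w, 4000, mean_history_len=2.0, seed=2)
        per_patient = events.groupby("patient_id")["code"].agg(set)
        both_01 = sum(1 for s in per_patient if {"D0000", "D0001"} <= s)
        both_02 = sum(1 for s in per_patient if {"D0000", "D0002"} <= s)
        assert both_01 > both_02


class TestSynthesizeEstimates:
    def test_vanishing_noise_recovers_truth(self, small_world):
        est = synthetic.synthesize_estimates(
            small_world, 2, se_range=(1e-9, 1e-9), seed=1
        )
        h2 = est[est["estimate_type"] == "h2"].set_index("disease_a")
        truth = small_world.diseases.set_index("code")["h2_true"]
        for code, sub in h2.groupby(level=0):
            assert np.allclose(sub["value"], truth[code], atol=1e-6)

    def test_record_counts(self):
        w = synthetic.generate_world(10, 4, seed=3)
        est = synthetic.synthesize_estimates(w, 3, seed=4, include_pairs=False)
        assert len(est[est["estimate_type"] == "h2"]) == 30

    def test_invalid_se_range(self, small_world):
        with pytest.raises(ValueError):
            synthetic.synthesize_estimates(small_world, 1, se_range=(0.0, 0.5), seed=0)

    def test_pooled_mean_concentrates_on_truth(self):
        # inverse-variance pooling of 100 records at SE=0.1 has SE 0.01
        from phenoherit.gbm import pool_estimates

        w = synthetic.generate_world(20, 4, seed=6)
        est = synthetic.synthesize_estimates(
            w, 100, se_range=(0.1, 0.1), seed=7, include_pairs=False
        )
        truth = w.diseases.set_index("code")["h2_true"]
        hits = 0
        for code, sub in est.groupby("disease_a"):
            pooled = pool_estimates(sub["value"].to_numpy(), sub["se"].to_numpy())
            hits += abs(pooled.value - truth[code]) <= 0.03
        assert hits >= 0.95 * len(truth)


def test_analysis_b_converges_to_archetype_curve():
    """Prevalence consistency: curve from a large stream approaches the
    generating archetype, with JSD decreasing in expectation with n."""
    from phenoherit.curves import combined_sex_curve_b

    w = synthetic.generate_world(2, 2, seed=21, sex_tilt=0.0)
    target = w.archetypes[w.diseases.loc[0, "archetype"]].evaluate()
    ds = []
    for n in (1000, 10_000, 50_000):
        events, _ = synthetic.simulate_events(w, n, mean_history_len=1.5, seed=22)
        curve = combined_sex_curve_b(events, "D0000", "US")
        ds.append(jsd(curve.values, target))
    assert ds[-1] < ds[0]
    assert ds[-1] < 0.02
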