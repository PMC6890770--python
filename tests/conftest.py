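import numpy as np
import pytest

from phenoherit import synthetic
from phenoherit.archetypes import ARCHETYPE_NAMES, N_AGES, default_archetypes


@pytest.fixture(scope="session")
def small_world():
    return synthetic.generate_world(10, 4, seed=11)


@pytest.fixture(scope="session")
def small_events(small_world):
    events, enrollment = synthetic.simulate_events(small_world, 800, seed=12)
    return events, enrollment


def archetype_curve_set(n_per: int, noise_sd: float, seed: int):
    """Noisy curves drawn around each archetype (log-normal bin noise)."""
    rng = np.random.default_rng(seed)
    arch = default_archetypes()
    curves, labels = [], []
    for a, name in enumerate(ARCHETYPE_NAMES):
        base = arch[name].evaluate()
        for _ in range(n_per):
            v = base * np.exp(rng.normal(0.0, noise_sd, size=N_AGES))
            curves.append(v / v.sum())
            labels.append(a)
    return curves, np.array(labels)


def random_distribution(rng, n, sparse=False):
    v = rng.random(n)
    if sparse:
        v[rng.random(n) < 0.5] = 0.0
        if v.sum() == 0:
            v[rng.integers(n)] = 1.0
    return v / v.sum()
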