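"""Parametric disease-prevalence curve archetypes.

Population-scale diagnosis data show a small number of recurring prevalence
curve shapes over patient age: L-shaped early-onset conditions, slowly rising
early-onset curves, multimodal curves, steeply rising late-onset curves, and
skewed bell shapes peaking in childhood.  These five archetypes are the
generative shapes used by the synthetic-data module; each evaluates to a
probability distribution over integer ages 0..65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Inclusive age range covered by all curves (66 integer bins).
AGE_MIN = 0
AGE_MAX = 65
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

ARCHETYPE_NAMES = (
    "early_L",
    "early_slow_rise",
    "multimodal",
    "late_steep_rise",
    "skewed_bell",
)


def _raw_profile(name: str, params: dict, ages: np.ndarray) -> np.ndarray:
    if name == "early_L":
        # geometric decay from birth; heavier right tail than the bell shape
        rate = params.get("rate", 0.05)
        return (1.0 - rate) ** ages
    if name == "early_slow_rise":
        mid = params.get("midpoint", 25.0)
        slope = params.get("slope", 10.0)
        return 1.0 / (1.0 + np.exp(-(ages - mid) / slope))
    if name == "late_steep_rise":
        mid = params.get("midpoint", 50.0)
        slope = params.get("slope", 1.2)
        return 1.0 / (1.0 + np.exp(-(ages - mid) / slope))
    if name == "multimodal":
        m1 = params.get("mode1", 5.0)
        m2 = params.get("mode2", 45.0)
        s1 = params.get("sd1", 3.0)
        s2 = params.get("sd2", 5.0)
        w = params.get("weight1", 0.5)
        return w * stats.norm.pdf(ages, m1, s1) + (1.0 - w) * stats.norm.pdf(ages, m2, s2)
    if name == "skewed_bell":
        # gamma density with mode (shape-1)*scale near age 10 and a light tail
        shape = params.get("shape", 8.0)
        scale = params.get("scale", 1.4)
        return stats.gamma.pdf(ages, shape, scale=scale)
    raise ValueError(f"unknown archetype name: {name!r}")


@dataclass(frozen=True)
class CurveArchetype:
    """A named parametric age profile, normalized to a probability vector.

    ``sex_modifier`` maps a sex label to a multiplicative adjustment of the
    age profile (a 66-vector or scalar); the modified profile is re-normalized,
    so only the relative age pattern of the modifier matters.
    """

    name: str
    params: dict = field(default_factory=dict)
    sex_modifier: dict = field(default_factory=dict)

    def evaluate(self, sex: str | None = None) -> np.ndarray:
        """Probability vector over ages 0..65 (optionally sex-adjusted)."""
        raw = _raw_profile(self.name, self.params, AGES).astype(float)
        if sex is not None and sex in self.sex_modifier:
            raw = raw * np.asarray(self.sex_modifier[sex], dtype=float)
        if np.any(raw < 0):
            raise ValueError("archetype profile produced negative values")
        total = raw.sum()
        if total <= 0:
            raise ValueError("archetype profile sums to zero")
        return raw / total


def default_archetypes() -> dict[str, CurveArchetype]:
    """The five default archetypes keyed by name."""
    return {name: CurveArchetype(name) for name in ARCHETYPE_NAMES}


def default_sex_modifier(tilt: float) -> dict[str, np.ndarray]:
    """A mild exponential age tilt applied with opposite sign per sex.

    Positive ``tilt`` shifts male diagnoses toward older ages and female
    diagnoses toward younger ages.
    """
    centered = (AGES - AGES.mean()) / N_AGES
    return {"M": np.exp(tilt * centered), "F": np.exp(-tilt * centered)}
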