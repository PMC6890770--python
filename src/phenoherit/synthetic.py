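"""Synthetic diagnosis-event worlds with known ground truth.

Real population registries (claims databases, national patient registries)
are licensed and cannot ship with an analysis package.  This module generates
desk-scale data with the same statistical structure the pipeline assumes:

* age/sex-stratified diagnosis incidence following five parametric curve
  archetypes,
* nonrandom within-patient disease co-occurrence driven by latent disease
  vectors (patients sample diseases with probability proportional to a
  softmax of the affinity between a per-patient latent vector and each
  disease's latent vector),
* noisy published-estimate tables whose true values are deterministic
  functions of disease descriptors.

The built-in truth table encodes a negative onset-age/heritability
dependence, ``h2 = clip(a - b * onset_age/65 + noise, 0, 1)``, so the
downstream association analyses have a known sign to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archetypes import (
    AGES,
    ARCHETYPE_NAMES,
    N_AGES,
    CurveArchetype,
    default_archetypes,
    default_sex_modifier,
)
from .vocab import CATEGORIES, DATA_TYPES, MODELS, SEXES

EVENT_COLUMNS = ["patient_id", "sex", "age", "code", "country"]
ENROLLMENT_COLUMNS = ["sex", "age", "country", "count"]
ESTIMATE_COLUMNS = [
    "estimate_type",
    "disease_a",
    "disease_b",
    "value",
    "se",
    "data_type",
    "model",
    "sex",
    "country",
    "source_id",
]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _onset_from_curve(values: np.ndarray) -> int:
    # smallest age whose cumulative mass reaches 5%
    c = np.cumsum(values)
    return int(np.argmax(c >= 0.05 - 1e-12))


@dataclass
class SyntheticWorld:
    """A generated disease universe with its ground-truth parameter table.

    ``diseases`` holds one row per disease code: archetype, biological-system
    category, true sex bias, true onset age and true heritability.
    ``pair_truth`` holds one row per unordered pair with true genetic
    correlation (cosine similarity of latent vectors) and true environmental
    correlation (cosine similarity of archetype curves rescaled to [-1, 1]).
    """

    diseases: pd.DataFrame
    latent: np.ndarray
    archetypes: dict[str, CurveArchetype]
    pair_truth: pd.DataFrame
    seed: int
    temperature: float = 1.0
    countries: tuple = ("US",)
    sex_modifier: dict = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        return list(self.diseases["code"])

    def curve_of(self, code: str, sex: str | None = None) -> np.ndarray:
        arch = self.archetypes[self.diseases.set_index("code").loc[code, "archetype"]]
        return arch.evaluate(sex=sex)


def generate_world(
    n_diseases: int,
    d_lat: int,
    seed: int,
    *,
    h2_intercept: float = 0.6,
    h2_slope: float = 0.4,
    h2_noise_sd: float = 0.05,
    temperature: float = 1.0,
    sex_bias_range: float = 0.3,
    sex_tilt: float = 0.6,
    countries: tuple = ("US",),
) -> SyntheticWorld:
    """Create a synthetic disease universe with known ground truth.

    Archetypes are assigned round-robin over the five default shapes; latent
    vectors are iid standard normal; true heritability is
    ``clip(h2_intercept - h2_slope * onset_age/65 + N(0, h2_noise_sd), 0, 1)``.
    Deterministic given ``seed``.
    """
    if n_diseases < 2:
        raise ValueError("n_diseases must be >= 2")
    if d_lat < 1:
        raise ValueError("d_lat must be >= 1")
    rng = np.random.default_rng(seed)
    archetypes = default_archetypes()
    sex_mod = default_sex_modifier(sex_tilt)
    names = [ARCHETYPE_NAMES[i % len(ARCHETYPE_NAMES)] for i in range(n_diseases)]
    codes = [f"D{i:04d}" for i in range(n_diseases)]
    latent = rng.standard_normal((n_diseases, d_lat))
    categories = rng.choice(CATEGORIES, size=n_diseases)
    sex_bias = rng.uniform(-sex_bias_range, sex_bias_range, size=n_diseases)

    onset = np.array([_onset_from_curve(archetypes[n].evaluate()) for n in names])
    h2 = np.clip(
        h2_intercept
        - h2_slope * onset / 65.0
        + rng.normal(0.0, h2_noise_sd, size=n_diseases),
        0.0,
        1.0,
    )
    diseases = pd.DataFrame(
        {
            "code": codes,
            "archetype": names,
            "category": categories,
            "sex_bias_true": sex_bias,
            "onset_age_true": onset,
            "h2_true": h2,
        }
    )

    curves = {n: archetypes[n].evaluate() for n in ARCHETYPE_NAMES}
    rows = []
    for i in range(n_diseases):
        for j in range(i + 1, n_diseases):
            rg = _cosine(latent[i], latent[j])
            re = 2.0 * _cosine(curves[names[i]], curves[names[j]]) - 1.0
            rows.append((codes[i], codes[j], rg, re))
    pair_truth = pd.DataFrame(rows, columns=["disease_a", "disease_b", "rg_true", "re_true"])

    return SyntheticWorld(
        diseases=diseases,
        latent=latent,
        archetypes=archetypes,
        pair_truth=pair_truth,
        seed=seed,
        temperature=temperature,
        countries=countries,
        sex_modifier=sex_mod,
    )


def simulate_events(
    world: SyntheticWorld,
    n_patients: int,
    mean_history_len: float = 4.0,
    seed: int = 0,
    *,
    repeat_rate: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a chronological diagnosis-event stream and enrollment table.

    Each patient draws a sex, a latent affinity vector, and a Poisson-sized
    set of diseases sampled without replacement with probability proportional
    to ``softmax(affinity . latent / temperature)`` times a sex-acceptance
    weight; each acquired disease emits ``1 + Poisson(repeat_rate)`` diagnosis
    codes at ages drawn from its sex-modified archetype curve, so the same
    code can repeat within a patient-year (deduplication is the curve
    module's job).  Enrollment counts every patient at every age, matching a
    population visible over the whole 0..65 range.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if mean_history_len <= 0:
        raise ValueError("mean_history_len must be positive")
    rng = np.random.default_rng(seed)
    n_d = len(world.diseases)
    codes = np.asarray(world.codes)
    names = world.diseases["archetype"].to_numpy()
    bias = world.diseases["sex_bias_true"].to_numpy()
    # per-disease, per-sex age pmfs
    pmf = {
        s: np.stack([world.archetypes[n].evaluate(sex=s) for n in names]) for s in SEXES
    }
    pmf_cum = {s: np.cumsum(p, axis=1) for s, p in pmf.items()}
    sex_weight = {"M": 0.5 + bias, "F": 0.5 - bias}

    n_countries = len(world.countries)
    country_ix = rng.integers(0, n_countries, size=n_patients)
    sexes = rng.choice(SEXES, size=n_patients)
    n_acquired = np.maximum(1, rng.poisson(mean_history_len, size=n_patients))
    n_acquired = np.minimum(n_acquired, n_d)

    pid_l, sex_l, age_l, code_l, ctry_l = [], [], [], [], []
    for p in range(n_patients):
        sex = sexes[p]
        affinity = rng.standard_normal(world.latent.shape[1])
        logits = world.latent @ affinity / world.temperature
        logits -= logits.max()
        w = np.exp(logits) * sex_weight[sex]
        total = w.sum()
        if total <= 0:
            continue
        w /= total
        chosen = rng.choice(n_d, size=n_acquired[p], replace=False, p=w)
        pid = f"P{p:07d}"
        country = world.countries[country_ix[p]]
        cum = pmf_cum[sex]
        for d in chosen:
            n_codes = 1 + rng.poisson(repeat_rate)
            ages = np.searchsorted(cum[d], rng.random(n_codes), side="right")
            for a in ages:
                pid_l.append(pid)
                sex_l.append(sex)
                age_l.append(int(min(a, N_AGES - 1)))
                code_l.append(codes[d])
                ctry_l.append(country)

    events = pd.DataFrame(
        {
            "patient_id": pid_l,
            "sex": sex_l,
            "age": age_l,
            "code": code_l,
            "country": ctry_l,
        }
    )
    # chronological order within patient, stable on emission order
    events = events.sort_values(["patient_id", "age"], kind="stable").reset_index(drop=True)

    rows = []
    for c_i, country in enumerate(world.countries):
        for s in SEXES:
            n_sc = int(np.sum((sexes == s) & (country_ix == c_i)))
            for a in AGES:
                rows.append((s, int(a), country, max(n_sc, 1)))
    enrollment = pd.DataFrame(rows, columns=ENROLLMENT_COLUMNS)
    return events, enrollment


def synthesize_estimates(
    world: SyntheticWorld,
    n_per_disease: int,
    se_range: tuple[float, float] = (0.02, 0.15),
    seed: int = 0,
    *,
    include_pairs: bool = True,
    pair_types: tuple = ("rg", "re"),
) -> pd.DataFrame:
    """Emit a noisy published-estimate table around the world's truth.

    Each disease contributes ``n_per_disease`` heritability records and (if
    ``include_pairs``) each unordered pair contributes ``n_per_disease``
    records per correlation type; ``value = truth + Normal(0, SE)`` with SE
    drawn uniformly from ``se_range``.  Study metadata (data type, model,
    sex, country) is drawn uniformly from the fixed vocabularies.
    """
    lo, hi = se_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("se_range must be within (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0

    def emit(etype, da, db, truth):
        nonlocal sid
        for _ in range(n_per_disease):
            se = rng.uniform(lo, hi)
            value = truth + rng.normal(0.0, se)
            rows.append(
                (
                    etype,
                    da,
                    db,
                    value,
                    se,
                    rng.choice(DATA_TYPES),
                    rng.choice(MODELS),
                    rng.choice(SEXES),
                    rng.choice(world.countries),
                    f"S{sid:06d}",
                )
            )
            sid += 1

    for _, d in world.diseases.iterrows():
        emit("h2", d["code"], "", d["h2_true"])
    if include_pairs:
        for _, p in world.pair_truth.iterrows():
            if "rg" in pair_types:
                emit("rg", p["disease_a"], p["disease_b"], p["rg_true"])
            if "re" in pair_types:
                emit("re", p["disease_a"], p["disease_b"], p["re_true"])
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
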