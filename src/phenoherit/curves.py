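"""Age/sex/country disease prevalence curves and per-disease summaries.

Two curve definitions are supported:

* **Analysis A** (enrollment-normalized): per age, the number of distinct
  patients carrying at least one diagnosis of the disease that year —
  a single code is counted per patient per year — divided by the number of
  enrollees in the same sex/age stratum, then re-normalized to sum to 1.
* **Analysis B** (share-of-diagnoses): per age, the disease's share of all
  diagnosis codes in the sex/age group, then re-normalized to sum to 1.
  Analysis B needs no enrollment table.

A disease's onset age is defined as the age at which the curve's inverse
distribution function reaches 0.05, i.e. the maximum age among the 5%
youngest diagnosis bearers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archetypes import AGE_MAX, AGES, N_AGES

logger = logging.getLogger(__name__)


class MissingEnrollmentError(ValueError):
    """An event stratum has no (or zero) enrollment."""


class EmptyCurveError(ValueError):
    """No mass available to normalize (no events for the selection)."""


@dataclass
class PrevalenceCurve:
    """A normalized 66-bin age distribution of a disease's diagnoses."""

    disease: str
    sex: str
    country: str
    values: np.ndarray
    analysis: str
    support_counts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AGES,):
            raise ValueError(f"curve must have {N_AGES} age bins")
        if np.any(self.values < 0):
            raise ValueError("curve values must be nonnegative")
        if not np.isclose(self.values.sum(), 1.0, atol=1e-9):
            raise ValueError("curve values must sum to 1")

    @property
    def label(self) -> tuple:
        return (self.disease, self.sex, self.country)


@dataclass
class DiseaseSummary:
    disease: str
    onset_age: int
    mean_carrier_age: float
    sex_bias: float
    total_diagnosis_count: int


def _drop_overage(events: pd.DataFrame) -> pd.DataFrame:
    over = events["age"] > AGE_MAX
    if over.any():
        logger.warning("dropping %d events with age > %d", int(over.sum()), AGE_MAX)
        events = events[~over]
    return events


def _normalize(raw: np.ndarray, pseudocount: float) -> np.ndarray:
    raw = raw + pseudocount
    total = raw.sum()
    if total <= 0:
        raise EmptyCurveError("all-zero curve cannot be normalized")
    return raw / total


def curve_analysis_a(
    events: pd.DataFrame,
    enrollment: pd.DataFrame,
    disease: str,
    sex: str,
    country: str,
    *,
    pseudocount: float = 0.0,
) -> PrevalenceCurve:
    """Enrollment-normalized prevalence curve (Analysis A).

    Counts one diagnosis per patient per year of age, divides by enrollment
    in the matching sex/age/country stratum, and re-normalizes to sum to 1.
    Raises :class:`MissingEnrollmentError` naming the first stratum that has
    events but no positive enrollment.
    """
    events = _drop_overage(events)
    sel = events[
        (events["code"] == disease)
        & (events["sex"] == sex)
        & (events["country"] == country)
    ]
    # one code per patient per year
    dedup = sel.drop_duplicates(subset=["patient_id", "age"])
    counts = np.zeros(N_AGES)
    vc = dedup["age"].value_counts()
    counts[vc.index.to_numpy()] = vc.to_numpy()

    enr = enrollment[(enrollment["sex"] == sex) & (enrollment["country"] == country)]
    enr_by_age = np.zeros(N_AGES)
    enr_by_age[enr["age"].to_numpy()] = enr["count"].to_numpy()
    bad = (counts > 0) & (enr_by_age <= 0)
    if bad.any():
        age = int(np.argmax(bad))
        raise MissingEnrollmentError(
            f"stratum (sex={sex}, age={age}, country={country}) has events but no enrollment"
        )
    rates = np.divide(counts, enr_by_age, out=np.zeros(N_AGES), where=enr_by_age > 0)
    values = _normalize(rates, pseudocount)
    return PrevalenceCurve(disease, sex, country, values, "A", counts)


def curve_analysis_b(
    events: pd.DataFrame,
    disease: str,
    sex: str,
    country: str,
    *,
    pseudocount: float = 0.0,
) -> PrevalenceCurve:
    """Share-of-diagnoses prevalence curve (Analysis B).

    Per age, the disease's raw code count divided by the total code count of
    all diseases in the sex/age/country group, re-normalized to sum to 1.
    """
    events = _drop_overage(events)
    group = events[(events["sex"] == sex) & (events["country"] == country)]
    if len(group) == 0:
        raise EmptyCurveError(f"no events for group (sex={sex}, country={country})")
    totals = np.zeros(N_AGES)
    vc_all = group["age"].value_counts()
    totals[vc_all.index.to_numpy()] = vc_all.to_numpy()
    counts = np.zeros(N_AGES)
    vc = group.loc[group["code"] == disease, "age"].value_counts()
    counts[vc.index.to_numpy()] = vc.to_numpy()
    shares = np.divide(counts, totals, out=np.zeros(N_AGES), where=totals > 0)
    values = _normalize(shares, pseudocount)
    return PrevalenceCurve(disease, sex, country, values, "B", counts)


def onset_age(curve) -> int:
    """Smallest age whose cumulative curve mass reaches 0.05.

    Accepts a :class:`PrevalenceCurve` or a bare normalized 66-vector.
    """
    values = curve.values if isinstance(curve, PrevalenceCurve) else np.asarray(curve, float)
    c = np.cumsum(values)
    reached = c >= 0.05 - 1e-12
    if not reached.any():
        raise EmptyCurveError("curve mass never reaches 0.05")
    return int(np.argmax(reached))


def mean_carrier_age(curve) -> float:
    """Expected age under the normalized curve."""
    values = curve.values if isinstance(curve, PrevalenceCurve) else np.asarray(curve, float)
    return float(np.dot(AGES, values))


def combined_sex_curve_b(events: pd.DataFrame, disease: str, country: str) -> PrevalenceCurve:
    """Analysis-B curve pooling both sexes (used for summaries/features)."""
    pooled = events.copy()
    pooled["sex"] = "all"
    return curve_analysis_b(pooled, disease, "all", country)


def summarize(
    events: pd.DataFrame,
    curves: dict | None = None,
    *,
    country: str | None = None,
) -> pd.DataFrame:
    """Per-disease summary descriptors from an event stream.

    ``sex_bias = 0.5 * (n_M - n_F) / (n_M + n_F)`` over raw code counts, so
    it is 0 for diseases equally frequent in both sexes and ±0.5 for
    single-sex diseases; ``mean_carrier_age`` is the expectation of the
    combined-sex curve (taken from ``curves`` if given, else an Analysis-B
    combined-sex curve computed here); ``total_diagnosis_count`` is the raw
    code count.
    """
    events = _drop_overage(events)
    if country is not None:
        events = events[events["country"] == country]
    if len(events) == 0:
        raise EmptyCurveError("no events to summarize")
    rows = []
    for disease, sub in events.groupby("code", sort=True):
        n_m = int((sub["sex"] == "M").sum())
        n_f = int((sub["sex"] == "F").sum())
        if n_m + n_f == 0:
            raise ValueError(f"disease {disease}: no sexed diagnoses, bias undefined")
        bias = 0.5 * (n_m - n_f) / (n_m + n_f)
        if curves is not None and disease in curves:
            curve = curves[disease]
        else:
            ctry = sub["country"].iloc[0]
            curve = combined_sex_curve_b(events, disease, ctry)
        rows.append(
            DiseaseSummary(
                disease=disease,
                onset_age=onset_age(curve),
                mean_carrier_age=mean_carrier_age(curve),
                sex_bias=bias,
                total_diagnosis_count=len(sub),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
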