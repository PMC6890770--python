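"""Downstream statistical analyses.

* Spearman rank correlation with AS 89 p-values (exact permutation
  enumeration at small n, the published Edgeworth series otherwise);
* onset-age associations with diagnosis count and pooled heritability,
  overall and per shape cluster, with OLS slope/intercept t-tests;
* the shape-of-curve dissimilarity regression
  ``D_soc ~ 1 + r_g + r_e + r_g * r_e``;
* a two-sided Wilcoxon rank-sum comparison of absolute prediction errors
  between disease groups (e.g. acute versus chronic), exact for small
  samples and normal-approximated with midrank tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

EXACT_SPEARMAN_MAX_N = 8
EXACT_RANKSUM_MAX_COMB = 100_000


class DegenerateInputError(ValueError):
    """Statistic undefined for the given input (e.g. constant vector)."""


class RankDeficiencyError(ValueError):
    """Regression design matrix is not full rank."""


# ---------------------------------------------------------------------------
# Spearman's rho with AS 89 p-values
# ---------------------------------------------------------------------------

# Edgeworth series coefficients of the AS 89 upper-tail approximation
_AS89_C = (
    0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
    0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.04567,
)


def _as89_upper_tail(s: float, n: int) -> float:
    """P(S >= s) for Spearman's sum of squared rank differences (n > 8)."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _AS89_C
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * math.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (
        c1
        + b * (c2 + c3 * b)
        + y * (-c4 + b * (c5 + c6 * b) - y * b * (c7 + c8 * b - y * (c9 - c10 * b + y * b * (c11 - c12 * y))))
    )
    p = u / math.exp(y / 2.0) + sps.norm.sf(x)
    return float(min(max(p, 0.0), 1.0))


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman_as89(x, y) -> tuple[float, float]:
    """Spearman's rho (midrank ties) with a two-sided AS 89 p-value.

    For n <= 8 the p-value is computed by exact enumeration over all
    permutations of one margin; above that, the tie-corrected statistic is
    mapped to the equivalent sum of squared rank differences
    ``S = (1 - rho) n (n^2 - 1) / 6`` and the AS 89 Edgeworth series gives
    the tail probabilities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= EXACT_SPEARMAN_MAX_N:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rho_from_ranks(rx, ry[list(perm)])) >= target:
                count += 1
        return rho, count / total

    s_obs = (1.0 - rho) * n * (n * n - 1.0) / 6.0
    s_max = n * (n * n - 1.0) / 3.0
    p_neg = _as89_upper_tail(s_obs, n)           # tail toward rho <= observed
    p_pos = _as89_upper_tail(s_max - s_obs, n)   # tail toward rho >= observed
    return rho, float(min(1.0, 2.0 * min(p_neg, p_pos)))


# ---------------------------------------------------------------------------
# onset-age associations
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One stratum's Spearman and OLS association between two descriptors."""

    analysis: str
    stratum: str
    n: int
    spearman_rho: float
    spearman_p: float
    ols_slope: float
    ols_intercept: float
    slope_p: float
    intercept_p: float


def _associate(x, y, analysis, stratum) -> AssociationResult:
    rho, p = spearman_as89(x, y)
    design = sm.add_constant(np.asarray(x, float))
    fit = sm.OLS(np.asarray(y, float), design).fit()
    return AssociationResult(
        analysis=analysis,
        stratum=str(stratum),
        n=len(x),
        spearman_rho=rho,
        spearman_p=p,
        ols_slope=float(fit.params[1]),
        ols_intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
    )


def onset_associations(
    summaries: pd.DataFrame,
    h2: pd.Series | None = None,
    cluster_by_disease: pd.Series | None = None,
    *,
    log_counts: bool = True,
) -> list[AssociationResult]:
    """Onset-age associations, overall and per shape cluster.

    Tests (onset age vs total diagnosis count) and, when pooled heritability
    values are supplied, (onset age vs h2).  Diagnosis counts span orders of
    magnitude, so the OLS fit uses log10 counts by default (Spearman is
    scale-free and unaffected).  Strata with fewer than 3 diseases are
    skipped.
    """
    df = summaries.set_index("disease")
    counts = df["total_diagnosis_count"].astype(float)
    if log_counts:
        counts = np.log10(counts)
    results = []

    def strata():
        yield "all", df.index
        if cluster_by_disease is not None:
            cl = cluster_by_disease.reindex(df.index)
            for k in sorted(cl.dropna().unique()):
                yield f"cluster_{int(k)}", cl.index[cl == k]

    for name, idx in strata():
        if len(idx) < 3:
            continue
        onset = df.loc[idx, "onset_age"].to_numpy(float)
        try:
            results.append(_associate(onset, counts.loc[idx].to_numpy(), "onset_vs_count", name))
        except DegenerateInputError:
            pass
        if h2 is not None:
            joined = h2.reindex(idx).dropna()
            if len(joined) >= 3:
                try:
                    results.append(
                        _associate(
                            df.loc[joined.index, "onset_age"].to_numpy(float),
                            joined.to_numpy(float),
                            "onset_vs_h2",
                            name,
                        )
                    )
                except DegenerateInputError:
                    pass
    return results


def associations_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# D_soc regression
# ---------------------------------------------------------------------------

@dataclass
class DsocRegressionResult:
    """OLS fit of D_soc on [1, r_g, r_e, r_g * r_e]."""

    beta0: float
    beta_g: float
    beta_e: float
    beta_ge: float
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n: int

    def predict(self, rg, re):
        rg = np.asarray(rg, float)
        re = np.asarray(re, float)
        return self.beta0 + self.beta_g * rg + self.beta_e * re + self.beta_ge * rg * re


def dsoc_regression(pairs: pd.DataFrame) -> DsocRegressionResult:
    """Regress shape-of-curve dissimilarity on genetic/environmental
    correlations with their interaction.

    ``pairs`` must carry columns ``dsoc``, ``rg``, ``re`` with no missing
    values; a rank-deficient design (e.g. a constant correlation column)
    raises :class:`RankDeficiencyError`.
    """
    req = {"dsoc", "rg", "re"}
    if not req.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(req)}")
    if len(pairs) < 5:
        raise ValueError("need at least 5 pairs")
    if pairs[list(req)].isna().any().any():
        raise ValueError("missing values in pairs table")
    rg = pairs["rg"].to_numpy(float)
    re = pairs["re"].to_numpy(float)
    X = np.column_stack([np.ones(len(rg)), rg, re, rg * re])
    if np.linalg.matrix_rank(X) < 4:
        raise RankDeficiencyError("design [1, rg, re, rg*re] is rank deficient")
    fit = sm.OLS(pairs["dsoc"].to_numpy(float), X).fit()
    return DsocRegressionResult(
        beta0=float(fit.params[0]),
        beta_g=float(fit.params[1]),
        beta_e=float(fit.params[2]),
        beta_ge=float(fit.params[3]),
        se=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        n=len(pairs),
    )


# ---------------------------------------------------------------------------
# rank-sum comparison of absolute errors
# ---------------------------------------------------------------------------

def acute_chronic_error_test(abs_errors_a, abs_errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on two groups of absolute errors.

    Returns (W, p) where W is the midrank sum of the first group.  Exact
    enumeration over all group assignments when feasible; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0

    if math.comb(n1 + n2, n1) <= EXACT_RANKSUM_MAX_COMB:
        dev = abs(w_obs - mu) - 1e-12
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev:
                count += 1
        return w_obs, count / total

    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
    if var <= 0:
        return w_obs, 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    return w_obs, float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
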