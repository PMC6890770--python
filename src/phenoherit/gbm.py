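"""From-scratch gradient boosting regression and its evaluation harness.

The imputer is a stage-wise additive ensemble of regression trees under
squared-error loss:

    F_0(X) = mean(y)
    for m = 1..M:
        r_i = y_i - F_{m-1}(X_i)            (residuals)
        fit a regression tree h_m to r       (greedy variance-reduction splits,
                                              leaf value = residual mean, the
                                              exact line-search solution per
                                              region under squared loss)
        F_m(X) = F_{m-1}(X) + rate * h_m(X)

Defaults are M = 200 trees and shrinkage rate 0.1.  Split candidates are
midpoints between consecutive distinct sorted feature values; ties in gain
break toward the lowest feature index, then the lowest threshold, so fitting
is fully deterministic.  Gain (squared-error reduction) is accumulated per
feature for importance reporting.

The harness evaluates held-out accuracy over repeated random 4:1
train/validation splits, reporting the Pearson correlation and the
least-squares slope/intercept of actual versus predicted values per split.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_SERIAL_VERSION = 1

try:  # optional JIT acceleration of the split scan
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@_njit(cache=False)
def _scan_splits(X_T, idx, r, min_leaf):  # pragma: no cover - JIT kernel
    """Scan all (feature, threshold) candidates over presorted indices.

    Returns (feature, split position, gain); feature is -1 when no split
    strictly reduces the squared error.  Scanning features then positions in
    ascending order with a strict improvement test implements the
    lowest-feature-then-lowest-threshold tie rule.
    """
    d, m = idx.shape
    total = 0.0
    for i in range(m):
        total += r[idx[0, i]]
    base = total * total / m
    best_gain = 1e-12
    best_j = -1
    best_i = -1
    for j in range(d):
        left = 0.0
        for i in range(m - 1):
            row = idx[j, i]
            left += r[row]
            if X_T[j, idx[j, i + 1]] <= X_T[j, row]:
                continue
            k = i + 1
            if k < min_leaf or m - k < min_leaf:
                continue
            right = total - left
            gain = left * left / k + right * right / (m - k) - base
            if gain > best_gain:
                best_gain = gain
                best_j = j
                best_i = i
    return best_j, best_i, best_gain


# ---------------------------------------------------------------------------
# regression trees
# ---------------------------------------------------------------------------

def _best_split_sorted(X_T: np.ndarray, idx: np.ndarray, r: np.ndarray, min_leaf: int):
    """Best split of residuals r over presorted per-feature row indices.

    ``X_T`` is the feature matrix transposed to (d, n); ``idx`` is a (d, m)
    matrix whose row j lists the node's rows sorted by feature j.  Returns
    (feature, split position, threshold, sse_reduction) or None when no
    split strictly reduces the squared error.
    """
    d, m = idx.shape
    if m < 2 * min_leaf:
        return None
    if _HAVE_NUMBA:
        j, i, best = _scan_splits(X_T, idx, r, min_leaf)
        if j < 0:
            return None
    else:
        Xs = np.take_along_axis(X_T, idx, axis=1)
        csum = np.cumsum(r[idx], axis=1)
        total = csum[0, -1]
        k = np.arange(1, m, dtype=float)
        left = csum[:, :-1]
        gain = left**2 / k + (total - left) ** 2 / (m - k) - total**2 / m
        valid = Xs[:, 1:] > Xs[:, :-1]
        if min_leaf > 1:
            ki = np.arange(1, m)
            valid = valid & (ki >= min_leaf) & (m - ki >= min_leaf)
        gain = np.where(valid, gain, -np.inf)
        best = gain.max()
        if not np.isfinite(best) or best <= 1e-12:
            return None
        # ties break toward the lowest feature index, then lowest threshold
        # (positions scan left to right, so thresholds increase)
        j = int(np.argmax((gain == best).any(axis=1)))
        i = int(np.argmax(gain[j] == best))
    x_lo = float(X_T[j, idx[j, i]])
    x_hi = float(X_T[j, idx[j, i + 1]])
    thr = 0.5 * (x_lo + x_hi)
    # midpoints of adjacent floats can round up to the right value, which
    # would empty the right child; fall back to the left value itself
    if thr >= x_hi:
        thr = x_lo
    return j, i, float(thr), float(best)


def _build_tree(X_T, idx, r, depth, max_depth, min_leaf, gains, train_pred):
    """Recursively grow one tree; writes leaf values into ``train_pred``."""
    d, m = idx.shape
    sp = None
    if depth < max_depth and m >= 2 * min_leaf:
        sp = _best_split_sorted(X_T, idx, r, min_leaf)
    if sp is None:
        rows = idx[0]
        value = float(r[rows].mean())
        train_pred[rows] = value
        return {"value": value}
    j, i, thr, g = sp
    gains[j] += g
    mask = np.zeros(X_T.shape[1], dtype=bool)
    mask[idx[j, : i + 1]] = True
    keep = mask[idx]
    left_idx = idx[keep].reshape(d, i + 1)
    right_idx = idx[~keep].reshape(d, m - i - 1)
    return {
        "feature": j,
        "threshold": thr,
        "left": _build_tree(X_T, left_idx, r, depth + 1, max_depth, min_leaf, gains, train_pred),
        "right": _build_tree(X_T, right_idx, r, depth + 1, max_depth, min_leaf, gains, train_pred),
    }


def _tree_predict(node, X, out, idx):
    if "value" in node:
        out[idx] = node["value"]
        return
    m = X[idx, node["feature"]] <= node["threshold"]
    _tree_predict(node["left"], X, out, idx[m])
    _tree_predict(node["right"], X, out, idx[~m])


def tree_predict(node, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    _tree_predict(node, X, out, np.arange(len(X)))
    return out


# ---------------------------------------------------------------------------
# the boosted model
# ---------------------------------------------------------------------------

@dataclass
class GBMModel:
    """A fitted stage-wise ensemble with constant initial predictor."""

    F0: float
    trees: list
    rate: float
    M: int
    max_depth: int
    n_features: int
    loss_trace: np.ndarray
    feature_gain: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"X must have {self.n_features} columns, got shape {X.shape}"
            )
        pred = np.full(len(X), self.F0)
        for tree in self.trees:
            pred += self.rate * tree_predict(tree, X)
        return pred

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": _SERIAL_VERSION,
                "F0": self.F0,
                "rate": self.rate,
                "M": self.M,
                "max_depth": self.max_depth,
                "n_features": self.n_features,
                "trees": self.trees,
                "loss_trace": list(self.loss_trace),
                "feature_gain": list(self.feature_gain),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GBMModel":
        obj = json.loads(text)
        if obj.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unknown model version: {obj.get('version')!r}")
        return cls(
            F0=obj["F0"],
            trees=obj["trees"],
            rate=obj["rate"],
            M=obj["M"],
            max_depth=obj["max_depth"],
            n_features=obj["n_features"],
            loss_trace=np.array(obj["loss_trace"]),
            feature_gain=np.array(obj["feature_gain"]),
        )


def fit(
    X,
    y,
    M: int = 200,
    rate: float = 0.1,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
    seed: int | None = None,
) -> GBMModel:
    """Fit the boosted ensemble; fully deterministic (seed kept for API).

    A stage whose tree finds no improving split degenerates to a constant
    (the residual mean); this is logged once, not an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per y value")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    F0 = float(y.mean())
    pred = np.full(len(y), F0)
    trees = []
    losses = []
    gains = np.zeros(X.shape[1])
    warned = False
    # features are presorted once; children inherit filtered sorted orders
    X_T = np.ascontiguousarray(X.T)
    root_idx = np.argsort(X, axis=0, kind="stable").T.copy()
    tree_out = np.empty(len(y))
    for _ in range(M):
        resid = y - pred
        tree = _build_tree(
            X_T, root_idx, resid, 0, max_depth, min_samples_leaf, gains, tree_out
        )
        if "value" in tree and not warned and M > 0:
            logger.info("stage tree found no improving split; constant update")
            warned = True
        trees.append(tree)
        pred += rate * tree_out
        losses.append(float(np.mean((y - pred) ** 2)))
    return GBMModel(
        F0=F0,
        trees=trees,
        rate=rate,
        M=M,
        max_depth=max_depth,
        n_features=X.shape[1],
        loss_trace=np.array(losses),
        feature_gain=gains,
    )


def predict(model: GBMModel, X) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# inverse-variance pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    value: float
    se: float | None
    n: int
    weighted: bool


def pool_estimates(values, ses=None) -> PooledEstimate:
    """Inverse-variance weighted pooling of estimates.

    ``value = sum(v_i / SE_i^2) / sum(1 / SE_i^2)`` and
    ``SE = sqrt(1 / sum(1 / SE_i^2))``.  If any SE is missing the pooled
    value falls back to the unweighted mean with SE undefined (flagged via
    ``weighted=False``).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot pool an empty list of estimates")
    if ses is None:
        return PooledEstimate(float(values.mean()), None, len(values), False)
    ses = np.asarray(ses, dtype=float)
    if ses.shape != values.shape:
        raise ValueError("values and ses must align")
    if np.any(np.isnan(ses)):
        return PooledEstimate(float(values.mean()), None, len(values), False)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    return PooledEstimate(
        float(np.sum(w * values) / np.sum(w)),
        float(math.sqrt(1.0 / np.sum(w))),
        len(values),
        True,
    )


# ---------------------------------------------------------------------------
# evaluation over repeated random splits
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Held-out accuracy over repeated random train/validation splits."""

    pearson_r: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    n_splits: int
    n_skipped: int
    mean_r: float = field(init=False)
    ci_half_r: float = field(init=False)
    mean_slope: float = field(init=False)
    mean_intercept: float = field(init=False)

    def __post_init__(self):
        self.mean_r = float(np.mean(self.pearson_r)) if len(self.pearson_r) else float("nan")
        self.mean_slope = float(np.mean(self.slope)) if len(self.slope) else float("nan")
        self.mean_intercept = (
            float(np.mean(self.intercept)) if len(self.intercept) else float("nan")
        )
        k = len(self.pearson_r)
        self.ci_half_r = (
            float(1.96 * np.std(self.pearson_r, ddof=1) / math.sqrt(k)) if k > 1 else float("nan")
        )


def evaluate(
    X,
    y,
    n_splits: int = 1000,
    split_frac: float = 0.8,
    seed: int = 0,
    *,
    fit_predict=None,
    **fit_kwargs,
) -> EvaluationReport:
    """Repeated random-split evaluation (default 4:1 train:validation).

    For each split, a model is fitted on the training fraction and its
    held-out predictions are compared with the actual values: Pearson r and
    the least-squares slope/intercept of actual (response) on predicted
    (regressor).  Splits with constant held-out actuals or predictions are
    skipped and counted.  ``fit_predict(Xtr, ytr, Xte) -> predictions`` may
    be injected to evaluate a different predictor through the same harness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 rows to evaluate")
    if fit_predict is None:
        def fit_predict(Xtr, ytr, Xte):
            return fit(Xtr, ytr, **fit_kwargs).predict(Xte)

    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(split_frac * n))
    rs, slopes, intercepts = [], [], []
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        pred = np.asarray(fit_predict(X[tr], y[tr], X[te]), dtype=float)
        actual = y[te]
        if np.std(actual) == 0 or np.std(pred) == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(pred, actual)[0, 1])
        slope = float(np.cov(pred, actual, ddof=1)[0, 1] / np.var(pred, ddof=1))
        intercept = float(actual.mean() - slope * pred.mean())
        rs.append(r)
        slopes.append(slope)
        intercepts.append(intercept)
    return EvaluationReport(
        pearson_r=np.array(rs),
        slope=np.array(slopes),
        intercept=np.array(intercepts),
        n_splits=n_splits,
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# importance accounting
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    per_feature: np.ndarray
    block_shares: dict
    no_splits: bool


def feature_importance(model: GBMModel, schema=None) -> ImportanceReport:
    """Gain importance per feature, optionally aggregated by schema group.

    Gain is the total squared-error reduction contributed by splits on each
    feature across all trees, normalized to sum to 1.  A model that never
    split is flagged (uniform zeros).
    """
    gains = model.feature_gain.copy()
    total = gains.sum()
    if total <= 0:
        per_feature = np.zeros_like(gains)
        no_splits = True
    else:
        per_feature = gains / total
        no_splits = False
    shares = {}
    if schema is not None:
        for group, cols in schema.groups().items():
            shares[group] = float(per_feature[cols].sum())
    return ImportanceReport(per_feature=per_feature, block_shares=shares, no_splits=no_splits)
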