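"""Shape-of-curve dissimilarity and shape clustering.

The shape-of-curve dissimilarity D_soc between two prevalence curves is the
minimum base-2 Jensen-Shannon divergence over integer temporal shifts of one
curve relative to the other (-8..+8 years by default); after a shift, both
curves are restricted to the overlapping age window and re-normalized, which
avoids the disjoint-support saturation that zero-padding would introduce.

Curve shapes are grouped by complete-linkage hierarchical clustering of the
full dissimilarity matrix; the number of clusters is chosen at the elbow of
the total intra-cluster variation W(K), computed from pairwise squared
dissimilarities via the identity
``sum_{i in C_k} (x_i - mu_k)^2 = (1 / (2 |C_k|)) * sum_{i,j in C_k} d_ij^2``
(exact when d is Euclidean), which avoids embedding the curves in a
coordinate space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between probability vectors.

    ``JSD(p, q) = 0.5 KL(p || m) + 0.5 KL(q || m)`` with ``m = (p + q)/2``,
    logs base 2 and the convention ``0 log 0 = 0``; bounded in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * (np.log2(p) - np.log2(m)), 0.0)
        kl_q = np.where(q > 0, q * (np.log2(q) - np.log2(m)), 0.0)
    return float(np.clip(0.5 * kl_p.sum() + 0.5 * kl_q.sum(), 0.0, 1.0))


def shifted_dissimilarity(p, q, max_shift: int = 8) -> tuple[float, int]:
    """Shift-minimized JSD between two curves and the optimal shift.

    For each integer shift s in [-max_shift, max_shift], curve ``q`` is slid
    by s years, both curves are restricted to the overlapping age window and
    re-normalized, and the JSD is computed; returns the minimum and its
    argmin shift.  Ties in JSD are broken toward the smallest |s|, negative
    before positive. Shifts whose overlap window has no mass in either curve
    are skipped.
    """
    pv = np.asarray(getattr(p, "values", p), dtype=float)
    qv = np.asarray(getattr(q, "values", q), dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("curves must share one age grid")
    n = len(pv)
    best = None
    shifts = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    for s in shifts:
        # positive s means q's pattern sits s years later than p's;
        # compare p[i] with q[i + s] over the valid window
        lo = max(0, -s)
        hi = n - max(0, s)
        if hi <= lo:
            continue
        pw = pv[lo:hi]
        qw = qv[lo + s : hi + s]
        ps, qs = pw.sum(), qw.sum()
        if ps <= 0 or qs <= 0:
            continue
        d = jsd(pw / ps, qw / qs)
        if best is None or d < best[0] - 1e-15:
            best = (d, s)
    if best is None:
        raise ValueError("no shift produced a non-empty overlap with mass")
    return best


@dataclass
class ShapeDissimilarityMatrix:
    """Symmetric shift-minimized JSD matrix with its antisymmetric shifts."""

    labels: list
    D: np.ndarray
    shifts: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        assert self.D.shape == (n, n) and self.shifts.shape == (n, n)


def dissimilarity_matrix(curves, max_shift: int = 8) -> ShapeDissimilarityMatrix:
    """Pairwise shift-minimized JSD over a list of curves.

    Labels are the curves' (disease, sex, country) keys; duplicates are
    rejected.  ``D`` is symmetric with zero diagonal; ``shifts`` is
    antisymmetric (the optimal shift of j relative to i).
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    labels = [getattr(c, "label", i) for i, c in enumerate(curves)]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate curve labels")
    n = len(curves)
    D = np.zeros((n, n))
    S = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d, s = shifted_dissimilarity(curves[i], curves[j], max_shift)
            D[i, j] = D[j, i] = d
            S[i, j] = s
            S[j, i] = -s
    return ShapeDissimilarityMatrix(labels, D, S)


def intra_cluster_variation(D: np.ndarray, assignment: np.ndarray) -> float:
    """Total intra-cluster variation W from a dissimilarity matrix.

    ``W = sum_k (1 / (2 |C_k|)) * sum_{i,j in C_k} D_ij^2``; for Euclidean D
    this equals the sum of squared deviations from cluster centroids.
    """
    D2 = np.asarray(D, float) ** 2
    w = 0.0
    for k in np.unique(assignment):
        idx = np.flatnonzero(assignment == k)
        w += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return float(w)


def select_elbow(W: np.ndarray) -> int:
    """Elbow of a non-increasing variation profile W(K), K = 1..len(W).

    The elbow — where the decline switches from fast to slow — is taken as
    the K maximizing the perpendicular distance between the normalized
    profile and the chord joining its endpoints (kneedle criterion); ties
    break toward smaller K.
    """
    W = np.asarray(W, float)
    K = len(W)
    if K == 1 or W[0] <= W[-1] + 1e-15:
        return 1
    x = np.linspace(0.0, 1.0, K)
    y = (W - W[-1]) / (W[0] - W[-1])
    # distance from (x, y) to the chord from (0, 1) to (1, 0)
    dist = (1.0 - x - y) / np.sqrt(2.0)
    return int(np.argmax(np.round(dist, 12))) + 1


@dataclass
class ClusterSolution:
    """A complete-linkage clustering with its elbow-selection profile."""

    K: int
    assignment: np.ndarray
    linkage: np.ndarray
    elbow_profile: np.ndarray
    labels: list


def cluster(dmat: ShapeDissimilarityMatrix, K_max: int = 25) -> ClusterSolution:
    """Complete-linkage clustering with elbow selection of K.

    Builds a bottom-up hierarchy on the dissimilarity matrix, computes the
    total intra-cluster variation W(K) for K = 1..K_max, and returns the
    assignment at the elbow K*.
    """
    n = len(dmat.labels)
    if K_max > n:
        logger.warning("K_max=%d exceeds n=%d labels; clipping", K_max, n)
        K_max = n
    condensed = squareform(dmat.D, checks=False)
    Z = linkage(condensed, method="complete")
    cuts = cut_tree(Z, n_clusters=list(range(1, K_max + 1)))
    W = np.array(
        [intra_cluster_variation(dmat.D, cuts[:, k - 1]) for k in range(1, K_max + 1)]
    )
    K_star = select_elbow(W)
    return ClusterSolution(
        K=K_star,
        assignment=cuts[:, K_star - 1].astype(int),
        linkage=Z,
        elbow_profile=W,
        labels=dmat.labels,
    )
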