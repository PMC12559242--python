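"""Cell-cell splicing similarity networks with adaptive neighborhood size.

Cells with similar splicing machinery activity are assumed to share splicing
patterns, so similarity can be measured from RNA-binding-protein (RBP)
expression, raw junction read counts, or raw PSI values.  The feature matrix
is reduced by PCA (components kept until cumulative explained variance
exceeds a threshold), pairwise Euclidean distances are computed in the
reduced space, a per-cell neighborhood size k_c is picked by the dynamic-K
jump detector on the sorted distance profile, and the k_c nearest distances
are mapped through an adaptive-bandwidth Gaussian kernel before the matrix
is symmetrized by adding its transpose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class SimilarityNetwork:
    """Square weighted similarity matrix over cells or events.

    ``state`` tracks the processing stage: ``kernel`` (symmetric Gaussian
    kernel weights), ``transition`` (row-stochastic), or ``diffused``
    (post random-walk, row-stochastic).
    """

    values: np.ndarray
    node_ids: list[str]
    per_node_k: np.ndarray
    state: str = "kernel"
    converged: bool | None = None
    iterations: int | None = None
    delta_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = [str(x) for x in self.node_ids]
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match node ids")
        if np.any(self.values < 0):
            raise ValueError("similarity values must be nonnegative")
        self.per_node_k = np.asarray(self.per_node_k, dtype=int)
        if self.per_node_k.shape == ():
            self.per_node_k = np.full(n, int(self.per_node_k))
        if self.per_node_k.shape != (n,):
            raise ValueError("per_node_k must have one entry per node")
        if self.state == "kernel" and not np.allclose(self.values, self.values.T):
            raise ValueError("kernel-state network must be symmetric")
        if self.state in ("transition", "diffused"):
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{self.state}-state network rows must sum to 1")


def reduce_dimensions(feature_matrix: np.ndarray, var_threshold: float = 0.9) -> np.ndarray:
    """PCA scores keeping the smallest number of components whose cumulative
    explained variance exceeds ``var_threshold``.

    Missing entries are treated as 0 before reduction (sparse splicing
    matrices carry structural zeros for unobserved pairs).
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 cells (rows) for reduction")
    X = np.nan_to_num(X, nan=0.0)
    nonconstant = np.ptp(X, axis=0) > 0
    if nonconstant.sum() < 2:
        raise ValueError("need at least 2 nonconstant features")
    X = X[:, nonconstant]
    n_max = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    over = np.nonzero(cum > var_threshold)[0]
    p = int(over[0]) + 1 if over.size else n_max
    return scores[:, :p]


def pairwise_euclidean(reduced: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    X = np.asarray(reduced, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in reduced matrix")
    return squareform(pdist(X, metric="euclidean"))


def select_dynamic_k(sorted_distances: np.ndarray) -> int:
    """Adaptive neighbor count from a sorted distance profile.

    With the ascending distances d_1..d_{M-1} of one cell to all others,
    df(i) = d_{i+1} - d_i and cdf(i) = mean(df(1..i)).  The jump threshold
    is the mean of the strictly positive values of df(i+1) - cdf(i) over
    i = 1..M-3 (0 if none is positive), and k is the first index with
    df(k) - cdf(k-1) above the threshold.  When no index qualifies the
    profile holds no detectable jump and k falls back to M-1.
    """
    d = np.asarray(sorted_distances, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise ValueError(
            "dynamic-K needs a sorted distance vector of length >= 3; "
            "use a fixed k for smaller datasets"
        )
    if np.any(np.diff(d) < -1e-12):
        raise ValueError("distance vector must be nondecreasing")
    df = np.diff(d)
    cdf = np.cumsum(df) / np.arange(1, df.size + 1)
    gaps = df[1:] - cdf[:-1]  # gaps[i-1] = df(i+1) - cdf(i), 1-based i
    positive = gaps[gaps > 0]
    delta_bar = float(positive.mean()) if positive.size else 0.0
    qualifying = np.nonzero(gaps > delta_bar)[0]
    if qualifying.size:
        return int(qualifying[0]) + 2  # gaps index i maps to k = i + 2
    logger.debug("dynamic-K: no jump detected, falling back to k = M-1 = %d", d.size)
    return int(d.size)


def _neighbor_order(distance_row: np.ndarray, self_index: int) -> np.ndarray:
    """Indices of the other nodes sorted by (distance, index) ascending."""
    order = np.lexsort((np.arange(distance_row.size), distance_row))
    return order[order != self_index]


def _kernel_bandwidth(sorted_d: np.ndarray, k: int) -> float:
    """Zoom factor: the (ceil(k/3)+1)-th smallest distance; degenerate rows
    with that distance 0 fall back to the smallest nonzero distance, or 1."""
    idx = math.ceil(k / 3) + 1  # 1-based rank
    sigma = float(sorted_d[min(idx, sorted_d.size) - 1])
    if sigma == 0.0:
        nonzero = sorted_d[sorted_d > 0]
        sigma = float(nonzero[0]) if nonzero.size else 1.0
    return sigma


def build_knn_kernel(
    distance_matrix: np.ndarray,
    per_node_k: np.ndarray | int,
    node_ids: list[str] | None = None,
) -> SimilarityNetwork:
    """Adaptive-bandwidth Gaussian kernel on the k nearest neighbors per node,
    symmetrized by adding the transpose.

    Shared by the cell network (per-cell dynamic k) and the event network
    (fixed k).  Entry (i, j) before symmetrization is exp(-(d_ij / sigma_i)^2)
    for j among i's k_i nearest nodes, 0 otherwise; sigma_i is the
    (ceil(k_i/3)+1)-th smallest distance of node i.  Distance ties are broken
    by node order so neighbor sets are reproducible.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    k_vec = np.asarray(per_node_k, dtype=int)
    if k_vec.shape == ():
        k_vec = np.full(n, int(k_vec))
    if np.any(k_vec < 1) or np.any(k_vec > n - 1):
        raise ValueError("per-node k must lie in [1, n-1]")
    S = np.zeros((n, n))
    for i in range(n):
        order = _neighbor_order(D[i], i)
        sorted_d = D[i][order]
        k = int(k_vec[i])
        sigma = _kernel_bandwidth(sorted_d, k)
        keep = order[:k]
        S[i, keep] = np.exp(-((D[i, keep] / sigma) ** 2))
    S = S + S.T
    return SimilarityNetwork(S, node_ids, k_vec, state="kernel")


def build_cell_similarity(
    distance_matrix: np.ndarray,
    per_node_k: np.ndarray | int | None = None,
    node_ids: list[str] | None = None,
) -> SimilarityNetwork:
    """Cell similarity kernel; ``per_node_k`` defaults to the dynamic-K choice
    per cell."""
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if per_node_k is None:
        ks = np.empty(n, dtype=int)
        for i in range(n):
            order = _neighbor_order(D[i], i)
            ks[i] = select_dynamic_k(D[i][order])
        per_node_k = ks
    return build_knn_kernel(D, per_node_k, node_ids)


def cell_network_from_features(
    feature_matrix: np.ndarray,
    node_ids: list[str] | None = None,
    var_threshold: float = 0.9,
    per_node_k: np.ndarray | int | None = None,
    max_k: int | None = None,
) -> SimilarityNetwork:
    """Full path from a cells x features matrix to the kernel network."""
    reduced = reduce_dimensions(feature_matrix, var_threshold)
    D = pairwise_euclidean(reduced)
    net = build_cell_similarity(D, per_node_k, node_ids)
    if max_k is not None and per_node_k is None:
        capped = np.minimum(net.per_node_k, max_k)
        if np.any(capped != net.per_node_k):
            net = build_knn_kernel(D, capped, node_ids)
    return net
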