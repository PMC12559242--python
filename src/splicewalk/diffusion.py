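"""Random walk with restart over similarity networks.

The kernel network is row-normalized into a transition matrix S̃.  Every
node's walk starts from its own transition row (V0 = S̃) and iterates
V <- (1-λ) V S̃ + λ V0, a convex combination of row-stochastic matrices, so
row sums are conserved exactly.  Convergence is declared when the relative
change Δ = SSE / SST between consecutive iterates drops below a tolerance;
SST is taken as the total sum of squares of the previous iterate around its
grand mean, matching the regression SSE/SST idiom.  After diffusion each row
is re-sparsified to the same top-k as the pre-diffusion network and
renormalized so products with PSI matrices stay convex combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cell_similarity import SimilarityNetwork

logger = logging.getLogger(__name__)


@dataclass
class DiffusionConfig:
    restart_lambda: float = 0.2
    tol: float = 0.05
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.restart_lambda <= 1:
            raise ValueError("restart_lambda must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


def row_normalize(network: SimilarityNetwork) -> SimilarityNetwork:
    """Row-stochastic transition matrix from a kernel network."""
    sums = network.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        ids = [network.node_ids[i] for i in zero]
        raise ValueError(f"isolated nodes with all-zero rows: {ids}")
    values = network.values / sums[:, None]
    return replace(network, values=values, state="transition")


def convergence_delta(current: np.ndarray, previous: np.ndarray) -> float:
    """Relative change Δ = SSE(current, previous) / SST(previous)."""
    cur = np.asarray(current, dtype=float)
    prev = np.asarray(previous, dtype=float)
    if cur.shape != prev.shape:
        raise ValueError("matrices must share a shape")
    sse = float(np.sum((cur - prev) ** 2))
    sst = float(np.sum((prev - prev.mean()) ** 2))
    if sst == 0.0:
        logger.warning("convergence_delta: constant previous matrix, SST = 0")
        return float("inf") if sse > 0 else 0.0
    return sse / sst


def rwr_diffuse(transition: SimilarityNetwork, config: DiffusionConfig | None = None) -> SimilarityNetwork:
    """Simultaneous random walk with restart for all nodes."""
    if transition.state != "transition":
        raise ValueError("rwr_diffuse expects a transition-state network")
    cfg = config or DiffusionConfig()
    S = transition.values
    V0 = S.copy()
    V = S.copy()
    lam = cfg.restart_lambda
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        V_next = (1 - lam) * (V @ S) + lam * V0
        # convexity of stochastic matrices conserves row sums
        row_sums = V_next.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise FloatingPointError("RWR iterate lost row-stochasticity")
        delta = convergence_delta(V_next, V)
        trace.append(delta)
        V = V_next
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("RWR did not converge within %d iterations (Δ=%.3g)",
                       cfg.max_iter, trace[-1])
    return replace(
        transition,
        values=V,
        state="diffused",
        converged=converged,
        iterations=iterations,
        delta_trace=trace,
    )


def sparsify_topk(diffused: SimilarityNetwork, per_node_k: np.ndarray | int | None = None) -> SimilarityNetwork:
    """Keep the k largest entries per row (diagonal included as a candidate),
    zero the rest, and renormalize rows to sum 1.

    ``per_node_k`` defaults to the network's own per-node k, i.e. the
    neighborhood sizes of the pre-diffusion kernel.  Ties at the k-th value
    are broken by node order for reproducibility.
    """
    V = diffused.values
    n = V.shape[0]
    k_vec = diffused.per_node_k if per_node_k is None else np.asarray(per_node_k, dtype=int)
    if k_vec.shape == ():
        k_vec = np.full(n, int(k_vec))
    out = np.zeros_like(V)
    for i in range(n):
        k = int(np.clip(k_vec[i], 1, n))
        order = np.lexsort((np.arange(n), -V[i]))  # by value desc, index asc
        keep = order[:k]
        out[i, keep] = V[i, keep]
        total = out[i].sum()
        if total == 0:
            out[i, i] = 1.0  # degenerate all-zero row: self-loop
        else:
            out[i] /= total
    return replace(diffused, values=out, per_node_k=k_vec)
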