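"""Three diffusion-based PSI imputation strategies.

Strategy 1 smooths the raw PSI matrix directly with the diffused cell
network.  Strategy 2 smooths the (library-normalized) inclusion and
exclusion junction count matrices with the cell network and recomputes PSI
from the imputed counts.  Strategy 3 takes the strategy-2 PSI and smooths it
across events with the diffused event network.  Each strategy iterates its
product to a fixed point, stopping when the SSE/SST change between
consecutive iterates falls below the same tolerance used for network
diffusion.  All three products are convex combinations (networks are
row-renormalized), so imputed PSI stays in [0, 1] and imputed counts stay
nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cell_similarity import SimilarityNetwork
from .diffusion import convergence_delta
from .events import CountMatrix, EventDefinition, PsiMatrix, compute_raw_psi

logger = logging.getLogger(__name__)


@dataclass
class ImputationResult:
    psi_strategy1: PsiMatrix
    psi_strategy2: PsiMatrix
    psi_strategy3: PsiMatrix
    rc_ijc_imputed: CountMatrix
    rc_ejc_imputed: CountMatrix
    iterations_used: dict[str, int]
    converged: dict[str, bool]


def _iterate_smoothing(
    matrix: np.ndarray,
    operator: np.ndarray,
    tol: float,
    max_iter: int,
    transpose: bool = False,
) -> tuple[np.ndarray, int, bool]:
    """Iterate X <- O @ X (or X <- X @ O.T when ``transpose``) to a fixed point."""
    X = matrix.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        X_next = X @ operator.T if transpose else operator @ X
        delta = convergence_delta(X_next, X)
        X = X_next
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("imputation iteration hit max_iter=%d without converging", max_iter)
    return X, iterations, converged


def _check_network(network: SimilarityNetwork, n: int, what: str) -> np.ndarray:
    if network.values.shape != (n, n):
        raise ValueError(f"{what} network shape {network.values.shape} mismatches {n}")
    sums = network.values.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError(f"{what} network rows must be renormalized to sum 1")
    return network.values


def impute_strategy1(
    psi_raw: PsiMatrix,
    cell_network_diffused: SimilarityNetwork,
    tol: float = 0.05,
    max_iter: int = 100,
) -> tuple[PsiMatrix, int, bool]:
    """Smooth raw PSI across similar cells."""
    S = _check_network(cell_network_diffused, len(psi_raw.cell_ids), "cell")
    values, iters, ok = _iterate_smoothing(psi_raw.values, S, tol, max_iter)
    out = PsiMatrix(np.clip(values, 0.0, 1.0), psi_raw.cell_ids, psi_raw.event_ids)
    return out, iters, ok


def impute_strategy2(
    rc_ijc: CountMatrix,
    rc_ejc: CountMatrix,
    cell_network_diffused: SimilarityNetwork,
    events: Sequence[EventDefinition],
    tol: float = 0.05,
    max_iter: int = 100,
) -> tuple[PsiMatrix, CountMatrix, CountMatrix, int, bool]:
    """Smooth junction counts across similar cells, then recompute PSI.

    Event-cell pairs whose entire neighborhood lacks reads keep the
    conventional PSI 0 and are flagged unsupported.
    """
    S = _check_network(cell_network_diffused, len(rc_ijc.cell_ids), "cell")
    vi, it_i, ok_i = _iterate_smoothing(rc_ijc.values, S, tol, max_iter)
    ve, it_e, ok_e = _iterate_smoothing(rc_ejc.values, S, tol, max_iter)
    imputed_i = CountMatrix(np.maximum(vi, 0.0), rc_ijc.cell_ids, rc_ijc.junction_ids,
                            normalized=rc_ijc.normalized)
    imputed_e = CountMatrix(np.maximum(ve, 0.0), rc_ejc.cell_ids, rc_ejc.junction_ids,
                            normalized=rc_ejc.normalized)
    psi = compute_raw_psi(imputed_i, imputed_e, events)
    return psi, imputed_i, imputed_e, max(it_i, it_e), ok_i and ok_e


def impute_strategy3(
    psi_from_strategy2: PsiMatrix,
    event_network_diffused: SimilarityNetwork,
    tol: float = 0.05,
    max_iter: int = 100,
) -> tuple[PsiMatrix, int, bool]:
    """Smooth the strategy-2 PSI across similar events (transpose product)."""
    S = _check_network(event_network_diffused, len(psi_from_strategy2.event_ids), "event")
    values, iters, ok = _iterate_smoothing(
        psi_from_strategy2.values, S, tol, max_iter, transpose=True
    )
    out = PsiMatrix(np.clip(values, 0.0, 1.0),
                    psi_from_strategy2.cell_ids, psi_from_strategy2.event_ids)
    return out, iters, ok


def impute_all(
    psi_raw: PsiMatrix,
    rc_ijc: CountMatrix,
    rc_ejc: CountMatrix,
    events: Sequence[EventDefinition],
    cell_network_diffused: SimilarityNetwork,
    event_network_diffused: SimilarityNetwork,
    tol: float = 0.05,
    max_iter: int = 100,
) -> ImputationResult:
    """Run all three strategies densely; the scenario combination picks per
    pair downstream."""
    s1, it1, ok1 = impute_strategy1(psi_raw, cell_network_diffused, tol, max_iter)
    s2, rci, rce, it2, ok2 = impute_strategy2(
        rc_ijc, rc_ejc, cell_network_diffused, events, tol, max_iter
    )
    s3, it3, ok3 = impute_strategy3(s2, event_network_diffused, tol, max_iter)
    return ImputationResult(
        psi_strategy1=s1,
        psi_strategy2=s2,
        psi_strategy3=s3,
        rc_ijc_imputed=rci,
        rc_ejc_imputed=rce,
        iterations_used={"strategy1": it1, "strategy2": it2, "strategy3": it3},
        converged={"strategy1": ok1, "strategy2": ok2, "strategy3": ok3},
    )
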