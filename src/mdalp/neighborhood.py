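"""Linear neighborhood similarity (LNS).

Each entity is reconstructed as a convex combination of its K nearest
neighbors (ranked by a base similarity matrix).  For entity ``i`` with
feature vector ``X_i`` (the i-th row of the base similarity), the weights
``w`` over the neighbor set solve the simplex-constrained quadratic
program

    minimize  w' (G_i + alpha I) w
    s.t.      sum(w) = 1,  w >= 0,

where ``G_i[j, k] = (X_i - X_{i_j}) . (X_i - X_{i_k})`` is the Gram
matrix of reconstruction residual directions and ``alpha`` is a Tikhonov
regularizer that makes the solution unique.  Stacking the solved rows
yields a row-stochastic, generally asymmetric neighbor-weight graph W
used for label propagation.

The QP is solved exactly by a small active-set method (KKT solves with
variable drop/re-add); scipy's SLSQP is kept as a fallback for the rare
degenerate Gram matrix at ``alpha = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .io import EntityIndex, MdalpError, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodConfig",
    "LNSGraph",
    "select_neighbors",
    "lns_weights",
    "build_lns_graph",
    "solve_simplex_qp",
]


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Neighborhood size and regularization settings.

    Exactly one of ``k_neighbors`` (absolute) or ``neighbor_fraction``
    (K = round(fraction * N), at least 1) determines the neighbor count;
    K is always capped at N - 1.
    """

    k_neighbors: int | None = None
    neighbor_fraction: float = 0.3
    alpha: float = 0.7
    qp_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.k_neighbors is not None and self.k_neighbors < 1:
            raise MdalpError("k_neighbors must be >= 1")
        if not 0 < self.neighbor_fraction <= 1:
            raise MdalpError("neighbor_fraction must be in (0, 1]")
        if self.alpha < 0:
            raise MdalpError("alpha must be nonnegative")
        if self.qp_tolerance <= 0:
            raise MdalpError("qp_tolerance must be positive")

    def effective_k(self, n: int) -> int:
        if n < 2:
            raise MdalpError("need at least 2 entities to build a neighborhood")
        if self.k_neighbors is not None:
            k = self.k_neighbors
        else:
            k = int(round(self.neighbor_fraction * n))
        return min(max(k, 1), n - 1)


@dataclass(frozen=True)
class LNSGraph:
    """Row-stochastic neighbor-weight matrix with zero diagonal."""

    index: EntityIndex
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        n = len(self.index)
        if W.shape != (n, n):
            raise MdalpError("LNS weight matrix shape does not match index")
        if W.min(initial=0.0) < 0:
            raise MdalpError("LNS weights must be nonnegative")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise MdalpError("LNS diagonal must be zero")
        if np.abs(W.sum(axis=1) - 1.0).max(initial=0.0) > 1e-6:
            raise MdalpError("LNS rows must sum to 1")
        object.__setattr__(self, "weights", W)


def select_neighbors(base: SimilarityMatrix | np.ndarray, i: int, K: int) -> np.ndarray:
    """Positions of the K most similar entities to ``i`` (self excluded).

    Ties in similarity break by ascending position index.
    """
    values = base.values if isinstance(base, SimilarityMatrix) else np.asarray(base)
    n = values.shape[0]
    if K < 1:
        raise MdalpError("K must be >= 1")
    if K > n - 1:
        raise MdalpError(f"K={K} exceeds the {n - 1} available neighbors")
    others = np.delete(np.arange(n), i)
    # lexsort: primary key = descending similarity, secondary = index
    order = np.lexsort((others, -values[i, others]))
    return others[order[:K]]


def solve_simplex_qp(M: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Minimize ``w' M w`` over the probability simplex, exactly.

    Active-set method: solve the equality-constrained KKT system on the
    free variables, drop the most negative variable when the solution
    leaves the simplex, and re-admit a bound variable whose multiplier
    violates dual feasibility.  Falls back to SLSQP if it fails to settle
    (possible only for singular M).
    """
    M = np.asarray(M, dtype=float)
    k = M.shape[0]
    if k == 1:
        return np.array([1.0])
    free = np.ones(k, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        nk = idx.size
        kkt = np.zeros((nk + 1, nk + 1))
        kkt[:nk, :nk] = 2.0 * M[np.ix_(idx, idx)]
        kkt[:nk, nk] = -1.0
        kkt[nk, :nk] = 1.0
        rhs = np.zeros(nk + 1)
        rhs[nk] = 1.0
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        w_free, lam = sol[:nk], sol[nk]
        if w_free.min() >= -tol:
            w = np.zeros(k)
            w[idx] = np.clip(w_free, 0.0, None)
            s = w.sum()
            if s <= 0:
                break
            w /= s
            grad = 2.0 * M @ w
            bound = np.flatnonzero(~free)
            if bound.size:
                viol = grad[bound] - lam
                worst = viol.argmin()
                if viol[worst] < -1e-9:
                    free[bound[worst]] = True
                    continue
            return w
        free[idx[w_free.argmin()]] = False
        if not free.any():
            break
    return _solve_simplex_qp_slsqp(M)


def _solve_simplex_qp_slsqp(M: np.ndarray) -> np.ndarray:
    k = M.shape[0]
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda w: float(w @ M @ w),
        x0,
        jac=lambda w: 2.0 * (M @ w),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success:
        raise MdalpError(f"QP solver failed to converge: {res.message}")
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def lns_weights(
    features: np.ndarray,
    i: int,
    neighbors: np.ndarray,
    alpha: float = 0.7,
    qp_tolerance: float = 1e-8,
) -> np.ndarray:
    """Optimal reconstruction weights of entity ``i`` over its neighbors.

    ``features`` holds one row per entity; ``X_i = features[i]``.  Returns
    a vector over ``neighbors`` on the probability simplex minimizing
    ``w' (G + alpha I) w``.
    """
    neighbors = np.asarray(neighbors, dtype=int)
    if neighbors.size < 1:
        raise MdalpError("need at least one neighbor")
    if neighbors.size == 1:
        return np.array([1.0])
    diffs = features[i][None, :] - features[neighbors]
    G = diffs @ diffs.T
    M = G + alpha * np.eye(neighbors.size)
    w = solve_simplex_qp(M)
    w[np.abs(w) < qp_tolerance] = 0.0
    s = w.sum()
    if s <= 0:
        raise MdalpError("QP produced a degenerate all-zero weight vector")
    return w / s


def build_lns_graph(
    base: SimilarityMatrix, config: NeighborhoodConfig | None = None
) -> LNSGraph:
    """Solve the per-row QPs and assemble the neighbor-weight graph W.

    ``W[i, j]`` is the reconstruction weight of neighbor ``j`` for entity
    ``i`` and 0 whenever ``j`` is not among ``i``'s K nearest neighbors;
    the diagonal is 0 and every row sums to 1.
    """
    config = config or NeighborhoodConfig()
    n = len(base.index)
    K = config.effective_k(n)
    features = base.values
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = select_neighbors(base, i, K)
        W[i, nbrs] = lns_weights(
            features, i, nbrs, alpha=config.alpha, qp_tolerance=config.qp_tolerance
        )
    return LNSGraph(base.index, W)
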