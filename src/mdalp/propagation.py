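"""Label propagation on neighbor graphs and score integration.

Labels (known associations) diffuse over the row-stochastic
neighbor-weight graph W: at each step a node blends its neighbors'
current scores at rate ``beta`` with its initial label at rate
``1 - beta``,

    Y(t+1) = beta * W @ Y(t) + (1 - beta) * Y0,

whose fixed point has the closed form

    Y* = (1 - beta) (I - beta W)^{-1} Y0.

The closed form is the production path (the graphs are small); the
iterative update is retained as a verification oracle.  ``side`` selects
whether W mixes microbes (rows of Y0) or diseases (columns).

Scores from models built on different similarity sources are combined by
a convex (simplex-weighted) sum; the weights can be fixed, uniform, or
fitted on a simplex grid by maximizing the AUC separating known
positives from selected reliable negatives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .io import MdalpError, ScoreMatrix
from .metrics import rank_auc
from .neighborhood import LNSGraph
from .negatives import ConvergenceError, NegativeSet

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "IntegrationWeights",
    "label_propagate",
    "integrate",
    "simplex_grid",
    "fit_integration_weights",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Diffusion rate and solver mode.

    ``beta`` is the neighbor-blending rate; ``beta < 1`` keeps
    ``I - beta W`` invertible for row-stochastic W.  Default 0.1 is the
    reported grid-search optimum.
    """

    beta: float = 0.1
    mode: str = "closed_form"
    iter_tolerance: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0 <= self.beta < 1:
            raise MdalpError("beta must lie in [0, 1)")
        if self.mode not in ("closed_form", "iterative"):
            raise MdalpError(f"unknown propagation mode {self.mode!r}")
        if self.iter_tolerance <= 0:
            raise MdalpError("iter_tolerance must be positive")
        if self.max_iter < 1:
            raise MdalpError("max_iter must be >= 1")


@dataclass(frozen=True)
class IntegrationWeights:
    """Simplex weights over the per-similarity models."""

    omega: tuple[float, ...]

    def __post_init__(self) -> None:
        om = tuple(float(x) for x in self.omega)
        if any(x < 0 for x in om):
            raise MdalpError("integration weights must be nonnegative")
        if abs(sum(om) - 1.0) > 1e-10:
            raise MdalpError("integration weights must sum to 1")
        object.__setattr__(self, "omega", om)

    def __len__(self) -> int:
        return len(self.omega)


def label_propagate(
    W: LNSGraph | np.ndarray,
    Y0: np.ndarray,
    config: PropagationConfig | None = None,
    side: str = "microbe",
) -> np.ndarray:
    """Propagate initial labels Y0 over graph W.

    ``side="microbe"``: W is n x n and mixes the rows of Y0 (each
    disease's column vector diffuses over the microbe graph).
    ``side="disease"``: W is m x m and mixes the columns.
    """
    config = config or PropagationConfig()
    Wm = W.weights if isinstance(W, LNSGraph) else np.asarray(W, dtype=float)
    Y0 = np.asarray(Y0, dtype=float)
    if side not in ("microbe", "disease"):
        raise MdalpError(f"unknown propagation side {side!r}")
    axis_len = Y0.shape[0] if side == "microbe" else Y0.shape[1]
    if Wm.shape != (axis_len, axis_len):
        raise MdalpError(
            f"graph shape {Wm.shape} incompatible with labels {Y0.shape} "
            f"on side {side!r}"
        )
    beta = config.beta
    if beta == 0.0:
        return Y0.copy()
    if config.mode == "closed_form":
        A = np.eye(axis_len) - beta * Wm
        try:
            if side == "microbe":
                return (1.0 - beta) * np.linalg.solve(A, Y0)
            return (1.0 - beta) * np.linalg.solve(A, Y0.T).T
        except np.linalg.LinAlgError as exc:
            raise MdalpError(f"I - beta*W numerically singular: {exc}") from exc
    Y = Y0.copy()
    for _ in range(config.max_iter):
        if side == "microbe":
            Y_next = beta * (Wm @ Y) + (1.0 - beta) * Y0
        else:
            Y_next = beta * (Y @ Wm.T) + (1.0 - beta) * Y0
        delta = np.abs(Y_next - Y).max()
        Y = Y_next
        if delta < config.iter_tolerance:
            return Y
    raise ConvergenceError(
        f"label propagation did not converge in {config.max_iter} iterations "
        f"(last max-abs change {delta:.3e})"
    )


def integrate(
    models: list[ScoreMatrix] | list[np.ndarray],
    weights: IntegrationWeights,
) -> np.ndarray:
    """Convex combination ``Z = sum_k omega_k * Y_k`` of model scores."""
    if len(models) != len(weights):
        raise MdalpError(
            f"{len(models)} models but {len(weights)} integration weights"
        )
    arrays = [
        m.values if isinstance(m, ScoreMatrix) else np.asarray(m, dtype=float)
        for m in models
    ]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise MdalpError("model score matrices differ in shape")
    Z = np.zeros(shape)
    for om, a in zip(weights.omega, arrays):
        Z += om * a
    return Z


def simplex_grid(S: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All weight vectors on the S-simplex with coordinates multiple of ``step``.

    Enumerated in lexicographic order of the coordinate tuple.
    """
    levels = int(round(1.0 / step))
    if abs(levels * step - 1.0) > 1e-9 or levels < 1:
        raise MdalpError("grid step must evenly divide 1")
    out = []
    for combo in itertools.product(range(levels + 1), repeat=S - 1):
        if sum(combo) <= levels:
            last = levels - sum(combo)
            out.append(tuple(c / levels for c in combo) + (last / levels,))
    # lexicographic over the full tuple
    out.sort()
    return out


def fit_integration_weights(
    models: list[ScoreMatrix] | list[np.ndarray],
    positives: np.ndarray,
    negatives: NegativeSet | np.ndarray,
    grid_step: float = 0.1,
) -> IntegrationWeights:
    """Pick simplex-grid weights maximizing positive/negative ranking AUC.

    Ties prefer the candidate closest to uniform weights, then the first
    in lexicographic grid order, so the all-models-tie case returns the
    canonical uninformed choice.  With no negatives available the
    fallback is uniform weights.
    """
    S = len(models)
    pos = np.asarray(positives, dtype=int).reshape(-1, 2)
    if pos.shape[0] == 0:
        raise MdalpError("cannot fit integration weights without positives")
    neg = negatives.pairs if isinstance(negatives, NegativeSet) else negatives
    neg = np.asarray(neg, dtype=int).reshape(-1, 2)
    uniform = IntegrationWeights(tuple(1.0 / S for _ in range(S)))
    if neg.shape[0] == 0:
        logger.info("no negatives supplied; using uniform integration weights")
        return uniform
    if {tuple(p) for p in pos} & {tuple(p) for p in neg}:
        raise MdalpError("positives and negatives must be disjoint")
    arrays = [
        m.values if isinstance(m, ScoreMatrix) else np.asarray(m, dtype=float)
        for m in models
    ]
    pos_feats = np.stack([a[pos[:, 0], pos[:, 1]] for a in arrays])
    neg_feats = np.stack([a[neg[:, 0], neg[:, 1]] for a in arrays])
    best = None
    aucs = []
    for omega in simplex_grid(S, grid_step):
        w = np.asarray(omega)
        auc = rank_auc(w @ pos_feats, w @ neg_feats)
        aucs.append(auc)
        dist = float(np.abs(w - 1.0 / S).sum())
        key = (-auc, dist, omega)
        if best is None or key < best[0]:
            best = (key, omega)
    if max(aucs) - min(aucs) < 1e-12:  # every candidate ties
        return uniform
    return IntegrationWeights(best[1])
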