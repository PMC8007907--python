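"""Reliable-negative selection by random walk with restart (RWR).

Known associations are positives; everything else is unlabeled.  To mine
"reliable negatives" from the unlabeled pairs (a positive-unlabeled
scheme), a walker is released on the heterogeneous microbe-disease
network -- the block matrix

    [[S_M, Y ],
     [Y',  S_D]]

column-normalized into a transition matrix -- restarting with probability
``r`` at each disease node plus its known microbes.  The stationary mass
an unlabeled microbe receives is that pair's affinity estimate; the
lowest-scoring unlabeled pairs are the negatives least likely to be
missing positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, MdalpError, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NegativeSelectionConfig",
    "NegativeSet",
    "ConvergenceError",
    "build_heterogeneous_network",
    "rwr_scores",
    "select_negatives",
]


class ConvergenceError(MdalpError):
    """Iterative solver exhausted its iteration budget."""


@dataclass(frozen=True)
class NegativeSelectionConfig:
    restart_prob: float = 0.5
    rwr_tolerance: float = 1e-10
    max_iter: int = 1000
    n_negatives: int | str = "match_positives"

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob < 1:
            raise MdalpError("restart_prob must be strictly inside (0, 1)")
        if self.rwr_tolerance <= 0:
            raise MdalpError("rwr_tolerance must be positive")
        if self.max_iter < 1:
            raise MdalpError("max_iter must be >= 1")
        if isinstance(self.n_negatives, str):
            if self.n_negatives != "match_positives":
                raise MdalpError(
                    "n_negatives must be a positive integer or 'match_positives'"
                )
        elif self.n_negatives < 1:
            raise MdalpError("n_negatives must be >= 1")


@dataclass(frozen=True)
class NegativeSet:
    """Selected negative pairs, ascending by RWR score."""

    pairs: np.ndarray  # (k, 2) microbe/disease positions
    scores: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        scores = np.asarray(self.scores, dtype=float)
        if pairs.shape[0] != scores.shape[0]:
            raise MdalpError("pairs and scores length mismatch")
        if scores.size > 1 and np.any(np.diff(scores) < 0):
            raise MdalpError("negative set must be sorted ascending by score")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.pairs.shape[0]


def build_heterogeneous_network(
    Y: AssociationMatrix, S_M: SimilarityMatrix, S_D: SimilarityMatrix
) -> np.ndarray:
    """Column-stochastic transition matrix over the n + m node network.

    Similarity blocks get a zero diagonal (no self-loops); columns whose
    total weight is zero (isolated nodes) stay all-zero with a warning.
    """
    n, m = Y.values.shape
    if S_M.values.shape != (n, n) or S_D.values.shape != (m, m):
        raise MdalpError("similarity shapes do not match association matrix")
    A = np.zeros((n + m, n + m))
    A[:n, :n] = S_M.values
    A[n:, n:] = S_D.values
    np.fill_diagonal(A, 0.0)
    A[:n, n:] = Y.values
    A[n:, :n] = Y.values.T
    colsum = A.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("%d isolated node(s) in heterogeneous network", int(zero.sum()))
    T = np.divide(A, np.where(zero, 1.0, colsum)[None, :])
    return T


def rwr_scores(
    transition: np.ndarray,
    seeds: np.ndarray | list[int],
    config: NegativeSelectionConfig | None = None,
) -> np.ndarray:
    """Stationary distribution of a restarting walk, by power iteration.

    Solves ``p = r e + (1 - r) T p`` with ``e`` uniform over the seed
    nodes, iterating until the L1 change drops below ``rwr_tolerance``.
    """
    config = config or NegativeSelectionConfig()
    T = np.asarray(transition, dtype=float)
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise MdalpError("seed set must be nonempty")
    r = config.restart_prob
    e = np.zeros(T.shape[0])
    e[seeds] = 1.0 / seeds.size
    p = e.copy()
    for it in range(config.max_iter):
        p_next = r * e + (1.0 - r) * (T @ p)
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < config.rwr_tolerance:
            return p
    raise ConvergenceError(
        f"RWR did not converge in {config.max_iter} iterations "
        f"(last L1 change {delta:.3e})"
    )


def select_negatives(
    Y: AssociationMatrix,
    S_M: SimilarityMatrix,
    S_D: SimilarityMatrix,
    config: NegativeSelectionConfig | None = None,
) -> NegativeSet:
    """Pick the unlabeled pairs least supported by the restarting walk.

    For each disease, the walk is seeded at the disease node together with
    its known microbes; pair (i, j) is scored by the stationary mass on
    microbe node i.  The ``n_negatives`` lowest-scoring unlabeled pairs
    are returned (``"match_positives"`` selects as many negatives as
    there are known positives), ties broken by (i, j) index order.
    """
    config = config or NegativeSelectionConfig()
    n, m = Y.values.shape
    if Y.n_positives < 1:
        raise MdalpError("need at least one known positive association")
    T = build_heterogeneous_network(Y, S_M, S_D)
    score = np.zeros((n, m))
    for j in range(m):
        microbes = np.flatnonzero(Y.values[:, j] == 1.0)
        seeds = np.concatenate([microbes, [n + j]])
        p = rwr_scores(T, seeds, config)
        score[:, j] = p[:n]
    unlabeled = Y.unlabeled_pairs()
    if unlabeled.shape[0] == 0:
        raise MdalpError("no unlabeled pairs to select negatives from")
    want = (
        Y.n_positives
        if config.n_negatives == "match_positives"
        else int(config.n_negatives)
    )
    if want > unlabeled.shape[0]:
        logger.warning(
            "requested %d negatives but only %d unlabeled pairs; clamping",
            want,
            unlabeled.shape[0],
        )
        want = unlabeled.shape[0]
    s = score[unlabeled[:, 0], unlabeled[:, 1]]
    order = np.lexsort((unlabeled[:, 1], unlabeled[:, 0], s))[:want]
    return NegativeSet(unlabeled[order], s[order])
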