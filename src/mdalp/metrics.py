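"""Classification metrics for ranked association predictions.

AUC is the Mann-Whitney rank statistic (probability that a random test
positive outranks a random test negative, ties counted half), computed
with tied-rank averaging.  The threshold for the contingency-table
metrics is prevalence matching: the top-q scored test pairs are declared
positive, where q is the number of test positives -- a parameter-free
deterministic rule; AUC remains the headline, threshold-free metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import MdalpError, ScoreMatrix

__all__ = ["MetricsReport", "rank_auc", "compute_metrics"]


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC of positives vs negatives with tie averaging."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0:
        raise MdalpError("AUC undefined: empty positive set")
    if neg.size == 0:
        raise MdalpError("AUC undefined: empty negative set")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class MetricsReport:
    """Contingency counts plus derived metrics for one evaluation set."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    per_fold: object = field(default=None, compare=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        if total < 1:
            raise MdalpError("empty evaluation set")
        checks = {
            "sensitivity": self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0,
            "specificity": self.tn / (self.fp + self.tn) if self.fp + self.tn else 0.0,
            "accuracy": (self.tp + self.tn) / total,
        }
        for name, expect in checks.items():
            if abs(getattr(self, name) - expect) > 1e-12:
                raise MdalpError(f"{name} inconsistent with counts")


def _pair_scores(scores: ScoreMatrix | np.ndarray, pairs: np.ndarray) -> np.ndarray:
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return values[pairs[:, 0], pairs[:, 1]]


def compute_metrics(
    scores: ScoreMatrix | np.ndarray,
    test_positives: np.ndarray,
    test_negatives: np.ndarray,
    threshold_rule: str = "prevalence",
) -> MetricsReport:
    """Score the ranking of test positives against test negatives.

    ``test_positives`` / ``test_negatives`` are (k, 2) arrays of
    (microbe position, disease position); the two sets must be disjoint.
    """
    tp_pairs = np.asarray(test_positives, dtype=int).reshape(-1, 2)
    tn_pairs = np.asarray(test_negatives, dtype=int).reshape(-1, 2)
    if tp_pairs.shape[0] == 0:
        raise MdalpError("test positive set must be nonempty")
    joint = {tuple(p) for p in tp_pairs} & {tuple(p) for p in tn_pairs}
    if joint:
        raise MdalpError("test positive and negative sets overlap")
    if threshold_rule != "prevalence":
        raise MdalpError(f"unknown threshold rule {threshold_rule!r}")

    pos = _pair_scores(scores, tp_pairs)
    neg = _pair_scores(scores, tn_pairs)
    auc = rank_auc(pos, neg)

    q = pos.size
    all_pairs = np.vstack([tp_pairs, tn_pairs])
    all_scores = np.concatenate([pos, neg])
    is_pos = np.zeros(all_scores.size, dtype=bool)
    is_pos[:q] = True
    # deterministic: descending score, ties by (microbe, disease) position
    order = np.lexsort((all_pairs[:, 1], all_pairs[:, 0], -all_scores))
    predicted_pos = order[:q]
    tp = int(is_pos[predicted_pos].sum())
    fp = q - tp
    fn = q - tp
    tn = neg.size - fp
    total = q + neg.size
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / q,
        specificity=tn / (fp + tn) if fp + tn else 0.0,
        accuracy=(tp + tn) / total,
        auc=auc,
    )
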