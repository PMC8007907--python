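"""Cross-validation schemes, repeated-trial averaging, and grid search.

Three masking schemes probe different prediction settings:

* CV1 masks whole microbe rows (new-microbe prediction);
* CV2 masks whole disease columns (new-disease prediction);
* CV3 masks individual positive entries (new-pair prediction).

In every scheme the training matrix zeroes the masked units; test
positives are the masked known associations.  Test negatives follow the
all-unlabeled convention: under CV3 every unlabeled pair is a test
negative; under CV1/CV2 the unlabeled pairs within the masked
rows/columns are (``negatives="global"`` switches to all unlabeled
pairs).  Trial t of a repeated run uses seed + t, so the averaged report
is reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AssociationMatrix, MdalpError, SymptomTable, SimilarityMatrix
from .metrics import MetricsReport, compute_metrics
from .model import MDAModel, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["CVPlan", "Fold", "CVResult", "make_folds", "run_cv", "grid_search"]

SCHEMES = ("CV1", "CV2", "CV3")


@dataclass(frozen=True)
class CVPlan:
    scheme: str
    n_folds: int = 5
    n_trials: int = 100
    seed: int = 0
    #: "within_mask" (CV1/CV2 negatives restricted to masked units) or "global"
    negatives: str = "within_mask"

    def __post_init__(self) -> None:
        if self.scheme.upper() not in SCHEMES:
            raise MdalpError(f"scheme must be one of {SCHEMES}")
        object.__setattr__(self, "scheme", self.scheme.upper())
        if self.n_folds < 2:
            raise MdalpError("n_folds must be >= 2")
        if self.n_trials < 1:
            raise MdalpError("n_trials must be >= 1")
        if self.negatives not in ("within_mask", "global"):
            raise MdalpError("negatives must be 'within_mask' or 'global'")


@dataclass(frozen=True)
class Fold:
    """One train/test split: zeroed training matrix plus test pair sets."""

    train_values: np.ndarray
    test_positives: np.ndarray
    test_negatives: np.ndarray
    masked: np.ndarray  # rows (CV1), columns (CV2) or positive pairs (CV3)


def make_folds(
    Y: AssociationMatrix, plan: CVPlan, seed: int | None = None
) -> list[Fold]:
    """Partition Y into ``plan.n_folds`` train/test splits for one trial."""
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    n, m = Y.values.shape
    scheme = plan.scheme
    folds: list[Fold] = []
    if scheme in ("CV1", "CV2"):
        axis_len = n if scheme == "CV1" else m
        if axis_len < plan.n_folds:
            raise MdalpError(
                f"{scheme} needs at least {plan.n_folds} "
                f"{'rows' if scheme == 'CV1' else 'columns'}"
            )
        perm = rng.permutation(axis_len)
        for chunk in np.array_split(perm, plan.n_folds):
            chunk = np.sort(chunk)
            train = Y.values.copy()
            if scheme == "CV1":
                train[chunk, :] = 0.0
                inmask = np.zeros((n, m), dtype=bool)
                inmask[chunk, :] = True
            else:
                train[:, chunk] = 0.0
                inmask = np.zeros((n, m), dtype=bool)
                inmask[:, chunk] = True
            pos = np.argwhere((Y.values == 1.0) & inmask)
            if plan.negatives == "within_mask":
                neg = np.argwhere((Y.values == 0.0) & inmask)
            else:
                neg = Y.unlabeled_pairs()
            folds.append(Fold(train, pos, neg, chunk))
    else:  # CV3
        positives = Y.positive_pairs()
        if positives.shape[0] < plan.n_folds:
            raise MdalpError(f"CV3 needs at least {plan.n_folds} positives")
        perm = rng.permutation(positives.shape[0])
        neg = Y.unlabeled_pairs()
        for chunk in np.array_split(perm, plan.n_folds):
            pos = positives[np.sort(chunk)]
            train = Y.values.copy()
            train[pos[:, 0], pos[:, 1]] = 0.0
            folds.append(Fold(train, pos, neg, pos))
    return folds


@dataclass(frozen=True)
class CVResult:
    """Averaged metrics plus the per-(trial, fold) table."""

    plan: CVPlan
    mean: MetricsReport
    table: pd.DataFrame = field(compare=False)
    std_auc: float = 0.0
    n_fits: int = 0

    @property
    def mean_auc(self) -> float:
        return self.mean.auc

    def summary(self) -> str:
        se = self.std_auc / max(np.sqrt(len(self.table)), 1.0)
        return (
            f"{self.plan.scheme}: {self.plan.n_trials} trial(s) x "
            f"{self.plan.n_folds}-fold\n"
            f"  AUC          {self.mean.auc:.4f} (sd {self.std_auc:.4f}, "
            f"se {se:.4f})\n"
            f"  sensitivity  {self.mean.sensitivity:.4f}\n"
            f"  specificity  {self.mean.specificity:.4f}\n"
            f"  accuracy     {self.mean.accuracy:.4f}"
        )


def _fit_and_score(
    Y: AssociationMatrix,
    fold: Fold,
    symptoms: SymptomTable | None,
    symptom_sim: SimilarityMatrix | None,
    config: PipelineConfig,
) -> MetricsReport:
    train = Y.with_values(fold.train_values)
    # leakage guard: masked test positives must be absent from training data
    if train.values[fold.test_positives[:, 0], fold.test_positives[:, 1]].any():
        raise MdalpError("test positives leaked into the training matrix")
    res = MDAModel(
        train, symptoms=symptoms, symptom_sim=symptom_sim, config=config
    ).fit()
    return compute_metrics(res.scores, fold.test_positives, fold.test_negatives)


def run_cv(
    Y: AssociationMatrix,
    plan: CVPlan,
    symptoms: SymptomTable | None = None,
    symptom_sim: SimilarityMatrix | None = None,
    config: PipelineConfig | None = None,
) -> CVResult:
    """Repeated cross-validation of the full pipeline.

    Each trial draws fresh folds (seed + trial index), refits the
    pipeline on every training matrix and evaluates on the fold's test
    sets; metrics are averaged over all trials and folds.
    """
    config = config or PipelineConfig()
    records = []
    counts = np.zeros(4)
    n_fits = 0
    for trial in range(plan.n_trials):
        folds = make_folds(Y, plan, seed=plan.seed + trial)
        for k, fold in enumerate(folds):
            if fold.test_positives.shape[0] == 0:
                logger.warning("trial %d fold %d has no test positives; skipped",
                               trial, k)
                continue
            rep = _fit_and_score(Y, fold, symptoms, symptom_sim, config)
            n_fits += 1
            counts += (rep.tp, rep.fp, rep.tn, rep.fn)
            records.append(
                {
                    "trial": trial,
                    "fold": k,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                    "auc": rep.auc,
                }
            )
    if not records:
        raise MdalpError("cross-validation produced no evaluable folds")
    table = pd.DataFrame.from_records(records)
    tp, fp, tn, fn = (int(round(c)) for c in counts)
    mean = MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (fp + tn) if fp + tn else 0.0,
        accuracy=(tp + tn) / (tp + fp + tn + fn),
        per_fold=table,
    auc=float(table["auc"].mean()),
    )
    return CVResult(
        plan=plan,
        mean=mean,
        table=table,
        std_auc=float(table["auc"].std(ddof=1)) if len(table) > 1 else 0.0,
        n_fits=n_fits,
    )


_GRID_KEYS = {
    "gamma_m_prime",
    "gamma_d_prime",
    "gamma",
    "alpha",
    "beta",
    "k_neighbors",
    "neighbor_fraction",
}


def _apply_params(config: PipelineConfig, params: dict) -> PipelineConfig:
    sim = config.similarity
    nbr = config.neighborhood
    prop = config.propagation
    if "gamma_m_prime" in params:
        sim = replace(sim, gamma_m_prime=params["gamma_m_prime"])
    if "gamma_d_prime" in params:
        sim = replace(sim, gamma_d_prime=params["gamma_d_prime"])
    if "gamma" in params:
        sim = replace(sim, gamma=params["gamma"])
    if "alpha" in params:
        nbr = replace(nbr, alpha=params["alpha"])
    if "k_neighbors" in params:
        nbr = replace(nbr, k_neighbors=params["k_neighbors"])
    if "neighbor_fraction" in params:
        nbr = replace(nbr, neighbor_fraction=params["neighbor_fraction"],
                      k_neighbors=None)
    if "beta" in params:
        prop = replace(prop, beta=params["beta"])
    return replace(config, similarity=sim, neighborhood=nbr, propagation=prop)


def grid_search(
    Y: AssociationMatrix,
    grids: dict[str, list],
    plan: CVPlan,
    symptoms: SymptomTable | None = None,
    symptom_sim: SimilarityMatrix | None = None,
    config: PipelineConfig | None = None,
) -> tuple[PipelineConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search by mean cross-validated AUC.

    Returns the best configuration (first in iteration order on ties) and
    the full table of evaluated combinations.
    """
    config = config or PipelineConfig()
    unknown = set(grids) - _GRID_KEYS
    if unknown:
        raise MdalpError(f"unknown grid parameter(s): {sorted(unknown)}")
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise MdalpError("grids must be nonempty")
    keys = list(grids)
    rows = []
    best: tuple[float, int, PipelineConfig] | None = None
    for rank, combo in enumerate(itertools.product(*(grids[k] for k in keys))):
        params = dict(zip(keys, combo))
        candidate = _apply_params(config, params)
        result = run_cv(Y, plan, symptoms=symptoms, symptom_sim=symptom_sim,
                        config=candidate)
        rows.append({**params, "mean_auc": result.mean_auc,
                     "std_auc": result.std_auc})
        if best is None or result.mean_auc > best[0]:
            best = (result.mean_auc, rank, candidate)
    return best[2], pd.DataFrame.from_records(rows)
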