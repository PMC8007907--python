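"""The microbe-disease association predictor, statsmodels-style.

:class:`MDAModel` is constructed from a binary association matrix plus
optional disease symptom data; :meth:`MDAModel.fit` runs the pipeline and
returns an :class:`MDAResults` carrying the integrated score matrix, the
per-similarity model scores, the fitted or default integration weights,
and the selected reliable negatives.

Pipeline (one ``fit``):

1. similarities -- microbe GAP kernel ``S_M``, disease GAP kernel
   ``S_G``, disease symptom cosine ``S_s`` (from a symptom table or a
   precomputed matrix), and the combined ``S_D = S_G + gamma * S_s``;
2. neighbor graphs -- one linear-neighborhood (LNS) graph per
   similarity;
3. reliable negatives -- random walk with restart on the heterogeneous
   network built from ``S_M`` and ``S_D``;
4. three label-propagation models -- microbe-side diffusion on
   LNS(S_M), disease-side diffusion on LNS(S_G) and on LNS(S_s);
5. integration -- convex combination of the three score matrices
   (uniform by default, or grid-fitted against the selected negatives).

When no symptom information is given, the third model falls back to the
combined disease similarity, which then equals ``S_G`` -- effectively a
two-source model (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    AssociationMatrix,
    MdalpError,
    ScoreMatrix,
    SimilarityMatrix,
    SymptomTable,
    load_associations,
    load_similarity,
    load_symptom_table,
)
from .negatives import NegativeSelectionConfig, NegativeSet, select_negatives
from .neighborhood import LNSGraph, NeighborhoodConfig, build_lns_graph
from .propagation import (
    IntegrationWeights,
    PropagationConfig,
    fit_integration_weights,
    integrate,
    label_propagate,
)
from .similarity import (
    SimilarityConfig,
    combine_disease_similarity,
    gap_similarity,
    symptom_similarity,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "MDAModel", "MDAResults", "predict_associations"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline hyperparameters with the reported grid-search optimum
    as defaults (gamma_m' = gamma_d' = 1, gamma = 0.7, alpha = 0.7,
    beta = 0.1)."""

    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    negatives: NegativeSelectionConfig = field(
        default_factory=NegativeSelectionConfig
    )
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    #: "uniform", "fit", or explicit IntegrationWeights
    integration: str | IntegrationWeights = "uniform"
    #: drive the third model with the combined S_D instead of S_s
    model3_source: str = "symptom"
    #: run negative selection even when weights are not fitted
    select_negatives: bool = True
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if isinstance(self.integration, str):
            if self.integration not in ("uniform", "fit"):
                raise MdalpError(
                    "integration must be 'uniform', 'fit', or explicit weights"
                )
        if self.model3_source not in ("symptom", "combined"):
            raise MdalpError("model3_source must be 'symptom' or 'combined'")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from flat config keys (YAML/CLI style)."""
        sim = SimilarityConfig(
            gamma_m_prime=float(raw.get("gamma_m_prime", 1.0)),
            gamma_d_prime=float(raw.get("gamma_d_prime", 1.0)),
            gamma=float(raw.get("gamma", 0.7)),
        )
        nbr_kwargs = {}
        if "k_neighbors" in raw and raw["k_neighbors"] is not None:
            nbr_kwargs["k_neighbors"] = int(raw["k_neighbors"])
        if "neighbor_fraction" in raw and raw["neighbor_fraction"] is not None:
            nbr_kwargs["neighbor_fraction"] = float(raw["neighbor_fraction"])
        nbr = NeighborhoodConfig(alpha=float(raw.get("alpha", 0.7)), **nbr_kwargs)
        neg = NegativeSelectionConfig(
            restart_prob=float(raw.get("restart_prob", 0.5)),
            n_negatives=raw.get("n_negatives", "match_positives"),
        )
        prop = PropagationConfig(beta=float(raw.get("beta", 0.1)))
        integration = raw.get("integration", "uniform")
        if isinstance(integration, (list, tuple)):
            integration = IntegrationWeights(tuple(float(x) for x in integration))
        return cls(
            similarity=sim,
            neighborhood=nbr,
            negatives=neg,
            propagation=prop,
            integration=integration,
            model3_source=raw.get("model3_source", "symptom"),
            select_negatives=bool(raw.get("select_negatives", True)),
            grid_step=float(raw.get("grid_step", 0.1)),
        )


class MDAModel:
    """Bipartite link predictor over a binary association matrix.

    Parameters
    ----------
    associations
        Binary microbe x disease matrix; must contain at least one 1.
    symptoms
        Optional disease x symptom weight table (aligned by disease ID).
    symptom_sim
        Optional precomputed disease symptom-similarity matrix; takes
        precedence over ``symptoms``.
    config
        Pipeline hyperparameters (defaults = reported optimum).
    """

    #: total fits executed in this process (bookkeeping for CV tests)
    n_fits_total = 0

    def __init__(
        self,
        associations: AssociationMatrix,
        symptoms: SymptomTable | None = None,
        symptom_sim: SimilarityMatrix | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        if associations.n_positives < 1:
            raise MdalpError("association matrix has no positive entries")
        self.associations = associations
        self.config = config or PipelineConfig()
        self.symptoms = symptoms
        if symptom_sim is not None:
            if symptom_sim.index.ids != associations.diseases.ids:
                # align by ID; missing diseases get zero similarity
                aligned = np.zeros((associations.n_diseases,) * 2)
                src = symptom_sim.index
                for a, da in enumerate(associations.diseases.ids):
                    if da not in src:
                        continue
                    for b, db in enumerate(associations.diseases.ids):
                        if db in src:
                            aligned[a, b] = symptom_sim.values[src[da], src[db]]
                symptom_sim = SimilarityMatrix(
                    associations.diseases, aligned, "disease_symptom"
                )
            self.symptom_sim = symptom_sim
        elif symptoms is not None:
            weights = symptoms.aligned_to(associations.diseases)
            self.symptom_sim = symptom_similarity(
                SymptomTable(associations.diseases, symptoms.symptoms, weights)
            )
        else:
            self.symptom_sim = None

    @classmethod
    def from_files(
        cls,
        associations_path: str,
        association_format: str = "edge_list",
        symptoms_path: str | None = None,
        symptom_sim_path: str | None = None,
        config: PipelineConfig | None = None,
    ) -> "MDAModel":
        assoc = load_associations(associations_path, format=association_format)
        symptoms = load_symptom_table(symptoms_path) if symptoms_path else None
        sym_sim = (
            load_similarity(symptom_sim_path, "disease_symptom")
            if symptom_sim_path
            else None
        )
        return cls(assoc, symptoms=symptoms, symptom_sim=sym_sim, config=config)

    # -- pipeline stages -------------------------------------------------

    def _similarities(self) -> dict[str, SimilarityMatrix]:
        cfg = self.config.similarity
        Y = self.associations
        S_M = gap_similarity(
            Y.values, cfg.gamma_m_prime, index=Y.microbes, role="microbe_gap"
        )
        S_G = gap_similarity(
            Y.values.T, cfg.gamma_d_prime, index=Y.diseases, role="disease_gap"
        )
        if self.symptom_sim is not None:
            S_s = self.symptom_sim
        else:
            logger.info(
                "no symptom information; third model falls back to the "
                "combined disease similarity (effectively two sources)"
            )
            S_s = SimilarityMatrix(
                Y.diseases,
                np.zeros((Y.n_diseases, Y.n_diseases)),
                "disease_symptom",
            )
        S_D = combine_disease_similarity(S_G, S_s, cfg.gamma)
        return {"S_M": S_M, "S_G": S_G, "S_s": S_s, "S_D": S_D}

    def fit(self) -> "MDAResults":
        """Run the full pipeline and return results."""
        cfg = self.config
        Y = self.associations
        sims = self._similarities()
        graphs: dict[str, LNSGraph] = {
            "microbe": build_lns_graph(sims["S_M"], cfg.neighborhood),
            "disease_gap": build_lns_graph(sims["S_G"], cfg.neighborhood),
        }
        use_symptom = (
            cfg.model3_source == "symptom"
            and self.symptom_sim is not None
            and sims["S_s"].values.any()
        )
        third_sim = sims["S_s"] if use_symptom else sims["S_D"]
        graphs["disease_third"] = build_lns_graph(third_sim, cfg.neighborhood)

        negatives: NegativeSet | None = None
        if cfg.select_negatives or cfg.integration == "fit":
            negatives = select_negatives(
                Y, sims["S_M"], sims["S_D"], cfg.negatives
            )

        # negatives are clamped to label 0 -- a no-op on unlabeled entries,
        # made explicit here
        Y0 = Y.values.copy()
        if negatives is not None and len(negatives):
            Y0[negatives.pairs[:, 0], negatives.pairs[:, 1]] = 0.0

        prop = cfg.propagation
        model_values = [
            label_propagate(graphs["microbe"], Y0, prop, side="microbe"),
            label_propagate(graphs["disease_gap"], Y0, prop, side="disease"),
            label_propagate(graphs["disease_third"], Y0, prop, side="disease"),
        ]
        model_names = ("microbe_gap", "disease_gap",
                       "disease_symptom" if use_symptom else "disease_combined")

        if isinstance(cfg.integration, IntegrationWeights):
            weights = cfg.integration
        elif cfg.integration == "fit":
            weights = fit_integration_weights(
                model_values, Y.positive_pairs(), negatives, cfg.grid_step
            )
        else:
            weights = IntegrationWeights((1 / 3, 1 / 3, 1 / 3))
        Z = integrate(model_values, weights)

        MDAModel.n_fits_total += 1
        return MDAResults(
            model=self,
            scores=ScoreMatrix(Y.microbes, Y.diseases, Z, provenance="integrated"),
            model_scores={
                name: ScoreMatrix(Y.microbes, Y.diseases, vals, provenance=name)
                for name, vals in zip(model_names, model_values)
            },
            weights=weights,
            negatives=negatives,
            similarities=sims,
            graphs=graphs,
        )


@dataclass(frozen=True)
class MDAResults:
    """Fitted scores and pipeline artifacts."""

    model: MDAModel
    scores: ScoreMatrix
    model_scores: dict[str, ScoreMatrix]
    weights: IntegrationWeights
    negatives: NegativeSet | None
    similarities: dict[str, SimilarityMatrix]
    graphs: dict[str, LNSGraph]

    def top_pairs(self, k: int = 10, novel_only: bool = True) -> list[tuple]:
        """Highest-scoring (microbe_id, disease_id, score) triples."""
        Y = self.model.associations
        mids, dids = Y.microbes.ids, Y.diseases.ids
        pairs = []
        for i in range(len(mids)):
            for j in range(len(dids)):
                if novel_only and Y.values[i, j] == 1.0:
                    continue
                pairs.append((mids[i], dids[j], float(self.scores.values[i, j])))
        pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
        return pairs[:k]

    def summary(self) -> str:
        """Human-readable fit summary."""
        Y = self.model.associations
        cfg = self.model.config
        lines = [
            "Microbe-Disease Association Model Results",
            "=" * 45,
            f"microbes:            {Y.n_microbes}",
            f"diseases:            {Y.n_diseases}",
            f"known associations:  {Y.n_positives}",
            f"density:             {Y.n_positives / Y.values.size:.4f}",
            f"gamma_m', gamma_d':  {cfg.similarity.gamma_m_prime}, "
            f"{cfg.similarity.gamma_d_prime}",
            f"gamma (symptom mix): {cfg.similarity.gamma}",
            f"alpha (LNS ridge):   {cfg.neighborhood.alpha}",
            f"beta (diffusion):    {cfg.propagation.beta}",
            f"models integrated:   {', '.join(self.model_scores)}",
            "integration weights: "
            + ", ".join(f"{w:.4f}" for w in self.weights.omega),
        ]
        if self.negatives is not None:
            lines.append(f"selected negatives:  {len(self.negatives)}")
        lines.append("-" * 45)
        lines.append("top novel predictions (microbe, disease, score):")
        for mid, did, s in self.top_pairs(5):
            lines.append(f"  {mid:<16} {did:<12} {s:.4f}")
        return "\n".join(lines)


def predict_associations(
    associations: AssociationMatrix,
    symptoms: SymptomTable | None = None,
    symptom_sim: SimilarityMatrix | None = None,
    config: PipelineConfig | None = None,
) -> ScoreMatrix:
    """One-call convenience wrapper: fit the pipeline, return scores."""
    return MDAModel(
        associations, symptoms=symptoms, symptom_sim=symptom_sim, config=config
    ).fit().scores
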