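"""Entity-entity similarity measures.

Three similarities feed the predictor:

* microbe GAP similarity -- a Gaussian (RBF) kernel on the rows of the
  association matrix, with bandwidth normalized by the mean squared
  profile norm: ``S(i, j) = exp(-gamma * ||A(i) - A(j)||^2)`` with
  ``gamma = gamma' / mean_k ||A(k)||^2``;
* disease GAP similarity -- the same kernel on the columns;
* disease symptom similarity -- cosine similarity of (optionally
  TF-IDF-weighted) disease-symptom vectors, the construction used for the
  human symptoms-disease network.

The combined disease similarity is ``S_D = S_G + gamma * S_s`` where
``gamma`` weighs the symptom contribution against the profile kernel.
``S_D`` is deliberately left unnormalized (entries may exceed 1); the
downstream neighborhood step re-derives weights, so the scale is
immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import EntityIndex, MdalpError, SimilarityMatrix, SymptomTable

__all__ = [
    "SimilarityConfig",
    "DegenerateBandwidthError",
    "gap_similarity",
    "symptom_similarity",
    "combine_disease_similarity",
]


class DegenerateBandwidthError(MdalpError):
    """All profiles are zero, so the normalized kernel bandwidth is undefined."""


@dataclass(frozen=True)
class SimilarityConfig:
    """Kernel and combination hyperparameters.

    ``gamma_m_prime`` / ``gamma_d_prime`` scale the microbe / disease GAP
    kernel bandwidths; ``gamma`` weighs symptom similarity in the combined
    disease similarity.  Defaults are the grid-search optimum reported for
    the HMDAD benchmark.
    """

    gamma_m_prime: float = 1.0
    gamma_d_prime: float = 1.0
    gamma: float = 0.7

    def __post_init__(self) -> None:
        for name in ("gamma_m_prime", "gamma_d_prime"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise MdalpError(f"{name} must be a positive finite real")
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise MdalpError("gamma must be a nonnegative finite real")


def gap_similarity(
    profiles: np.ndarray,
    gamma_prime: float = 1.0,
    index: EntityIndex | None = None,
    role: str = "microbe_gap",
) -> SimilarityMatrix:
    """Gaussian association-profile kernel over row profiles.

    Parameters
    ----------
    profiles
        (N, d) matrix; row k is entity k's binary association profile.
    gamma_prime
        Bandwidth scale; effective bandwidth is
        ``gamma_prime / mean_k ||profiles[k]||^2``.

    Raises
    ------
    DegenerateBandwidthError
        If every profile is all-zero (the bandwidth normalizer vanishes).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise MdalpError("profiles must be a nonempty 2-D matrix")
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateBandwidthError(
            "degenerate bandwidth: all profiles are zero"
        )
    gamma = gamma_prime / mean_sq_norm
    n = profiles.shape[0]
    if n == 1:
        values = np.ones((1, 1))
    else:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
        values = np.exp(-gamma * d2)
        np.fill_diagonal(values, 1.0)
    if index is None:
        kind = "microbe" if role == "microbe_gap" else "disease"
        index = EntityIndex(kind, tuple(f"e{k}" for k in range(n)))
    return SimilarityMatrix(index, values, role)


def symptom_similarity(table: SymptomTable, tfidf: bool = True) -> SimilarityMatrix:
    """Cosine similarity between disease symptom vectors.

    With ``tfidf`` (default), each symptom weight is multiplied by the
    smoothed inverse document frequency ``1 + log(N / df)``, where ``df``
    is the number of diseases presenting the symptom -- de-emphasizing
    (but not erasing) ubiquitous symptoms.  A symptom with constant
    document frequency contributes exactly as in the raw cosine.
    Diseases with an all-zero vector get similarity 0 to everything,
    including themselves.
    """
    X = np.asarray(table.weights, dtype=float)
    n = X.shape[0]
    if tfidf:
        df = (X > 0).sum(axis=0)
        idf = np.zeros(X.shape[1])
        nz = df > 0
        idf[nz] = 1.0 + np.log(n / df[nz])
        X = X * idf
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    values = U @ U.T
    np.clip(values, 0.0, 1.0, out=values)
    d = np.where(norms > 0, 1.0, 0.0)
    np.fill_diagonal(values, d)
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    return SimilarityMatrix(table.diseases, values, "disease_symptom")


def combine_disease_similarity(
    gap: SimilarityMatrix, symptom: SimilarityMatrix, gamma: float = 0.7
) -> SimilarityMatrix:
    """Combined disease similarity ``S_D = S_G + gamma * S_s`` (elementwise)."""
    if gap.index.ids != symptom.index.ids:
        raise MdalpError("disease indexes of the two similarities differ")
    return SimilarityMatrix(
        gap.index, gap.values + gamma * symptom.values, "disease_combined"
    )
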