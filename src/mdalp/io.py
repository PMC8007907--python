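"""Domain containers and TSV readers/writers.

The central object is a binary microbe-disease association matrix ``Y``
(rows = microbes, columns = diseases), with stable string-ID indexes on
both axes.  Similarity matrices, neighbor graphs and score matrices all
carry the same indexes so files can round-trip by ID rather than by
position.

File conventions:

* edge list -- TSV, no header, columns ``microbe_id <TAB> disease_id``;
  lines starting with ``#`` are ignored.
* dense matrix -- TSV; first row = disease IDs, first column = microbe IDs.
* score output -- TSV with header ``rank microbe_id disease_id score known``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MdalpError",
    "ParseError",
    "EntityIndex",
    "AssociationMatrix",
    "SimilarityMatrix",
    "ScoreMatrix",
    "load_associations",
    "save_associations",
    "load_symptom_table",
    "SymptomTable",
    "load_similarity",
    "save_similarity",
    "save_scores",
]


class MdalpError(ValueError):
    """Base class for validation errors raised by this package."""


class ParseError(MdalpError):
    """Malformed input file."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered set of entity IDs with a stable id -> position mapping.

    Parameters
    ----------
    kind
        ``"microbe"`` or ``"disease"`` (``"symptom"`` is also accepted for
        symptom-term axes).
    ids
        Unique string identifiers; their order defines matrix positions.
    """

    kind: str
    ids: tuple[str, ...]
    position: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = {eid: k for k, eid in enumerate(self.ids)}
        if len(pos) != len(self.ids):
            raise MdalpError(f"duplicate {self.kind} ids in index")
        object.__setattr__(self, "position", pos)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, eid: str) -> bool:
        return eid in self.position

    def __getitem__(self, eid: str) -> int:
        return self.position[eid]


def _as_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise MdalpError("association values must be a 2-D matrix")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise MdalpError("association matrix entries must be 0 or 1")
    return arr


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary microbe x disease incidence matrix.

    ``values[i, j] = 1`` iff microbe ``i`` is known to associate with
    disease ``j``.  Row ``i`` is the Gaussian association profile (GAP)
    of microbe ``i``; column ``j`` is the GAP of disease ``j``.
    """

    microbes: EntityIndex
    diseases: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_binary(self.values)
        if arr.shape != (len(self.microbes), len(self.diseases)):
            raise MdalpError(
                f"association matrix shape {arr.shape} does not match indexes "
                f"({len(self.microbes)}, {len(self.diseases)})"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> np.ndarray:
        """(k, 2) array of (microbe position, disease position) for known links."""
        return np.argwhere(self.values == 1.0)

    def unlabeled_pairs(self) -> np.ndarray:
        return np.argwhere(self.values == 0.0)

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(self.microbes, self.diseases, values)


SIMILARITY_ROLES = (
    "microbe_gap",
    "disease_gap",
    "disease_symptom",
    "disease_combined",
)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square nonnegative entity-entity similarity with a role tag."""

    index: EntityIndex
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if arr.shape != (n, n):
            raise MdalpError(f"similarity shape {arr.shape} != ({n}, {n})")
        if self.role not in SIMILARITY_ROLES:
            raise MdalpError(f"unknown similarity role {self.role!r}")
        if arr.min(initial=0.0) < 0:
            raise MdalpError("similarity entries must be nonnegative")
        if self.role in ("microbe_gap", "disease_gap"):
            if not np.allclose(arr, arr.T, atol=1e-10):
                raise MdalpError(f"{self.role} similarity must be symmetric")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued predicted association propensities, same shape as Y."""

    microbes: EntityIndex
    diseases: EntityIndex
    values: np.ndarray
    provenance: str = "scores"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.microbes), len(self.diseases)):
            raise MdalpError("score matrix shape does not match indexes")
        if not np.isfinite(arr).all():
            raise MdalpError("score matrix entries must be finite")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class SymptomTable:
    """Nonnegative disease x symptom weight table."""

    diseases: EntityIndex
    symptoms: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.weights, dtype=float)
        if arr.shape != (len(self.diseases), len(self.symptoms)):
            raise MdalpError("symptom table shape does not match indexes")
        if arr.min(initial=0.0) < 0:
            raise MdalpError("symptom weights must be nonnegative")
        object.__setattr__(self, "weights", arr)

    def aligned_to(self, diseases: EntityIndex) -> np.ndarray:
        """Reorder rows to ``diseases``; missing diseases get all-zero rows.

        Missing diseases are logged as a warning, not an error: their
        symptom similarities are simply zero.
        """
        out = np.zeros((len(diseases), len(self.symptoms)))
        missing = []
        for k, did in enumerate(diseases.ids):
            if did in self.diseases:
                out[k] = self.weights[self.diseases[did]]
            else:
                missing.append(did)
        if missing:
            logger.warning(
                "%d disease(s) missing from symptom table (similarities set "
                "to 0): %s",
                len(missing),
                ", ".join(missing[:5]),
            )
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_edge_list(path: str) -> AssociationMatrix:
    microbes: list[str] = []
    diseases: list[str] = []
    mpos: dict[str, int] = {}
    dpos: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns (microbe_id, disease_id)"
                )
            n_lines += 1
            mid, did = fields[0].strip(), fields[1].strip()
            if mid not in mpos:
                mpos[mid] = len(microbes)
                microbes.append(mid)
            if did not in dpos:
                dpos[did] = len(diseases)
                diseases.append(did)
            edges.add((mpos[mid], dpos[did]))
    if n_lines == 0:
        raise ParseError(f"{path}: no association records found")
    values = np.zeros((len(microbes), len(diseases)))
    for i, j in edges:
        values[i, j] = 1.0
    return AssociationMatrix(
        EntityIndex("microbe", tuple(microbes)),
        EntityIndex("disease", tuple(diseases)),
        values,
    )


def _read_dense(path: str) -> AssociationMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: could not parse dense matrix: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty dense association matrix")
    values = np.empty(df.shape)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            if str(cell).strip() not in ("0", "1"):
                raise ParseError(
                    f"{path}: row {r + 2}: cell value {cell!r} is not 0 or 1"
                )
            values[r, c] = float(cell)
    return AssociationMatrix(
        EntityIndex("microbe", tuple(str(x) for x in df.index)),
        EntityIndex("disease", tuple(str(x) for x in df.columns)),
        values,
    )


def load_associations(path: str, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary association matrix from a TSV file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"edge_list"`` (two columns, duplicates collapse, entity order =
        first appearance) or ``"dense"`` (headered 0/1 matrix, entity order
        = header order).
    """
    if format == "edge_list":
        return _read_edge_list(path)
    if format == "dense":
        return _read_dense(path)
    raise MdalpError(f"unknown association format {format!r}")


def save_associations(
    assoc: AssociationMatrix, path: str, format: str = "edge_list"
) -> None:
    """Write associations as an edge list or dense matrix (see ``load_associations``)."""
    if format == "edge_list":
        with open(path, "w") as fh:
            for i, j in assoc.positive_pairs():
                fh.write(f"{assoc.microbes.ids[i]}\t{assoc.diseases.ids[j]}\n")
    elif format == "dense":
        df = pd.DataFrame(
            assoc.values.astype(int),
            index=list(assoc.microbes.ids),
            columns=list(assoc.diseases.ids),
        )
        df.to_csv(path, sep="\t")
    else:
        raise MdalpError(f"unknown association format {format!r}")


def load_symptom_table(path: str) -> SymptomTable:
    """Read a disease x symptom weight TSV (header row = symptom terms)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty symptom table")
    return SymptomTable(
        EntityIndex("disease", tuple(str(x) for x in df.index)),
        tuple(str(x) for x in df.columns),
        df.to_numpy(dtype=float),
    )


def load_similarity(path: str, role: str, kind: str = "disease") -> SimilarityMatrix:
    """Read a precomputed square similarity TSV headered by entity IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ParseError(f"{path}: row and column IDs differ")
    return SimilarityMatrix(
        EntityIndex(kind, tuple(str(x) for x in df.index)),
        df.to_numpy(dtype=float),
        role,
    )


def save_similarity(sim: SimilarityMatrix, path: str) -> None:
    pd.DataFrame(
        sim.values, index=list(sim.index.ids), columns=list(sim.index.ids)
    ).to_csv(path, sep="\t")


def _ranked_rows(
    scores: ScoreMatrix,
    known: np.ndarray | None,
    top_k: int | None,
    per_disease: bool,
) -> list[tuple[int, str, str, float, int]]:
    mids = scores.microbes.ids
    dids = scores.diseases.ids
    rows: list[tuple[int, str, str, float, int]] = []

    def sort_key(pair: tuple[int, int]) -> tuple[float, str, str]:
        i, j = pair
        return (-scores.values[i, j], mids[i], dids[j])

    if per_disease:
        for j in range(len(dids)):
            pairs = sorted(((i, j) for i in range(len(mids))), key=sort_key)
            if top_k is not None:
                pairs = pairs[:top_k]
            for rank, (i, jj) in enumerate(pairs, start=1):
                flag = int(known[i, jj]) if known is not None else 0
                rows.append((rank, mids[i], dids[jj], scores.values[i, jj], flag))
    else:
        pairs = sorted(
            ((i, j) for i in range(len(mids)) for j in range(len(dids))),
            key=sort_key,
        )
        if top_k is not None:
            pairs = pairs[:top_k]
        for rank, (i, j) in enumerate(pairs, start=1):
            flag = int(known[i, j]) if known is not None else 0
            rows.append((rank, mids[i], dids[j], scores.values[i, j], flag))
    return rows


def save_scores(
    scores: ScoreMatrix,
    path: str,
    top_k: int | None = None,
    per_disease: bool = False,
    known: AssociationMatrix | None = None,
) -> None:
    """Write ranked predictions as TSV.

    Rows are sorted by descending score (globally, or within each disease
    when ``per_disease``); ties break by (microbe_id, disease_id) so output
    is deterministic.  ``known`` flags pairs already present in the
    association matrix.
    """
    if top_k is not None and top_k < 1:
        raise MdalpError("top_k must be a positive integer")
    kvals = known.values if known is not None else None
    rows = _ranked_rows(scores, kvals, top_k, per_disease)
    with open(path, "w") as fh:
        fh.write("rank\tmicrobe_id\tdisease_id\tscore\tknown\n")
        for rank, mid, did, score, flag in rows:
            fh.write(f"{rank}\t{mid}\t{did}\t{score:.10g}\t{flag}\n")
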