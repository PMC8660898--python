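"""Reading, validation and normalization of the five input tables.

The data model mirrors the inputs of the tri-factorization pipeline:

* a per-variant score table (nine constituent deleteriousness /
  conservation predictors per missense variant, possibly with gaps),
* a binary label vector (1 = deleterious, 0 = neutral),
* a STRING-style protein–protein interaction edge list,
* a gene→protein mapping,
* a gene–disease association table.

Raw predictor scores live on heterogeneous scales, and for SIFT and LRT
the *minimum* is the most damaging value. Scores are therefore flipped
(``1 - A``) where needed and min–max rescaled to [0, 1]; the resulting
complete matrix is the variant×score relation matrix consumed by the
factorization core. Bounds are always fitted on training data and reused,
with clipping, on test data, so the relation matrix stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import logging

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, FormatError, ValidationError

logger = logging.getLogger("snmtfvar")

#: The nine constituent predictors used as score columns, in canonical order.
DEFAULT_SCORE_NAMES: tuple[str, ...] = (
    "SIFT",
    "Polyphen2",
    "LRT",
    "MutationAssessor",
    "PROVEAN",
    "GERP++",
    "phyloP",
    "phastCons",
    "SiPhy",
)

#: Scores whose raw minimum means most damaging; flipped to 1-A before rescaling.
DEFAULT_FLIP_SET: frozenset[str] = frozenset({"SIFT", "LRT"})

#: Cell contents treated as missing in the score table.
MISSING_TOKENS = {"", "NA", "."}


@dataclass(frozen=True)
class VariantRecord:
    """A missense variant and the single gene harboring it."""

    variant_id: str
    gene_id: str


@dataclass
class RawScoreTable:
    """Ordered variant records plus an m×n grid of raw scores (NaN = missing)."""

    records: list[VariantRecord]
    score_names: list[str]
    values: np.ndarray  # float64, shape (m, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.records)
        if self.values.shape != (m, len(self.score_names)):
            raise ValidationError(
                f"score grid shape {self.values.shape} does not match "
                f"{m} records x {len(self.score_names)} scores"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise ValidationError(f"duplicate variant_id: {rec.variant_id!r}")
            seen.add(rec.variant_id)
            if not rec.gene_id:
                raise ValidationError(f"variant {rec.variant_id!r} has empty gene_id")

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, row_index: np.ndarray) -> "RawScoreTable":
        """Row-subset preserving order (row_index: integer or boolean index)."""
        idx = np.arange(len(self.records))[row_index]
        return RawScoreTable(
            records=[self.records[i] for i in idx],
            score_names=list(self.score_names),
            values=self.values[idx],
        )


@dataclass(frozen=True)
class OrientationMap:
    """Per-score flip flags and training min/max bounds for Eq.-style rescaling."""

    score_names: tuple[str, ...]
    flip: tuple[bool, ...]
    a_min: tuple[float, ...]
    a_max: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.score_names)
        if not (len(self.flip) == len(self.a_min) == len(self.a_max) == n):
            raise ValidationError("OrientationMap fields have inconsistent lengths")
        for name, lo, hi in zip(self.score_names, self.a_min, self.a_max):
            if lo > hi:
                raise ValidationError(f"A_min > A_max for score {name!r}")


# m×n relation matrices and label vectors are plain numpy arrays; the
# structural invariants (range, binariness) are enforced at construction.


@dataclass(frozen=True)
class PPIEdge:
    protein_a: str
    protein_b: str
    confidence: float


@dataclass
class PPIEdgeList:
    """Undirected, deduplicated protein interaction edges with confidence in (0,1]."""

    edges: list[PPIEdge]

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneDiseaseTable:
    """Unique (gene_id, disease_id) association pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        # preserve first-seen order while deduplicating
        self.pairs = list(dict.fromkeys(self.pairs))

    @property
    def diseases(self) -> list[str]:
        return sorted({d for _, d in self.pairs})

    def genes_for(self, disease_id: str) -> set[str]:
        return {g for g, d in self.pairs if d == disease_id}


# ---------------------------------------------------------------------------
# readers


def read_score_table(path, score_names: Sequence[str] = DEFAULT_SCORE_NAMES) -> RawScoreTable:
    """Read the variant score TSV into a :class:`RawScoreTable`.

    The file must have a header with ``variant_id``, ``gene_id`` and every
    requested score column. Unparseable numeric cells ("NA", ".", empty or
    other junk) become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["variant_id", "gene_id", *score_names]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"score table {path} lacks mandatory column {col!r}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"duplicate variant_id in score table: {dup!r}")
    records = [
        VariantRecord(v, g) for v, g in zip(df["variant_id"], df["gene_id"])
    ]
    def parse_cell(tok: str) -> float:
        if tok in MISSING_TOKENS:
            return np.nan
        try:
            return float(tok)  # correctly-rounded, exact round trip with repr()
        except ValueError:
            return np.nan

    values = df[list(score_names)].map(parse_cell).to_numpy(dtype=float)
    return RawScoreTable(records=records, score_names=list(score_names), values=values)


def filter_missing(
    table: RawScoreTable, labels: np.ndarray | None = None
) -> tuple[RawScoreTable, np.ndarray | None]:
    """Drop every variant row with at least one missing score cell.

    Returns the filtered table and, if given, the label vector subset to the
    surviving rows. Raises :class:`EmptyDatasetError` when nothing survives.
    """
    keep = ~np.isnan(table.values).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_missing: dropped %d of %d variants with missing scores",
                    dropped, len(keep))
    if not keep.any():
        raise EmptyDatasetError("all variant rows contain missing score cells")
    out = table.subset(keep)
    if labels is None:
        return out, None
    labels = np.asarray(labels)
    if labels.shape[0] != len(keep):
        raise ValidationError("label vector length does not match score table")
    return out, labels[keep]


def fit_orientation(
    table: RawScoreTable, flip_set: Iterable[str] = DEFAULT_FLIP_SET
) -> OrientationMap:
    """Fit per-score (A_min, A_max) bounds on a complete (training) table.

    Flip-flagged columns are transformed to ``1 - A`` before the bounds are
    taken, so the bounds describe the damaging-ascending orientation.
    """
    if np.isnan(table.values).any():
        raise ValidationError("fit_orientation requires a table without missing cells")
    flip_set = set(flip_set)
    unknown = flip_set - set(table.score_names)
    if unknown:
        logger.warning("flip requested for absent scores: %s", sorted(unknown))
    flips = tuple(name in flip_set for name in table.score_names)
    oriented = np.where(np.asarray(flips), 1.0 - table.values, table.values)
    return OrientationMap(
        score_names=tuple(table.score_names),
        flip=flips,
        a_min=tuple(oriented.min(axis=0)),
        a_max=tuple(oriented.max(axis=0)),
    )


def normalize_scores(table: RawScoreTable, omap: OrientationMap) -> np.ndarray:
    """Min–max rescale every score column into [0, 1] using fitted bounds.

    Applies the recorded flips, then ``(A' - A_min) / (A_max - A_min)``, then
    clips to [0, 1] (test values may fall outside the training range).
    Constant columns (A_min == A_max) map to 0.5 everywhere: an uninformative
    score should not push predictions either way.
    """
    if tuple(table.score_names) != omap.score_names:
        raise ValidationError(
            "score columns do not match the fitted orientation map: "
            f"{table.score_names} vs {list(omap.score_names)}"
        )
    if np.isnan(table.values).any():
        raise ValidationError("normalize_scores requires a table without missing cells")
    flips = np.asarray(omap.flip)
    lo = np.asarray(omap.a_min)
    hi = np.asarray(omap.a_max)
    oriented = np.where(flips, 1.0 - table.values, table.values)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (oriented - lo) / span
    scaled = np.where(span == 0.0, 0.5, scaled)
    return np.clip(scaled, 0.0, 1.0)


def read_ppi(path, min_confidence: float = 0.15) -> PPIEdgeList:
    """Read a STRING-style edge list: ``protein1 protein2 score`` triples.

    Scores on the STRING 0–1000 integer scale are auto-detected (any value
    above 1 rescales the whole file by 1/1000). Edges are kept when
    confidence is strictly greater than ``min_confidence``; duplicates and
    self-edges are dropped.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 whitespace-separated fields, "
                    f"got {len(parts)}"
                )
            a, b, raw = parts
            if lineno == 1 and _looks_like_header(raw):
                continue
            try:
                score = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable score {raw!r}") from exc
            if score < 0:
                raise FormatError(f"{path}:{lineno}: negative confidence {score}")
            rows.append((a, b, score))
    if rows and max(s for _, _, s in rows) > 1.0:
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
    edges: dict[tuple[str, str], float] = {}
    for a, b, s in rows:
        if a == b or s <= min_confidence:
            continue
        key = (a, b) if a <= b else (b, a)
        edges[key] = max(edges.get(key, 0.0), s)
    return PPIEdgeList([PPIEdge(a, b, s) for (a, b), s in edges.items()])


def _looks_like_header(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return True
    return False


def read_gene_disease(path) -> GeneDiseaseTable:
    """Read the gene–disease association TSV (``gene_id<TAB>disease_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "disease_id"):
        if col not in df.columns:
            raise FormatError(f"gene-disease table {path} lacks column {col!r}")
    return GeneDiseaseTable(list(zip(df["gene_id"], df["disease_id"])))


def read_labels(path, variant_order: Sequence[str]) -> np.ndarray:
    """Read ``variant_id<TAB>label`` and align the 0/1 vector to ``variant_order``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("variant_id", "label"):
        if col not in df.columns:
            raise FormatError(f"label table {path} lacks column {col!r}")
    mapping: dict[str, int] = {}
    for vid, raw in zip(df["variant_id"], df["label"]):
        if raw not in {"0", "1"}:
            raise ValidationError(f"label for {vid!r} must be 0 or 1, got {raw!r}")
        mapping[vid] = int(raw)
    missing = [v for v in variant_order if v not in mapping]
    if missing:
        raise ValidationError(f"labels missing for {len(missing)} variants, e.g. {missing[0]!r}")
    return np.array([mapping[v] for v in variant_order], dtype=float)


def read_gene_map(path=None, genes: Iterable[str] = ()) -> dict[str, str]:
    """Read ``gene_id<TAB>protein_id``; identity map over ``genes`` if no path given."""
    if path is None:
        return {g: g for g in genes}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "protein_id"):
        if col not in df.columns:
            raise FormatError(f"gene map {path} lacks column {col!r}")
    return dict(zip(df["gene_id"], df["protein_id"]))


def remove_overlap(
    train: RawScoreTable, test: RawScoreTable
) -> tuple[RawScoreTable, np.ndarray]:
    """Optional utility: drop test variants whose IDs also appear in training.

    Returns the reduced test table and the boolean mask of kept rows; never
    applied implicitly by the pipeline.
    """
    train_ids = set(train.variant_ids)
    keep = np.array([v not in train_ids for v in test.variant_ids])
    if not keep.any():
        raise EmptyDatasetError("every test variant overlaps the training set")
    return test.subset(keep), keep
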