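"""Intra-type networks (V–V, S–S, D–D), the variant–disease relation, and Laplacians.

The variant–variant network projects a protein interaction network down to
variants: variants sharing a gene form a clique with edge weight 1/(n−1)
(n = variants on the gene), so each variant's same-gene weighted degree is 1
regardless of how densely annotated the gene is; variants on different genes
whose proteins interact inherit the interaction confidence as edge weight.

The score–score network compares predictor columns of the normalized
relation matrix by Manhattan distance; the disease–disease network scores a
disease pair by the Jaccard index of their associated variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import EmptyDatasetError, ValidationError
from .ingest import GeneDiseaseTable, PPIEdgeList, VariantRecord


@dataclass
class WeightedGraph:
    """Symmetric non-negative adjacency with a fixed node order and zero diagonal."""

    node_ids: list[str]
    W: sp.csr_matrix
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.W = sp.csr_matrix(self.W)
        if self.W.shape != (n, n):
            raise ValidationError(f"adjacency shape {self.W.shape} != ({n}, {n})")
        if self.W.nnz and self.W.data.min() < 0:
            raise ValidationError("adjacency has negative weights")
        if abs(self.W - self.W.T).nnz:
            diff = abs(self.W - self.W.T)
            if diff.data.size and diff.data.max() > 1e-12:
                raise ValidationError("adjacency is not symmetric")
        if n and np.abs(self.W.diagonal()).max() > 0:
            raise ValidationError("adjacency has nonzero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()


@dataclass
class LaplacianMatrix:
    """Unnormalized graph Laplacian L = Deg − W, same node order as its graph."""

    node_ids: list[str]
    matrix: sp.csr_matrix

    def split(self) -> tuple[np.ndarray, sp.csr_matrix]:
        """Return (degree vector, adjacency W) recovered from L = Deg − W."""
        deg = self.matrix.diagonal().copy()
        W = sp.diags(deg) - self.matrix
        return deg, sp.csr_matrix(W)


def laplacian(G: WeightedGraph) -> LaplacianMatrix:
    """L = Deg − W with Deg = diag(row sums); symmetric PSD with zero row sums."""
    deg = G.degrees()
    L = sp.diags(deg) - G.W
    return LaplacianMatrix(node_ids=list(G.node_ids), matrix=sp.csr_matrix(L))


def build_variant_network(
    variants: Sequence[VariantRecord],
    ppi: PPIEdgeList,
    gene_map: Mapping[str, str] | None = None,
) -> WeightedGraph:
    """Project the PPI network onto variants.

    Rules (applied independently; a variant hit by neither is isolated):

    * same-gene: a gene carrying n ≥ 2 variants connects every pair of them
      with weight 1/(n−1);
    * cross-gene: a PPI edge of confidence c between the proteins of two
      different genes connects every cross pair of their variants with
      weight c.
    """
    ids = [v.variant_id for v in variants]
    m = len(ids)
    gene_rows: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        gene_rows.setdefault(v.gene_id, []).append(i)
    if gene_map is None:
        gene_map = {g: g for g in gene_rows}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    for gene, idx in gene_rows.items():
        n = len(idx)
        if n < 2:
            continue
        w = 1.0 / (n - 1)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append(idx[a])
                cols.append(idx[b])
                vals.append(w)

    protein_genes: dict[str, list[str]] = {}
    for gene in gene_rows:
        prot = gene_map.get(gene)
        if prot is not None:
            protein_genes.setdefault(prot, []).append(gene)
    for edge in ppi:
        genes_a = protein_genes.get(edge.protein_a, ())
        genes_b = protein_genes.get(edge.protein_b, ())
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue
                for i in gene_rows[ga]:
                    for j in gene_rows[gb]:
                        a, b = (i, j) if i < j else (j, i)
                        rows.append(a)
                        cols.append(b)
                        vals.append(edge.confidence)

    if rows:
        # duplicate (i,j) entries can only arise from multiple PPI routes;
        # keep the strongest link rather than summing
        dedup: dict[tuple[int, int], float] = {}
        for r, c, v in zip(rows, cols, vals):
            key = (r, c)
            dedup[key] = max(dedup.get(key, 0.0), v)
        r2, c2 = zip(*dedup.keys())
        upper = sp.coo_matrix((list(dedup.values()), (list(r2), list(c2))), shape=(m, m))
        W = upper + upper.T
    else:
        W = sp.csr_matrix((m, m))
    return WeightedGraph(node_ids=ids, W=sp.csr_matrix(W))


def build_score_network(
    R: np.ndarray,
    score_names: Sequence[str],
    ss_weight: Literal["similarity", "distance"] = "similarity",
) -> WeightedGraph:
    """Score–score network from the normalized m×n relation matrix.

    The Manhattan distance between two score columns, d(j,k) = Σ_i |R_ij −
    R_ik|, is rescaled to a similarity w = 1 − d/m so that the Laplacian
    penalty pulls mutually consistent predictors together; ``ss_weight=
    "distance"`` stores the raw distance as the edge weight instead. The raw
    distance matrix is always kept in ``meta["manhattan"]``.
    """
    R = np.asarray(R, dtype=float)
    m, n = R.shape
    if m == 0:
        raise EmptyDatasetError("cannot build score network from an empty relation matrix")
    if len(score_names) != n:
        raise ValidationError("score_names length does not match relation matrix columns")
    dist = np.abs(R[:, :, None] - R[:, None, :]).sum(axis=0)
    if ss_weight == "similarity":
        W = 1.0 - dist / m
    elif ss_weight == "distance":
        W = dist.copy()
    else:
        raise ValidationError(f"unknown ss_weight mode {ss_weight!r}")
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, None)
    return WeightedGraph(
        node_ids=list(score_names),
        W=sp.csr_matrix(W),
        meta={"manhattan": dist, "ss_weight": ss_weight},
    )


def build_relation_vd(
    variants: Sequence[VariantRecord],
    gd: GeneDiseaseTable,
    disease_order: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Binary m×n_D variant–disease relation: 1 iff the variant's gene is associated.

    Returns (R_VD, disease_order). Variants on genes without associations get
    all-zero rows.
    """
    if disease_order is None:
        disease_order = gd.diseases
    disease_order = list(disease_order)
    known = set(disease_order)
    extra = {d for _, d in gd.pairs} - known
    if extra:
        raise ValidationError(f"disease_order does not cover: {sorted(extra)[:3]}")
    col = {d: j for j, d in enumerate(disease_order)}
    R = np.zeros((len(variants), len(disease_order)))
    gene_cols: dict[str, list[int]] = {}
    for g, d in gd.pairs:
        gene_cols.setdefault(g, []).append(col[d])
    for i, v in enumerate(variants):
        for j in gene_cols.get(v.gene_id, ()):
            R[i, j] = 1.0
    return R, disease_order


def build_disease_network(
    variant_disease: np.ndarray, disease_order: Sequence[str]
) -> WeightedGraph:
    """Disease–disease network: Jaccard index of associated variant sets.

    weight(d1, d2) = |V1 ∩ V2| / |V1 ∪ V2| over the variants associated with
    each disease; pairs where both sets are empty get weight 0.
    """
    R = np.asarray(variant_disease, dtype=float)
    if not np.isin(R, (0.0, 1.0)).all():
        raise ValidationError("variant-disease relation must be binary")
    inter = R.T @ R
    sizes = R.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(node_ids=list(disease_order), W=sp.csr_matrix(W))


# ---------------------------------------------------------------------------
# export / import


def save_graph(G: WeightedGraph, prefix) -> None:
    """Write ``<prefix>.mtx`` (adjacency), ``<prefix>.nodes.tsv`` (node order)
    and ``<prefix>.edges.tsv`` (TSV triples)."""
    import scipy.io
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", G.W)
    with open(str(prefix) + ".nodes.tsv", "w") as fh:
        fh.write("node_id\n")
        for n in G.node_ids:
            fh.write(f"{n}\n")
    coo = sp.triu(G.W, k=1).tocoo()
    with open(str(prefix) + ".edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{G.node_ids[i]}\t{G.node_ids[j]}\t{float(w)!r}\n")


def load_graph(prefix) -> WeightedGraph:
    """Read back a graph written by :func:`save_graph`."""
    import scipy.io

    W = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    with open(str(prefix) + ".nodes.tsv") as fh:
        next(fh)
        nodes = [line.strip() for line in fh if line.strip()]
    return WeightedGraph(node_ids=nodes, W=W)
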