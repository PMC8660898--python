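"""Fully synthetic variant datasets with planted co-cluster structure.

The generator emulates the five input tables of the pipeline end to end:

* a raw score table whose normalized form is a planted tri-factorization
  R = V*U*S*ᵀ plus truncated Gaussian noise, where deleterious variant
  clusters sit ``signal`` above neutral clusters in mean normalized score;
* labels tied to the planted variant clusters, balanced to ``label_balance``;
* a modular PPI network whose gene modules coincide with variant clusters;
* a gene→protein map;
* gene–disease associations informative for a configurable fraction of
  deleterious genes, plus uniform noise pairs.

Raw scores are emitted on realistic per-predictor scales, with SIFT and LRT
written damaging-descending, so ingestion has to exercise the flip and
min–max normalization logic. What this deliberately does not emulate: real
allele-frequency spectra, per-gene mutation-type composition, or the
correlation structure of the actual nine predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .evaluation import Bundle
from .ingest import (
    DEFAULT_SCORE_NAMES,
    GeneDiseaseTable,
    PPIEdge,
    PPIEdgeList,
    RawScoreTable,
    VariantRecord,
    filter_missing,
    read_gene_disease,
    read_gene_map,
    read_labels,
    read_ppi,
    read_score_table,
)

#: Plausible raw ranges for the nine constituent predictors. Flipped scores
#: (SIFT, LRT) must live on [0, 1] because the flip is 1−A.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "SIFT": (0.0, 1.0),
    "Polyphen2": (0.0, 1.0),
    "LRT": (0.0, 1.0),
    "MutationAssessor": (-5.5, 6.5),
    "PROVEAN": (-14.0, 14.0),
    "GERP++": (-12.3, 6.17),
    "phyloP": (-20.0, 30.0),
    "phastCons": (0.0, 1.0),
    "SiPhy": (0.0, 37.9),
}

FLIPPED = ("SIFT", "LRT")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated dataset."""

    n_genes: int = 40
    variants_per_gene: tuple[int, int] = (5, 15)
    n_scores: int = 9
    n_diseases: int = 20
    k_V_true: int = 4
    k_S_true: int = 3
    signal: float = 0.6  # separation of deleterious vs neutral mean normalized score
    ppi_density: float = 0.3
    disease_informative_fraction: float = 0.8
    disease_noise_rate: float = 0.1  # noise pairs per informative pair
    label_balance: float = 0.4  # fraction of deleterious variants
    noise_sd: float = 0.1
    missing_rate: float = 0.0  # per-row chance of one injected missing cell
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_scores, self.n_diseases) < 1:
            raise ValidationError("counts must be positive")
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ValidationError("variants_per_gene must be a positive (lo, hi) range")
        for name in ("signal", "ppi_density", "disease_informative_fraction",
                     "label_balance", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.k_V_true < 2:
            raise ValidationError("need >= 2 planted variant clusters (one per class)")
        if self.k_S_true < 1 or self.k_S_true > self.n_scores:
            raise ValidationError("k_S_true must be in [1, n_scores]")


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted ground truth."""

    config: SyntheticConfig
    table: RawScoreTable  # raw scores, NaN where missing was injected
    labels: np.ndarray
    ppi: PPIEdgeList
    gene_map: dict[str, str]
    gene_disease: GeneDiseaseTable
    truth: dict = field(default_factory=dict)


def _score_names(n: int) -> list[str]:
    names = list(DEFAULT_SCORE_NAMES[:n])
    names += [f"score{i}" for i in range(len(names) + 1, n + 1)]
    return names


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset under the planted-co-cluster model. Deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.variants_per_gene
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    counts = rng.integers(lo, hi + 1, size=cfg.n_genes)
    m = int(counts.sum())
    if cfg.k_V_true > m:
        raise ValidationError(f"k_V_true={cfg.k_V_true} exceeds total variants {m}")

    records: list[VariantRecord] = []
    gene_of: list[int] = []
    for gi, (g, c) in enumerate(zip(genes, counts)):
        for j in range(c):
            records.append(VariantRecord(f"v{len(records):05d}", g))
            gene_of.append(gi)
    gene_of = np.array(gene_of)

    # labels: fill shuffled genes wholly deleterious until the quota, then
    # split one gene (a natural "mix" gene) to hit the balance exactly
    n_del = int(round(cfg.label_balance * m))
    labels = np.zeros(m)
    order = rng.permutation(cfg.n_genes)
    remaining = n_del
    for gi in order:
        if remaining <= 0:
            break
        idx = np.flatnonzero(gene_of == gi)
        take = min(len(idx), remaining)
        labels[idx[:take]] = 1.0
        remaining -= take

    # planted clusters: deleterious variants spread over the first half of
    # the clusters, neutral over the rest, grouped by gene
    n_del_clusters = max(1, cfg.k_V_true // 2)
    del_clusters = np.arange(n_del_clusters)
    neu_clusters = np.arange(n_del_clusters, cfg.k_V_true)
    cluster = np.empty(m, dtype=int)
    for gi in range(cfg.n_genes):
        idx = np.flatnonzero(gene_of == gi)
        for i in idx:
            pool = del_clusters if labels[i] == 1 else neu_clusters
            cluster[i] = pool[gi % len(pool)]

    # planted factors and the normalized relation matrix
    names = _score_names(cfg.n_scores)
    score_cluster = np.arange(cfg.n_scores) % cfg.k_S_true
    base_del = (1.0 + cfg.signal) / 2.0
    base_neu = (1.0 - cfg.signal) / 2.0
    # per-cluster jitter distinguishes the planted score clusters without
    # leaking label information at either signal extreme
    jitter_amp = 0.05 * cfg.signal * (1.0 - cfg.signal)
    U_true = np.empty((cfg.k_V_true, cfg.k_S_true))
    for c in range(cfg.k_V_true):
        base = base_del if c in del_clusters else base_neu
        U_true[c] = base + rng.uniform(-jitter_amp, jitter_amp, size=cfg.k_S_true)
    V_true = np.zeros((m, cfg.k_V_true))
    V_true[np.arange(m), cluster] = 1.0
    S_true = np.zeros((cfg.n_scores, cfg.k_S_true))
    S_true[np.arange(cfg.n_scores), score_cluster] = 1.0
    R = V_true @ U_true @ S_true.T
    if cfg.noise_sd > 0:
        R = R + rng.normal(0.0, cfg.noise_sd, size=R.shape)
    R = np.clip(R, 0.0, 1.0)

    # raw table on realistic scales; SIFT/LRT written damaging-descending
    raw = np.empty_like(R)
    for j, name in enumerate(names):
        srange = SCORE_RANGES.get(name, (0.0, 1.0))
        v = 1.0 - R[:, j] if name in FLIPPED else R[:, j]
        raw[:, j] = srange[0] + v * (srange[1] - srange[0])
    if cfg.missing_rate > 0:
        hit = rng.random(m) < cfg.missing_rate
        cols = rng.integers(0, cfg.n_scores, size=m)
        raw[hit, cols[hit]] = np.nan
    table = RawScoreTable(records=records, score_names=names, values=raw)

    # modular PPI aligned with variant clusters: a gene's module is the
    # cluster of its majority of variants
    gene_module = np.empty(cfg.n_genes, dtype=int)
    for gi in range(cfg.n_genes):
        vals, cnts = np.unique(cluster[gene_of == gi], return_counts=True)
        gene_module[gi] = int(vals[np.argmax(cnts)])
    gene_map = {g: f"P_{g}" for g in genes}
    edges: list[PPIEdge] = []
    for a in range(cfg.n_genes):
        for b in range(a + 1, cfg.n_genes):
            if gene_module[a] == gene_module[b] and rng.random() < cfg.ppi_density:
                conf = 1.0 - rng.random() * 0.85  # uniform (0.15, 1]
                edges.append(PPIEdge(gene_map[genes[a]], gene_map[genes[b]], float(conf)))
    ppi = PPIEdgeList(edges)

    # disease associations: informative pairs for a fraction of the
    # deleterious genes (disease keyed to the gene's planted cluster),
    # plus uniform noise pairs
    diseases = [f"d{i:03d}" for i in range(cfg.n_diseases)]
    pairs: list[tuple[str, str]] = []
    del_genes = sorted({int(gi) for gi in gene_of[labels == 1]})
    cluster_diseases: dict[int, list[str]] = {}
    for di, d in enumerate(diseases):
        c = int(del_clusters[di % len(del_clusters)])
        cluster_diseases.setdefault(c, []).append(d)
    for gi in del_genes:
        if rng.random() < cfg.disease_informative_fraction:
            pool = cluster_diseases.get(int(gene_module[gi]))
            if pool is None:  # majority-neutral gene with some deleterious variants
                pool = cluster_diseases[int(del_clusters[0])]
            # associate with about half the module's disease pool (min one),
            # so diseases of a module co-occur across genes and the planted
            # D-D Jaccard structure is block-modular rather than empty
            hits = [d for d in pool if rng.random() < 0.5]
            if not hits:
                hits = [pool[int(rng.integers(len(pool)))]]
            pairs.extend((genes[gi], d) for d in hits)
    n_noise = int(round(cfg.disease_noise_rate * len(pairs)))
    for _ in range(n_noise):
        g = genes[int(rng.integers(cfg.n_genes))]
        d = diseases[int(rng.integers(cfg.n_diseases))]
        pairs.append((g, d))
    gd = GeneDiseaseTable(pairs)

    truth = {
        "R": R,
        "V": V_true,
        "U": U_true,
        "S": S_true,
        "variant_cluster": cluster,
        "gene_module": {g: int(c) for g, c in zip(genes, gene_module)},
        "informative_diseases": cluster_diseases,
    }
    return SyntheticDataset(config=cfg, table=table, labels=labels, ppi=ppi,
                            gene_map=gene_map, gene_disease=gd, truth=truth)


# ---------------------------------------------------------------------------
# file round trip


def _fmt(x: float) -> str:
    return "NA" if np.isnan(x) else repr(float(x))


def write_bundle(ds: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the five tables in the exact dialects the ingest module reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.tsv"
             for name in ("scores", "labels", "ppi", "gene_map", "gene_disease")}

    with open(paths["scores"], "w") as fh:
        fh.write("variant_id\tgene_id\t" + "\t".join(ds.table.score_names) + "\n")
        for rec, row in zip(ds.table.records, ds.table.values):
            fh.write(rec.variant_id + "\t" + rec.gene_id + "\t"
                     + "\t".join(_fmt(x) for x in row) + "\n")
    with open(paths["labels"], "w") as fh:
        fh.write("variant_id\tlabel\n")
        for rec, y in zip(ds.table.records, ds.labels):
            fh.write(f"{rec.variant_id}\t{int(y)}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for e in ds.ppi:
            fh.write(f"{e.protein_a}\t{e.protein_b}\t{e.confidence!r}\n")
    with open(paths["gene_map"], "w") as fh:
        fh.write("gene_id\tprotein_id\n")
        for g, p in ds.gene_map.items():
            fh.write(f"{g}\t{p}\n")
    with open(paths["gene_disease"], "w") as fh:
        fh.write("gene_id\tdisease_id\n")
        for g, d in ds.gene_disease.pairs:
            fh.write(f"{g}\t{d}\n")
    return paths


def read_bundle(directory, algorithm: str = "two_source",
                score_names=None) -> Bundle:
    """Read a written bundle back, drop rows with missing scores, and package it."""
    directory = Path(directory)
    import csv

    if score_names is None:
        with open(directory / "scores.tsv") as fh:
            header = next(csv.reader(fh, delimiter="\t"))
        score_names = header[2:]
    table = read_score_table(directory / "scores.tsv", score_names)
    labels = read_labels(directory / "labels.tsv", table.variant_ids)
    table, labels = filter_missing(table, labels)
    ppi = read_ppi(directory / "ppi.tsv")
    gene_map = read_gene_map(directory / "gene_map.tsv")
    gd_path = directory / "gene_disease.tsv"
    gd = read_gene_disease(gd_path) if gd_path.exists() else None
    return Bundle(table=table, labels=labels, ppi=ppi, gene_map=gene_map,
                  gene_disease=gd, algorithm=algorithm)


def to_bundle(ds: SyntheticDataset, algorithm: str = "two_source") -> Bundle:
    """Package an in-memory dataset for evaluation, dropping missing-score rows."""
    table, labels = filter_missing(ds.table, ds.labels)
    return Bundle(table=table, labels=labels, ppi=ds.ppi, gene_map=ds.gene_map,
                  gene_disease=ds.gene_disease, algorithm=algorithm)
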