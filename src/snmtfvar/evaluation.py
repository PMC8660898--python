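"""Metrics, threshold selection, gene-aware cross-validation and stratified reports.

Fold assignment is gene-partitioned: all variants of a gene land in the same
fold, so no information leaks between training and test through shared
genes. Thresholds on the continuous deleteriousness score are always chosen
on training-fold predictions (Youden's J by default), never on test data.

The pure/mix gene partition supports the circularity diagnostic: a "pure"
gene carries only one label class, a "mix" gene carries both; a predictor
that merely memorizes gene identity looks artificially good on pure genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import EmptyDatasetError, ValidationError
from .ingest import (
    GeneDiseaseTable,
    PPIEdgeList,
    RawScoreTable,
    fit_orientation,
    normalize_scores,
)
from .networks import (
    build_disease_network,
    build_relation_vd,
    build_score_network,
    build_variant_network,
    laplacian,
)
from . import snmtf

logger = logging.getLogger("snmtfvar")

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "F1", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    F1: float
    MCC: float
    AUC: float | None = None
    threshold: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "F1": self.F1,
            "MCC": self.MCC,
        }
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("labels must be binary 0/1")
    return y


def confusion(labels, scores, threshold: float) -> ConfusionCounts:
    """Count TP/FP/TN/FN calling deleterious iff score >= threshold."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValidationError("labels and scores have different lengths")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, TPR, TNR, F1 and MCC from a confusion table.

    Degenerate denominators follow the usual conventions: precision is 0
    (with a warning) when nothing was called positive, and MCC is 0 when any
    factor under its square root vanishes.
    """
    if c.total == 0:
        raise EmptyDatasetError("confusion table has no observations")
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    acc = (tp + tn) / c.total
    if tp + fp == 0:
        logger.warning("no positive calls; precision reported as 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (fp + tn) if fp + tn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(accuracy=acc, precision=prec, sensitivity=sens,
                         specificity=spec, F1=f1, MCC=float(mcc))


def auc(labels, scores) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute 1/2 per pair."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if len(set(y)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def choose_threshold(
    labels, scores, criterion: Literal["youden", "f1"] = "youden"
) -> float:
    """Score cut maximizing Youden's J (sensitivity + specificity − 1) or F1.

    Candidates are the observed score values; ties break toward the higher
    threshold (the more conservative deleterious call).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if len(set(y)) < 2:
        raise ValidationError("threshold selection needs both classes present")
    candidates = np.unique(s)
    best_t, best_val = candidates[-1], -np.inf
    for t in candidates:
        c = confusion(y, s, t)
        rep = metrics(c)
        val = rep.sensitivity + rep.specificity - 1 if criterion == "youden" else rep.F1
        if val >= best_val:  # >= so ties move toward higher thresholds
            best_val, best_t = val, t
    if best_val <= 0 and criterion == "youden":
        logger.warning("no threshold separates the classes (max Youden J = %.3f)", best_val)
    return float(best_t)


@dataclass
class FoldAssignment:
    """Gene-partitioned fold indices: every variant of a gene shares one fold."""

    variant_fold: np.ndarray  # int fold index per variant, 0..k-1
    gene_fold: dict[str, int]
    k: int


def gene_aware_folds(variants: Sequence, k: int, seed: int) -> FoldAssignment:
    """Shuffle genes and split them into k near-equal parts; variants inherit folds."""
    if k < 2:
        raise ValidationError("need at least 2 folds")
    genes = list(dict.fromkeys(v.gene_id for v in variants))
    if len(genes) < k:
        raise ValidationError(f"only {len(genes)} genes for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    gene_fold = {genes[g]: int(i % k) for i, g in enumerate(order)}
    variant_fold = np.array([gene_fold[v.gene_id] for v in variants], dtype=int)
    return FoldAssignment(variant_fold=variant_fold, gene_fold=gene_fold, k=k)


@dataclass
class GenePurityPartition:
    gene_class: dict[str, str]  # "pure" | "mix"
    variant_class: np.ndarray  # per-variant inherited class (object array of str)


def partition_by_gene_purity(variants: Sequence, labels) -> GenePurityPartition:
    """A gene is "mix" iff it harbors both a deleterious and a neutral variant."""
    y = _as_binary(labels)
    gene_labels: dict[str, set[float]] = {}
    for v, lab in zip(variants, y):
        gene_labels.setdefault(v.gene_id, set()).add(lab)
    gene_class = {g: ("mix" if len(s) > 1 else "pure") for g, s in gene_labels.items()}
    variant_class = np.array([gene_class[v.gene_id] for v in variants], dtype=object)
    return GenePurityPartition(gene_class=gene_class, variant_class=variant_class)


def gene_pathogenicity_mask(variants: Sequence, gd: GeneDiseaseTable) -> np.ndarray:
    """True for variants whose gene has at least one disease association."""
    pathogenic = {g for g, _ in gd.pairs}
    return np.array([v.gene_id in pathogenic for v in variants])


def stratified_report(
    labels, scores, threshold: float, groups: Sequence
) -> dict[str, MetricsReport]:
    """Per-group metric reports (e.g. pure vs mix genes, pathogenic vs not)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    groups = np.asarray(groups)
    out: dict[str, MetricsReport] = {}
    for g in dict.fromkeys(groups.tolist()):
        mask = groups == g
        rep = metrics(confusion(y[mask], s[mask], threshold))
        rep.threshold = threshold
        if len(set(y[mask])) == 2:
            rep.AUC = auc(y[mask], s[mask])
        out[str(g)] = rep
    return out


# ---------------------------------------------------------------------------
# end-to-end cross-validation


@dataclass
class Bundle:
    """Everything one train/evaluate cycle needs, in memory.

    ``table`` holds raw (unnormalized) scores with no missing cells; score
    orientation is re-fitted inside every training fold so test folds never
    influence the normalization bounds.
    """

    table: RawScoreTable
    labels: np.ndarray
    ppi: PPIEdgeList
    gene_map: Mapping[str, str] | None = None
    gene_disease: GeneDiseaseTable | None = None
    algorithm: Literal["two_source", "three_source"] = "two_source"
    flip_set: frozenset = frozenset({"SIFT", "LRT"})
    ss_weight: str = "similarity"

    def __post_init__(self) -> None:
        self.labels = _as_binary(self.labels)
        if len(self.labels) != len(self.table.records):
            raise ValidationError("labels do not align with the score table")
        if self.algorithm == "three_source" and self.gene_disease is None:
            raise ValidationError("three_source requires a gene-disease table")


@dataclass
class CVSummary:
    mean: dict[str, float]
    variance: dict[str, float]
    per_fold: list[dict[str, float]]


def fit_fold(bundle: Bundle, train_idx: np.ndarray, test_idx: np.ndarray,
             hp: snmtf.HyperParams) -> tuple[dict[str, float], float]:
    """Train on one gene-partitioned split and evaluate on the held-out part.

    Returns (metric dict, threshold). The orientation map, the score network
    and — for the three-source model — the disease network are all built
    from training-fold data only; the test-side variant network is built on
    the test variants.
    """
    tr = bundle.table.subset(train_idx)
    ts = bundle.table.subset(test_idx)
    y_tr = bundle.labels[train_idx]
    y_ts = bundle.labels[test_idx]

    omap = fit_orientation(tr, bundle.flip_set)
    R_tr = normalize_scores(tr, omap)
    R_ts = normalize_scores(ts, omap)

    vv_tr = build_variant_network(tr.records, bundle.ppi, bundle.gene_map)
    vv_ts = build_variant_network(ts.records, bundle.ppi, bundle.gene_map)
    ss = build_score_network(R_tr, tr.score_names, ss_weight=bundle.ss_weight)
    L_V_tr, L_V_ts, L_S = laplacian(vv_tr), laplacian(vv_ts), laplacian(ss)

    if bundle.algorithm == "two_source":
        model = snmtf.fit_two_source(R_tr, y_tr, L_V_tr, L_S, hp,
                                     score_names=tr.score_names)
        pred = snmtf.predict_two_source(model, R_ts, L_V_ts, hp)
    else:
        gd = bundle.gene_disease
        Rvd_tr, disease_order = build_relation_vd(tr.records, gd)
        Rvd_ts, _ = build_relation_vd(ts.records, gd, disease_order)
        dd = build_disease_network(Rvd_tr, disease_order)
        L_D = laplacian(dd)
        model = snmtf.fit_three_source(R_tr, Rvd_tr, y_tr, L_V_tr, L_S, L_D, hp,
                                       score_names=tr.score_names,
                                       disease_order=disease_order)
        pred = snmtf.predict_three_source(model, R_ts, Rvd_ts, L_V_ts, hp)

    # threshold from training rows pushed through the *test-time* inference
    # path, so the cut lives on the same scale as the held-out scores
    if bundle.algorithm == "two_source":
        self_pred = snmtf.predict_two_source(model, R_tr, L_V_tr, hp)
    else:
        self_pred = snmtf.predict_three_source(model, R_tr, Rvd_tr, L_V_tr, hp)
    threshold = choose_threshold(y_tr, self_pred.y_score)
    rep = metrics(confusion(y_ts, pred.y_score, threshold))
    row = rep.as_dict()
    if len(set(y_ts)) == 2:
        row["AUC"] = auc(y_ts, pred.y_score)
    else:
        logger.warning("held-out fold has a single class; AUC undefined for this fold")
        row["AUC"] = np.nan
    return row, threshold


def cross_validate(
    bundle: Bundle,
    hp: snmtf.HyperParams,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVSummary:
    """Repeated gene-aware k-fold cross-validation.

    Each repeat reshuffles the gene partition under a derived seed; every
    fold refits normalization, networks and the model from its training
    side only. Reports mean and variance of the seven metrics across all
    repeat×fold cells.
    """
    rows: list[dict[str, float]] = []
    for r in range(repeats):
        assign = gene_aware_folds(bundle.table.records, k, seed + 1000 * r)
        for f in range(k):
            test_idx = assign.variant_fold == f
            train_idx = ~test_idx
            fold_hp = replace(hp, seed=hp.seed + r * k + f)
            row, _ = fit_fold(bundle, train_idx, test_idx, fold_hp)
            rows.append(row)
    names = rows[0].keys()
    mean = {n: float(np.nanmean([r[n] for r in rows])) for n in names}
    var = {n: float(np.nanvar([r[n] for r in rows])) for n in names}
    return CVSummary(mean=mean, variance=var, per_fold=rows)
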