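"""Supervised non-negative matrix tri-factorization: objectives, updates, training, inference.

Training jointly factorizes the variant×score relation matrix and the label
vector in a shared variant basis,

    R_VS ≈ V U Sᵀ,    Y ≈ V U G_Yᵀ,

with graph-Laplacian penalties γ₁·tr(Vᵀ L_V V) and γ₂·tr(Sᵀ L_S S) pulling
network-linked variants (and mutually consistent scores) toward nearby
latent representations. The three-source variant adds a variant×disease
relation R_VD ≈ V U₂ Dᵀ and a disease-network penalty γ₃·tr(Dᵀ L_D D),
sharing the variant basis V across all three reconstruction terms.

All factors stay non-negative through multiplicative updates: each factor is
multiplied element-wise by the ratio of the positive to the negative part of
its gradient, with every Laplacian split as L = Deg − W so both parts remain
non-negative. At test time the score-side factors (S, G_Y, and D for the
three-source model) are frozen and only the test-variant factors are fitted,
after which the continuous deleteriousness score is Y_ts = V_ts U_ts G_Yᵀ.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import NumericalError, ValidationError
from .networks import LaplacianMatrix

__all__ = [
    "HyperParams",
    "TwoSourceModel",
    "ThreeSourceModel",
    "PredictionResult",
    "init_factors",
    "objective_two_source",
    "objective_three_source",
    "fit_two_source",
    "fit_three_source",
    "predict_two_source",
    "predict_three_source",
    "grid_search",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HyperParams:
    """Ranks, regularization weights and solver controls.

    k_V / k_S / k_D are the variant, score and disease cluster counts;
    gamma1..3 weight the V–V, S–S and D–D Laplacian penalties. ``init_p`` is
    the number of data columns averaged per factor column in random-Acol
    initialization. ``n_restarts`` trains from that many independent
    initializations and keeps the run with the lowest final objective —
    the usual defence against poor NMF local optima. ``reuse_u`` freezes
    the trained interaction factor(s) at test time (default) rather than
    re-estimating them from a warm start: the interaction factor carries
    the label mapping learned jointly with G_Y, and re-fitting it to the
    test reconstruction alone (where no label term exists) discards that
    supervision. Set ``reuse_u=False`` for warm-started re-estimation.
    """

    k_V: int = 10
    k_S: int = 3
    k_D: int = 5
    gamma1: float = 1.0
    gamma2: float = 1.0
    gamma3: float = 1.0
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    eps: float = 1e-10
    init_p: int = 5
    n_restarts: int = 5
    reuse_u: bool = True

    def __post_init__(self) -> None:
        if min(self.k_V, self.k_S, self.k_D) < 1:
            raise ValidationError("factorization ranks must be >= 1")
        if min(self.gamma1, self.gamma2, self.gamma3) < 0:
            raise ValidationError("regularization weights must be >= 0")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be >= 0")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.init_p < 1:
            raise ValidationError("init_p must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")


@dataclass
class TwoSourceModel:
    V: np.ndarray  # m x k_V
    U: np.ndarray  # k_V x k_S
    S: np.ndarray  # n x k_S
    G_Y: np.ndarray  # 1 x k_S
    objective_trace: list[float]
    hyperparams: HyperParams
    score_names: list[str] | None = None
    threshold: float | None = None

    def train_scores(self) -> np.ndarray:
        """Continuous deleteriousness scores for the training variants."""
        return (self.V @ self.U @ self.G_Y.T).ravel()


@dataclass
class ThreeSourceModel:
    V: np.ndarray  # m x k_V
    U1: np.ndarray  # k_V x k_S
    U2: np.ndarray  # k_V x k_D
    S: np.ndarray  # n x k_S
    D: np.ndarray  # n_D x k_D
    G_Y: np.ndarray  # 1 x k_S
    objective_trace: list[float]
    hyperparams: HyperParams
    score_names: list[str] | None = None
    disease_order: list[str] | None = None
    threshold: float | None = None

    def train_scores(self) -> np.ndarray:
        return (self.V @ self.U1 @ self.G_Y.T).ravel()


@dataclass
class PredictionResult:
    y_score: np.ndarray
    V_ts: np.ndarray
    U_ts: np.ndarray | None = None
    U2_ts: np.ndarray | None = None
    objective_trace: list[float] = field(default_factory=list)
    threshold: float | None = None


# ---------------------------------------------------------------------------
# initialization


def _acol_columns(R: np.ndarray, k: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Each output column = mean of p distinct, uniformly chosen columns of R."""
    m, n = R.shape
    p = min(p, n)
    out = np.empty((m, k))
    for j in range(k):
        cols = rng.choice(n, size=p, replace=False)
        out[:, j] = R[:, cols].mean(axis=1)
    return out


def init_factors(
    R: np.ndarray, k_rows: int, k_cols: int, seed: int, p: int = 5, eps: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random-Acol initialization for one relation matrix.

    Columns of V₀ are averages of ``p`` randomly chosen columns of R; columns
    of S₀ are averages of ``p`` randomly chosen rows of R. U₀ and G₀ are
    uniform(0, 1]. A small eps keeps every entry strictly positive so
    multiplicative updates can move any coordinate.
    """
    R = np.asarray(R, dtype=float)
    m, n = R.shape
    if k_rows > m or k_cols > n:
        raise ValidationError(
            f"ranks ({k_rows}, {k_cols}) exceed matrix dimensions ({m}, {n})"
        )
    rng = np.random.default_rng(seed)
    V0 = _acol_columns(R, k_rows, p, rng) + eps
    S0 = _acol_columns(R.T, k_cols, p, rng) + eps
    U0 = 1.0 - rng.random((k_rows, k_cols)) + eps
    G0 = 1.0 - rng.random((1, k_cols)) + eps
    return V0, U0, S0, G0


# ---------------------------------------------------------------------------
# objectives


def _lap_split(
    L: LaplacianMatrix | None, size: int
) -> tuple[np.ndarray, sp.csr_matrix]:
    if L is None:
        return np.zeros(size), sp.csr_matrix((size, size))
    if L.matrix.shape != (size, size):
        raise ValidationError(
            f"Laplacian shape {L.matrix.shape} does not match dimension {size}"
        )
    return L.split()


def _trace_quad(L: LaplacianMatrix | None, X: np.ndarray) -> float:
    """tr(Xᵀ L X) with the canonical orientation (L acts on rows of X)."""
    if L is None:
        return 0.0
    if L.matrix.shape[0] != X.shape[0]:
        raise ValidationError(
            f"Laplacian dimension {L.matrix.shape[0]} does not match factor rows {X.shape[0]}"
        )
    return float(np.sum(X * (L.matrix @ X)))


def objective_two_source(R, Y, V, U, S, G_Y, L_V=None, L_S=None, gamma1=0.0, gamma2=0.0) -> float:
    """‖R − VUSᵀ‖²_F + ‖Y − VUG_Yᵀ‖²_F + γ₁ tr(Vᵀ L_V V) + γ₂ tr(Sᵀ L_S S)."""
    R = np.asarray(R, dtype=float)
    Y = np.asarray(Y, dtype=float).reshape(-1, 1)
    VU = V @ U
    if R.shape != (V.shape[0], S.shape[0]) or Y.shape[0] != V.shape[0]:
        raise ValidationError("inconsistent shapes in two-source objective")
    j = float(np.sum((R - VU @ S.T) ** 2))
    j += float(np.sum((Y - VU @ G_Y.T) ** 2))
    j += gamma1 * _trace_quad(L_V, V)
    j += gamma2 * _trace_quad(L_S, S)
    return j


def objective_three_source(
    R_VS, R_VD, Y, V, U1, U2, S, D, G_Y,
    L_V=None, L_S=None, L_D=None, gamma1=0.0, gamma2=0.0, gamma3=0.0,
) -> float:
    """Two-source objective plus ‖R_VD − VU₂Dᵀ‖²_F and γ₃ tr(Dᵀ L_D D)."""
    R_VD = np.asarray(R_VD, dtype=float)
    if R_VD.shape != (V.shape[0], D.shape[0]):
        raise ValidationError("inconsistent R_VD shape in three-source objective")
    j = objective_two_source(R_VS, Y, V, U1, S, G_Y, L_V, L_S, gamma1, gamma2)
    j += float(np.sum((R_VD - V @ U2 @ D.T) ** 2))
    j += gamma3 * _trace_quad(L_D, D)
    return j


# ---------------------------------------------------------------------------
# training


def _check_finite(j: float) -> None:
    if not np.isfinite(j):
        raise NumericalError(
            "objective became non-finite; try smaller regularization weights (gamma)"
        )


def _converged(trace: list[float], tol: float, eps: float) -> bool:
    if len(trace) < 2:
        return False
    prev, cur = trace[-2], trace[-1]
    return abs(cur - prev) / max(prev, eps) < tol


def fit_two_source(
    R_tr: np.ndarray,
    Y_tr: np.ndarray,
    L_V_tr: LaplacianMatrix | None,
    L_S: LaplacianMatrix | None,
    hp: HyperParams,
    score_names: Sequence[str] | None = None,
) -> TwoSourceModel:
    """Train the two-source model by multiplicative updates.

    Iterates until the relative objective change drops below ``hp.tol`` or
    ``hp.max_iter`` is reached; the objective trace (initial value included)
    is non-increasing.
    """
    R = np.asarray(R_tr, dtype=float)
    Y = np.asarray(Y_tr, dtype=float).reshape(-1, 1)
    m, n = R.shape
    if Y.shape[0] != m:
        raise ValidationError("label vector length does not match relation matrix")
    deg_V, W_V = _lap_split(L_V_tr, m)
    deg_S, W_S = _lap_split(L_S, n)
    g1, g2, eps = hp.gamma1, hp.gamma2, hp.eps
    dV = deg_V[:, None]
    dS = deg_S[:, None]

    def run(seed: int):
        V, U, S, G = init_factors(R, hp.k_V, hp.k_S, seed, p=hp.init_p, eps=eps)
        trace = [objective_two_source(R, Y, V, U, S, G, L_V_tr, L_S, g1, g2)]
        _check_finite(trace[0])
        for _ in range(hp.max_iter):
            num = R @ S @ U.T + Y @ G @ U.T + g1 * (W_V @ V)
            den = V @ (U @ (S.T @ S) @ U.T + (U @ G.T) @ (G @ U.T)) + g1 * (dV * V)
            V = V * num / (den + eps)

            VtV = V.T @ V
            num = V.T @ R @ S + V.T @ Y @ G
            den = VtV @ U @ (S.T @ S + G.T @ G)
            U = U * num / (den + eps)

            num = R.T @ V @ U + g2 * (W_S @ S)
            den = S @ (U.T @ VtV @ U) + g2 * (dS * S)
            S = S * num / (den + eps)

            num = Y.T @ V @ U
            den = G @ (U.T @ VtV @ U)
            G = G * num / (den + eps)

            trace.append(objective_two_source(R, Y, V, U, S, G, L_V_tr, L_S, g1, g2))
            _check_finite(trace[-1])
            if _converged(trace, hp.tol, eps):
                break
        return (V, U, S, G), trace

    best, trace = run(hp.seed)
    for r in range(1, hp.n_restarts):
        cand, cand_trace = run(hp.seed + 100003 * r)
        if cand_trace[-1] < trace[-1]:
            best, trace = cand, cand_trace
    V, U, S, G = best

    return TwoSourceModel(
        V=V, U=U, S=S, G_Y=G,
        objective_trace=trace,
        hyperparams=hp,
        score_names=list(score_names) if score_names is not None else None,
    )


def fit_three_source(
    R_VS: np.ndarray,
    R_VD: np.ndarray,
    Y: np.ndarray,
    L_V: LaplacianMatrix | None,
    L_S: LaplacianMatrix | None,
    L_D: LaplacianMatrix | None,
    hp: HyperParams,
    score_names: Sequence[str] | None = None,
    disease_order: Sequence[str] | None = None,
) -> ThreeSourceModel:
    """Train the three-source model (scores + PPI network + disease associations)."""
    R = np.asarray(R_VS, dtype=float)
    Rd = np.asarray(R_VD, dtype=float)
    Yv = np.asarray(Y, dtype=float).reshape(-1, 1)
    m, n = R.shape
    if Rd.shape[0] != m:
        raise ValidationError("R_VS and R_VD row counts differ")
    n_D = Rd.shape[1]
    if hp.k_D > max(n_D, 1):
        raise ValidationError(f"k_D={hp.k_D} exceeds number of diseases {n_D}")
    deg_V, W_V = _lap_split(L_V, m)
    deg_S, W_S = _lap_split(L_S, n)
    deg_D, W_D = _lap_split(L_D, n_D)
    g1, g2, g3, eps = hp.gamma1, hp.gamma2, hp.gamma3, hp.eps
    dV = deg_V[:, None]
    dS = deg_S[:, None]
    dD = deg_D[:, None]

    def run(seed: int):
        V, U1, S, G = init_factors(R, hp.k_V, hp.k_S, seed, p=hp.init_p, eps=eps)
        rng = np.random.default_rng(seed + 1)
        U2 = 1.0 - rng.random((hp.k_V, hp.k_D)) + eps
        D = _acol_columns(Rd.T, hp.k_D, hp.init_p, rng) + eps

        trace = [
            objective_three_source(R, Rd, Yv, V, U1, U2, S, D, G,
                                   L_V, L_S, L_D, g1, g2, g3)
        ]
        _check_finite(trace[0])
        for _ in range(hp.max_iter):
            num = R @ S @ U1.T + Rd @ D @ U2.T + Yv @ G @ U1.T + g1 * (W_V @ V)
            den = V @ (
                U1 @ (S.T @ S) @ U1.T
                + U2 @ (D.T @ D) @ U2.T
                + U1 @ (G.T @ G) @ U1.T
            ) + g1 * (dV * V)
            V = V * num / (den + eps)

            VtV = V.T @ V
            num = V.T @ R @ S + V.T @ Yv @ G
            den = VtV @ U1 @ (S.T @ S + G.T @ G)
            U1 = U1 * num / (den + eps)

            num = V.T @ Rd @ D
            den = VtV @ U2 @ (D.T @ D)
            U2 = U2 * num / (den + eps)

            num = R.T @ V @ U1 + g2 * (W_S @ S)
            den = S @ (U1.T @ VtV @ U1) + g2 * (dS * S)
            S = S * num / (den + eps)

            num = Rd.T @ V @ U2 + g3 * (W_D @ D)
            den = D @ (U2.T @ VtV @ U2) + g3 * (dD * D)
            D = D * num / (den + eps)

            num = Yv.T @ V @ U1
            den = G @ (U1.T @ VtV @ U1)
            G = G * num / (den + eps)

            trace.append(
                objective_three_source(R, Rd, Yv, V, U1, U2, S, D, G,
                                       L_V, L_S, L_D, g1, g2, g3)
            )
            _check_finite(trace[-1])
            if _converged(trace, hp.tol, eps):
                break
        return (V, U1, U2, S, D, G), trace

    best, trace = run(hp.seed)
    for r in range(1, hp.n_restarts):
        cand, cand_trace = run(hp.seed + 100003 * r)
        if cand_trace[-1] < trace[-1]:
            best, trace = cand, cand_trace
    V, U1, U2, S, D, G = best

    return ThreeSourceModel(
        V=V, U1=U1, U2=U2, S=S, D=D, G_Y=G,
        objective_trace=trace,
        hyperparams=hp,
        score_names=list(score_names) if score_names is not None else None,
        disease_order=list(disease_order) if disease_order is not None else None,
    )


# ---------------------------------------------------------------------------
# inference


def predict_two_source(
    model: TwoSourceModel,
    R_ts: np.ndarray,
    L_V_ts: LaplacianMatrix | None = None,
    hp: HyperParams | None = None,
) -> PredictionResult:
    """Score unseen variants with a trained two-source model.

    Minimizes the test objective ‖R_ts − V U Sᵀ‖²_F + γ₁ tr(Vᵀ L_Vts V) over
    the test-variant factor V (and, unless ``reuse_u``, over a warm-started
    copy of U) with S and G_Y frozen; returns y_score = V U G_Yᵀ.
    """
    hp = hp or model.hyperparams
    R = np.asarray(R_ts, dtype=float)
    if R.ndim != 2 or R.shape[1] != model.S.shape[0]:
        raise ValidationError(
            f"test relation matrix has {R.shape[-1] if R.ndim == 2 else '?'} score "
            f"columns, model expects {model.S.shape[0]}"
        )
    m = R.shape[0]
    if m == 0:
        return PredictionResult(y_score=np.empty(0), V_ts=np.empty((0, hp.k_V)),
                                U_ts=model.U.copy(), objective_trace=[])
    S, G = model.S, model.G_Y
    deg_V, W_V = _lap_split(L_V_ts, m)
    g1, eps = hp.gamma1, hp.eps

    rng_seed = hp.seed + 7919  # distinct stream from training init
    V = _acol_columns(R, hp.k_V, min(hp.init_p, R.shape[1]),
                      np.random.default_rng(rng_seed)) + eps
    U = model.U.copy()

    def j_ts(Vc, Uc):
        j = float(np.sum((R - Vc @ Uc @ S.T) ** 2))
        if L_V_ts is not None:
            j += g1 * float(np.sum(Vc * (L_V_ts.matrix @ Vc)))
        return j

    trace = [j_ts(V, U)]
    _check_finite(trace[0])
    StS = S.T @ S
    dV = deg_V[:, None]
    for _ in range(hp.max_iter):
        num = R @ S @ U.T + g1 * (W_V @ V)
        den = V @ (U @ StS @ U.T) + g1 * (dV * V)
        V = V * num / (den + eps)
        if not hp.reuse_u:
            num = V.T @ R @ S
            den = (V.T @ V) @ U @ StS
            U = U * num / (den + eps)
        trace.append(j_ts(V, U))
        _check_finite(trace[-1])
        if _converged(trace, hp.tol, eps):
            break

    y = (V @ U @ G.T).ravel()
    return PredictionResult(y_score=y, V_ts=V, U_ts=U, objective_trace=trace,
                            threshold=model.threshold)


def predict_three_source(
    model: ThreeSourceModel,
    R_VS_ts: np.ndarray,
    R_VD_ts: np.ndarray,
    L_V_ts: LaplacianMatrix | None = None,
    hp: HyperParams | None = None,
) -> PredictionResult:
    """Score unseen variants with a trained three-source model.

    S, D and G_Y are frozen; V (and warm-started U₁, U₂) are fitted to
    ‖R_VS − VU₁Sᵀ‖² + ‖R_VD − VU₂Dᵀ‖² + γ₁ tr(Vᵀ L_Vts V); the returned
    score is y = V U₁ G_Yᵀ.
    """
    hp = hp or model.hyperparams
    R = np.asarray(R_VS_ts, dtype=float)
    Rd = np.asarray(R_VD_ts, dtype=float)
    if R.ndim != 2 or R.shape[1] != model.S.shape[0]:
        raise ValidationError("test score columns do not match the trained model")
    if Rd.ndim != 2 or Rd.shape[1] != model.D.shape[0]:
        raise ValidationError(
            f"test disease columns ({Rd.shape[-1] if Rd.ndim == 2 else '?'}) "
            f"do not match the trained model ({model.D.shape[0]})"
        )
    if Rd.shape[0] != R.shape[0]:
        raise ValidationError("R_VS and R_VD test row counts differ")
    m = R.shape[0]
    if m == 0:
        return PredictionResult(y_score=np.empty(0), V_ts=np.empty((0, hp.k_V)),
                                U_ts=model.U1.copy(), U2_ts=model.U2.copy(),
                                objective_trace=[])
    S, D, G = model.S, model.D, model.G_Y
    deg_V, W_V = _lap_split(L_V_ts, m)
    g1, eps = hp.gamma1, hp.eps

    V = _acol_columns(R, hp.k_V, min(hp.init_p, R.shape[1]),
                      np.random.default_rng(hp.seed + 7919)) + eps
    U1 = model.U1.copy()
    U2 = model.U2.copy()

    def j_ts(Vc, U1c, U2c):
        j = float(np.sum((R - Vc @ U1c @ S.T) ** 2))
        j += float(np.sum((Rd - Vc @ U2c @ D.T) ** 2))
        if L_V_ts is not None:
            j += g1 * float(np.sum(Vc * (L_V_ts.matrix @ Vc)))
        return j

    trace = [j_ts(V, U1, U2)]
    _check_finite(trace[0])
    StS = S.T @ S
    DtD = D.T @ D
    dV = deg_V[:, None]
    for _ in range(hp.max_iter):
        num = R @ S @ U1.T + Rd @ D @ U2.T + g1 * (W_V @ V)
        den = V @ (U1 @ StS @ U1.T + U2 @ DtD @ U2.T) + g1 * (dV * V)
        V = V * num / (den + eps)
        if not hp.reuse_u:
            VtV = V.T @ V
            num = V.T @ R @ S
            den = VtV @ U1 @ StS
            U1 = U1 * num / (den + eps)
            num = V.T @ Rd @ D
            den = VtV @ U2 @ DtD
            U2 = U2 * num / (den + eps)
        trace.append(j_ts(V, U1, U2))
        _check_finite(trace[-1])
        if _converged(trace, hp.tol, eps):
            break

    y = (V @ U1 @ G.T).ravel()
    return PredictionResult(y_score=y, V_ts=V, U_ts=U1, U2_ts=U2,
                            objective_trace=trace, threshold=model.threshold)


# ---------------------------------------------------------------------------
# hyper-parameter search

#: Default search ranges; override any subset via the ``grid`` argument.
DEFAULT_GRID: dict[str, tuple] = {
    "k_V": (5, 10, 20, 50),
    "k_S": (2, 3, 5),
    "gamma1": (0.01, 0.1, 1.0, 10.0),
    "gamma2": (0.01, 0.1, 1.0, 10.0),
}


def grid_search(
    bundle,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    base: HyperParams | None = None,
    seed: int = 0,
):
    """Pick the hyper-parameter combination maximizing mean gene-aware CV AUC.

    ``bundle`` is an :class:`~snmtfvar.evaluation.Bundle`. Returns
    ``(best HyperParams, results)`` where results is a list of dicts (one per
    grid point, with the mean AUC). Ties break toward the first point in
    deterministic grid order.
    """
    from . import evaluation  # deferred: evaluation drives the CV loop

    if grid is None:
        grid = DEFAULT_GRID
    if not grid:
        raise ValidationError("empty hyper-parameter grid")
    base = base or HyperParams(seed=seed)
    keys = list(grid)
    results = []
    best = None
    best_auc = -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        hp = replace(base, **dict(zip(keys, combo)), seed=seed)
        summary = evaluation.cross_validate(bundle, hp, k=folds, repeats=1, seed=seed)
        auc = summary.mean["AUC"]
        results.append({**dict(zip(keys, combo)), "mean_auc": auc})
        if auc > best_auc:
            best_auc = auc
            best = hp
    return best, results


# ---------------------------------------------------------------------------
# serialization


def _hp_to_dict(hp: HyperParams) -> dict:
    return asdict(hp)


def save_model(model: TwoSourceModel | ThreeSourceModel, directory) -> None:
    """Write factor matrices as MatrixMarket files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, TwoSourceModel):
        kind = "two_source"
        factors = {"V": model.V, "U": model.U, "S": model.S, "G_Y": model.G_Y}
    else:
        kind = "three_source"
        factors = {"V": model.V, "U1": model.U1, "U2": model.U2,
                   "S": model.S, "D": model.D, "G_Y": model.G_Y}
    for name, mat in factors.items():
        scipy.io.mmwrite(str(directory / f"{name}.mtx"), np.asarray(mat))
    manifest = {
        "model_type": kind,
        "hyperparams": _hp_to_dict(model.hyperparams),
        "score_names": model.score_names,
        "disease_order": getattr(model, "disease_order", None),
        "objective_trace": [float(x) for x in model.objective_trace],
        "threshold": model.threshold,
        "factors": sorted(factors),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_model(directory) -> TwoSourceModel | ThreeSourceModel:
    """Inverse of :func:`save_model`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    hp = HyperParams(**manifest["hyperparams"])
    load = lambda name: np.asarray(scipy.io.mmread(str(directory / f"{name}.mtx")))
    common = dict(
        objective_trace=list(manifest["objective_trace"]),
        hyperparams=hp,
        score_names=manifest["score_names"],
        threshold=manifest["threshold"],
    )
    if manifest["model_type"] == "two_source":
        return TwoSourceModel(V=load("V"), U=load("U"), S=load("S"), G_Y=load("G_Y"),
                              **common)
    return ThreeSourceModel(V=load("V"), U1=load("U1"), U2=load("U2"), S=load("S"),
                            D=load("D"), G_Y=load("G_Y"),
                            disease_order=manifest["disease_order"], **common)
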