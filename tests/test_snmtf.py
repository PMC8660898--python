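import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from snmtfvar import (
    HyperParams,
    ValidationError,
    WeightedGraph,
    fit_three_source,
    fit_two_source,
    grid_search,
    init_factors,
    laplacian,
    load_model,
    objective_three_source,
    objective_two_source,
    predict_three_source,
    predict_two_source,
    save_model,
)
from snmtfvar import auc as rank_auc
from snmtfvar import evaluation, gene_aware_folds, to_bundle


def random_laplacian(n, seed):
    rng = np.random.default_rng(seed)
    A = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.4), k=1)
    G = WeightedGraph(node_ids=[str(i) for i in range(n)], W=sp.csr_matrix(A + A.T))
    return laplacian(G)


def planted_two_source(m=60, n=9, k_v=4, k_s=3, seed=0):
    """Exactly factorizable R and binary Y sharing the variant clusters."""
    rng = np.random.default_rng(seed)
    cluster = rng.integers(0, k_v, size=m)
    V = np.zeros((m, k_v))
    V[np.arange(m), cluster] = 1.0
    U = np.zeros((k_v, k_s))
    U[: k_v // 2, 0] = 1.0  # deleterious clusters load on the first column
    U[k_v // 2:, 1] = 1.0
    U += 0.2 * rng.random((k_v, k_s))
    S = rng.random((n, k_s))
    G = np.zeros((1, k_s))
    G[0, 0] = 1.0
    Uy = np.zeros((k_v, k_s))
    Uy[: k_v // 2, 0] = 1.0
    R = V @ U @ S.T
    R /= R.max()
    Y = (V @ Uy @ G.T).ravel()  # exactly 1 on deleterious clusters, 0 elsewhere
    return R, Y, cluster


class TestInitFactors:
    def test_constant_matrix_gives_constant_columns(self):
        V0, U0, S0, G0 = init_factors(np.ones((8, 5)), 3, 2, seed=0)
        assert np.allclose(V0, 1.0, atol=1e-8)
        assert np.allclose(S0, 1.0, atol=1e-8)
        assert np.all(U0 > 0) and np.all(G0 > 0)

    def test_deterministic_under_seed(self):
        R = np.random.default_rng(1).random((10, 6))
        a = init_factors(R, 4, 3, seed=42)
        b = init_factors(R, 4, 3, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_p_one_columns_are_data_columns(self):
        R = np.random.default_rng(2).random((10, 6))
        V0, _, S0, _ = init_factors(R, 3, 2, seed=5, p=1)
        for j in range(3):
            assert any(np.allclose(V0[:, j], R[:, c], atol=1e-8) for c in range(6))
        for j in range(2):
            assert any(np.allclose(S0[:, j], R[i, :], atol=1e-8) for i in range(10))

    def test_rank_exceeding_dimension_rejected(self):
        with pytest.raises(ValidationError):
            init_factors(np.ones((3, 4)), 5, 2, seed=0)


class TestObjectives:
    def test_exact_factorization_is_zero(self):
        rng = np.random.default_rng(0)
        V, U, S, G = rng.random((6, 2)), rng.random((2, 3)), rng.random((4, 3)), rng.random((1, 3))
        R = V @ U @ S.T
        Y = (V @ U @ G.T).ravel()
        assert objective_two_source(R, Y, V, U, S, G) == pytest.approx(0.0)

    def test_zero_factors_give_squared_norms(self):
        rng = np.random.default_rng(1)
        R = rng.random((5, 4))
        Y = rng.integers(0, 2, 5).astype(float)
        j = objective_two_source(R, Y, np.zeros((5, 2)), np.zeros((2, 2)),
                                 np.zeros((4, 2)), np.zeros((1, 2)))
        assert j == pytest.approx(np.sum(R**2) + np.sum(Y**2))

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(2)
        m, n, nd, kv, ks, kd = 7, 5, 4, 3, 2, 2
        R, Rd = rng.random((m, n)), rng.random((m, nd))
        Y = rng.integers(0, 2, m).astype(float)
        V, U1, U2 = rng.random((m, kv)), rng.random((kv, ks)), rng.random((kv, kd))
        S, D, G = rng.random((n, ks)), rng.random((nd, kd)), rng.random((1, ks))
        LV, LS, LD = (random_laplacian(m, 3), random_laplacian(n, 4),
                      random_laplacian(nd, 5))
        g1, g2, g3 = 0.3, 0.7, 1.1

        # brute force, term by term, scalar loops
        def fro2(A, B):
            return sum((A[i, j] - B[i, j]) ** 2
                       for i in range(A.shape[0]) for j in range(A.shape[1]))

        expected = fro2(R, V @ U1 @ S.T)
        expected += fro2(Y.reshape(-1, 1), V @ U1 @ G.T)
        expected += fro2(Rd, V @ U2 @ D.T)
        for L, X, g in ((LV, V, g1), (LS, S, g2), (LD, D, g3)):
            expected += g * np.trace(X.T @ L.matrix.toarray() @ X)
        got = objective_three_source(R, Rd, Y, V, U1, U2, S, D, G,
                                     LV, LS, LD, g1, g2, g3)
        assert got == pytest.approx(expected)

    def test_three_source_reduces_to_two_source(self):
        rng = np.random.default_rng(3)
        m, n, kv, ks = 6, 4, 3, 2
        R = rng.random((m, n))
        Y = rng.integers(0, 2, m).astype(float)
        V, U, S, G = rng.random((m, kv)), rng.random((kv, ks)), rng.random((n, ks)), rng.random((1, ks))
        j2 = objective_two_source(R, Y, V, U, S, G)
        j3 = objective_three_source(R, np.zeros((m, 3)), Y, V, U,
                                    np.zeros((kv, 2)), S, np.zeros((3, 2)), G)
        assert j3 == pytest.approx(j2)

    def test_quadratic_homogeneity(self):
        # doubling data and the reconstruction scales the objective by 4
        rng = np.random.default_rng(4)
        R = rng.random((5, 4))
        Y = rng.integers(0, 2, 5).astype(float)
        V, U, S, G = rng.random((5, 2)), rng.random((2, 2)), rng.random((4, 2)), rng.random((1, 2))
        j1 = objective_two_source(R, Y, V, U, S, G)
        j2 = objective_two_source(2 * R, 2 * Y, V, 2 * U, S, G)
        assert j2 == pytest.approx(4 * j1)


class TestFitTwoSource:
    def test_zero_iterations_returns_initialization(self, fast_hp):
        R, Y, _ = planted_two_source(seed=1)
        hp = dataclasses.replace(fast_hp, max_iter=0)
        model = fit_two_source(R, Y, None, None, hp)
        V0, U0, S0, G0 = init_factors(R, hp.k_V, hp.k_S, hp.seed, p=hp.init_p,
                                      eps=hp.eps)
        assert len(model.objective_trace) == 1
        assert np.array_equal(model.V, V0)
        assert np.array_equal(model.G_Y, G0)

    def test_planted_structure_recovered(self):
        R, Y, _ = planted_two_source(seed=2)
        hp = HyperParams(k_V=4, k_S=3, gamma1=0, gamma2=0, tol=1e-12,
                         max_iter=2000, n_restarts=3, seed=0)
        model = fit_two_source(R, Y, None, None, hp)
        assert model.objective_trace[-1] < 1e-3 * model.objective_trace[0]

    def test_monotone_nonincreasing_objective(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            m, n = int(rng.integers(15, 60)), 9
            R = rng.random((m, n))
            Y = (rng.random(m) < 0.4).astype(float)
            hp = HyperParams(k_V=5, k_S=3, gamma1=float(rng.choice([0, 0.1, 1, 10])),
                             gamma2=float(rng.choice([0, 0.1, 1, 10])),
                             max_iter=50, n_restarts=1, seed=trial)
            model = fit_two_source(R, Y, random_laplacian(m, trial),
                                   random_laplacian(n, trial + 50), hp)
            t = np.array(model.objective_trace)
            assert np.all(t[1:] <= t[:-1] * (1 + 1e-9))
            assert model.objective_trace[-1] <= model.objective_trace[0]

    def test_factors_stay_nonnegative(self, fast_hp):
        R, Y, _ = planted_two_source(seed=3)
        model = fit_two_source(R, Y, random_laplacian(R.shape[0], 9),
                               random_laplacian(R.shape[1], 10), fast_hp)
        for X in (model.V, model.U, model.S, model.G_Y):
            assert np.all(X >= 0)

    def test_label_length_mismatch_rejected(self, fast_hp):
        with pytest.raises(ValidationError):
            fit_two_source(np.ones((5, 4)), np.ones(4), None, None, fast_hp)


class TestPredictTwoSource:
    def test_self_prediction_consistency(self):
        R, Y, _ = planted_two_source(m=80, seed=4)
        hp = HyperParams(k_V=4, k_S=3, gamma1=0, gamma2=0, seed=1, n_restarts=2)
        model = fit_two_source(R, Y, None, None, hp)
        train_auc = rank_auc(Y, model.train_scores())
        pred = predict_two_source(model, R, None, hp)
        assert rank_auc(Y, pred.y_score) >= train_auc - 0.05

    def test_zero_row_predicts_zero_without_regularization(self):
        R, Y, _ = planted_two_source(seed=5)
        hp = HyperParams(k_V=4, k_S=3, gamma1=0, gamma2=0, seed=0, n_restarts=1)
        model = fit_two_source(R, Y, None, None, hp)
        pred = predict_two_source(model, np.zeros((1, R.shape[1])), None, hp)
        assert pred.y_score[0] == pytest.approx(0.0, abs=1e-6)

    def test_column_count_mismatch_rejected(self, fast_hp):
        R, Y, _ = planted_two_source(seed=6)
        model = fit_two_source(R, Y, None, None, fast_hp)
        with pytest.raises(ValidationError):
            predict_two_source(model, np.ones((3, R.shape[1] + 1)), None, fast_hp)

    def test_empty_test_set(self, fast_hp):
        R, Y, _ = planted_two_source(seed=7)
        model = fit_two_source(R, Y, None, None, fast_hp)
        pred = predict_two_source(model, np.empty((0, R.shape[1])), None, fast_hp)
        assert pred.y_score.shape == (0,)


class TestThreeSource:
    def test_planted_structure_recovered(self):
        rng = np.random.default_rng(8)
        R, Y, cluster = planted_two_source(seed=8)
        m = R.shape[0]
        D = rng.random((10, 2))
        U2 = rng.random((4, 2))
        V = np.zeros((m, 4))
        V[np.arange(m), cluster] = 1.0
        Rd = V @ U2 @ D.T
        Rd /= Rd.max()
        hp = HyperParams(k_V=4, k_S=3, k_D=2, gamma1=0, gamma2=0, gamma3=0,
                         tol=1e-12, max_iter=3000, n_restarts=3, seed=0)
        model = fit_three_source(R, Rd, Y, None, None, None, hp)
        assert model.objective_trace[-1] < 1e-3 * model.objective_trace[0]

    def test_zero_disease_matrix_matches_two_source(self):
        R, Y, _ = planted_two_source(seed=9)
        hp = HyperParams(k_V=4, k_S=3, k_D=2, gamma1=0.1, gamma2=0.1, gamma3=0,
                         max_iter=60, n_restarts=1, seed=3)
        LV = random_laplacian(R.shape[0], 11)
        LS = random_laplacian(R.shape[1], 12)
        m2 = fit_two_source(R, Y, LV, LS, hp)
        m3 = fit_three_source(R, np.zeros((R.shape[0], 6)), Y, LV, LS, None, hp)
        assert np.allclose(m2.V, m3.V, atol=1e-6)

    def test_monotone_objective_including_prediction(self):
        rng = np.random.default_rng(10)
        m, n, nd = 40, 9, 12
        R, Rd = rng.random((m, n)), (rng.random((m, nd)) < 0.3).astype(float)
        Y = (rng.random(m) < 0.4).astype(float)
        hp = HyperParams(k_V=5, k_S=3, k_D=3, max_iter=50, n_restarts=1, seed=0)
        model = fit_three_source(R, Rd, Y, random_laplacian(m, 1),
                                 random_laplacian(n, 2), random_laplacian(nd, 3), hp)
        pred = predict_three_source(model, rng.random((10, n)),
                                    (rng.random((10, nd)) < 0.3).astype(float),
                                    random_laplacian(10, 4), hp)
        for trace in (model.objective_trace, pred.objective_trace):
            t = np.array(trace)
            assert np.all(t[1:] <= t[:-1] * (1 + 1e-9))

    def test_zero_disease_row_prediction_driven_by_scores(self):
        R, Y, _ = planted_two_source(m=50, seed=11)
        rng = np.random.default_rng(11)
        Rd = (rng.random((50, 8)) < 0.3).astype(float)
        hp = HyperParams(k_V=4, k_S=3, k_D=2, gamma1=0, gamma2=0, gamma3=0,
                         n_restarts=1, seed=2)
        model = fit_three_source(R, Rd, Y, None, None, None, hp)
        row = R[:1]
        with_term = predict_three_source(model, row, np.zeros((1, 8)), None, hp)
        # ablation: score through the two-source path with the same U1, S,
        # G_Y. The all-zero disease row still enters the V update through
        # the U2 D'D U2' denominator, so exact equality is not expected,
        # but the prediction must be score-driven to within 1% relative.
        from snmtfvar.snmtf import TwoSourceModel
        two = TwoSourceModel(V=model.V, U=model.U1, S=model.S, G_Y=model.G_Y,
                             objective_trace=[], hyperparams=hp)
        without_term = predict_two_source(two, row, None, hp)
        assert with_term.y_score[0] == pytest.approx(without_term.y_score[0], rel=0.01)

    def test_disease_column_mismatch_rejected(self, fast_hp):
        R, Y, _ = planted_two_source(seed=12)
        Rd = np.zeros((R.shape[0], 5))
        model = fit_three_source(R, Rd, Y, None, None, None, fast_hp)
        with pytest.raises(ValidationError):
            predict_three_source(model, R[:3], np.zeros((3, 7)), None, fast_hp)


class TestRegularizationAndSupervision:
    def test_laplacian_penalty_pulls_neighbors_together(self):
        # two-block V-V graph; stronger gamma1 must shrink the summed
        # squared factor differences across edges
        rng = np.random.default_rng(13)
        m = 40
        blocks = np.repeat([0, 1], m // 2)
        W = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if blocks[i] == blocks[j] and rng.random() < 0.4:
                    W[i, j] = W[j, i] = 1.0
        G = WeightedGraph(node_ids=[str(i) for i in range(m)], W=sp.csr_matrix(W))
        L = laplacian(G)
        R = rng.random((m, 9))
        Y = (blocks == 0).astype(float)

        def edge_smoothness(gamma):
            hp = HyperParams(k_V=4, k_S=3, gamma1=gamma, gamma2=0,
                             max_iter=300, n_restarts=1, seed=0)
            model = fit_two_source(R, Y, L, None, hp)
            V = model.V / max(np.linalg.norm(model.V), 1e-12)
            return sum(W[i, j] * np.sum((V[i] - V[j]) ** 2)
                       for i in range(m) for j in range(i + 1, m) if W[i, j])

        values = [edge_smoothness(g) for g in (0.0, 0.1, 1.0, 10.0)]
        assert values[-1] < values[0]
        assert all(b <= a * 1.05 for a, b in zip(values, values[1:]))

    def test_supervision_improves_heldout_auc(self, small_dataset):
        bundle = to_bundle(small_dataset)
        sup, unsup = [], []
        for seed in range(10):
            assign = gene_aware_folds(bundle.table.records, 4, seed)
            test = assign.variant_fold == 0
            row, _ = evaluation.fit_fold(bundle, ~test, test,
                                         HyperParams(seed=seed, n_restarts=2))
            sup.append(row["AUC"])
            # same split, labels zeroed during training
            blank = dataclasses.replace(bundle)
            blank.labels = np.zeros_like(bundle.labels)
            tr_idx, ts_idx = ~test, test
            import snmtfvar.ingest as ingest
            import snmtfvar.networks as nets
            import snmtfvar.snmtf as snmtf
            tr = bundle.table.subset(tr_idx)
            ts = bundle.table.subset(ts_idx)
            omap = ingest.fit_orientation(tr, bundle.flip_set)
            R_tr = ingest.normalize_scores(tr, omap)
            R_ts = ingest.normalize_scores(ts, omap)
            L_V_tr = nets.laplacian(nets.build_variant_network(tr.records, bundle.ppi, bundle.gene_map))
            L_V_ts = nets.laplacian(nets.build_variant_network(ts.records, bundle.ppi, bundle.gene_map))
            L_S = nets.laplacian(nets.build_score_network(R_tr, tr.score_names))
            model = snmtf.fit_two_source(R_tr, np.zeros(tr_idx.sum()), L_V_tr, L_S,
                                         HyperParams(seed=seed, n_restarts=2))
            pred = snmtf.predict_two_source(model, R_ts, L_V_ts)
            y_ts = bundle.labels[ts_idx]
            if len(set(y_ts)) == 2:
                unsup.append(rank_auc(y_ts, pred.y_score))
                continue
            unsup.append(np.nan)
        assert np.nanmean(sup) > np.nanmean(unsup)


class TestGridSearchAndSerialization:
    def test_single_point_grid_returns_that_point(self, small_bundle):
        base = HyperParams(max_iter=30, n_restarts=1)
        best, results = grid_search(small_bundle, {"k_V": [4], "gamma1": [0.5]},
                                    folds=3, base=base, seed=0)
        assert best.k_V == 4 and best.gamma1 == 0.5
        assert len(results) == 1

    def test_deterministic_under_seed(self, small_bundle):
        base = HyperParams(max_iter=30, n_restarts=1)
        grid = {"k_V": [3, 4]}
        a = grid_search(small_bundle, grid, folds=3, base=base, seed=1)
        b = grid_search(small_bundle, grid, folds=3, base=base, seed=1)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_model_roundtrip_two_source(self, tmp_path, fast_hp):
        R, Y, _ = planted_two_source(seed=14)
        model = fit_two_source(R, Y, None, None, fast_hp,
                               score_names=[f"s{i}" for i in range(R.shape[1])])
        model.threshold = 0.4
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.allclose(back.V, model.V)
        assert back.hyperparams == model.hyperparams
        assert back.score_names == model.score_names
        assert back.threshold == pytest.approx(0.4)

    def test_model_roundtrip_three_source(self, tmp_path, fast_hp):
        R, Y, _ = planted_two_source(seed=15)
        Rd = (np.random.default_rng(15).random((R.shape[0], 6)) < 0.3).astype(float)
        model = fit_three_source(R, Rd, Y, None, None, None, fast_hp,
                                 disease_order=[f"d{i}" for i in range(6)])
        save_model(model, tmp_path / "m3")
        back = load_model(tmp_path / "m3")
        assert np.allclose(back.D, model.D)
        assert back.disease_order == model.disease_order
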