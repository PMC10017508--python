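"""Autodiff correctness, niche embeddings, training-loop contracts."""

import numpy as np
import pytest

from ncem import (
    NicheEncoderConfig,
    NonlinearNCEM,
    TrainingConfig,
    build_graph,
    gcn_embed,
    indicator_embed,
    sender_presence,
    simulate_dependency,
    split_nodes,
    SimulationConfig,
)
from ncem.autodiff import Adam, Tensor, concat, sparse_matmul
from ncem.neural import fit_nl_ncem, train


class TestAutodiff:
    def test_gradients_match_finite_differences(self, rng):
        w = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        x = rng.normal(size=(5, 4))
        y = rng.normal(size=(5, 3))

        def f(wdata):
            h = np.maximum(x @ wdata, 0.0)
            e = np.exp(h - h.max(axis=1, keepdims=True))
            s = e / e.sum(axis=1, keepdims=True)
            return ((s - y) ** 2).mean()

        loss = (((Tensor(x) @ w).relu().softmax(axis=1) - y) ** 2.0).mean()
        loss.backward()
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                wp = w.data.copy()
                wp[i, j] += eps
                wm = w.data.copy()
                wm[i, j] -= eps
                num = (f(wp) - f(wm)) / (2 * eps)
                assert w.grad[i, j] == pytest.approx(num, abs=1e-5)

    def test_concat_and_sparse_matmul_backward(self, rng):
        from scipy.sparse import csr_matrix

        a = csr_matrix(rng.random((6, 4)) < 0.5).astype(float)
        x = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        z = Tensor(rng.normal(size=(6, 1)), requires_grad=True)
        out = concat([sparse_matmul(a, x), z], axis=1).sum()
        out.backward()
        assert np.allclose(x.grad, np.asarray(a.sum(axis=0)).T @ np.ones((1, 2)))
        assert np.allclose(z.grad, 1.0)

    def test_adam_descends_a_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(500):
            opt.zero_grad()
            loss = (p**2.0).sum()
            loss.backward()
            opt.step()
        assert np.all(np.abs(p.data) < 1e-2)


class TestEmbeddings:
    def test_gcn_identity_weights_highlight_neighbour_type(self):
        # node 0's neighbours are all type 1 (of 2)
        abar = np.array([[0.0, 0.5, 0.5], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        xl = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        emb = gcn_embed(abar, xl, np.eye(2))
        assert emb[0, 1] > emb[0, 0]

    def test_zero_weights_give_uniform_embedding(self, rng):
        abar = rng.random((4, 4))
        xl = np.eye(4)[:, :2].repeat(2, axis=1)[:, :3]
        emb = gcn_embed(abar, np.eye(4)[:, :3], np.zeros((3, 5)))
        assert np.allclose(emb, 0.2)

    def test_rows_sum_to_one_and_isolated_uniform(self, rng):
        abar = np.zeros((3, 3))
        abar[0, 1] = 1.0
        emb = gcn_embed(abar, rng.random((3, 2)), rng.normal(size=(2, 4)))
        assert np.allclose(emb.sum(axis=1), 1.0)
        assert np.allclose(emb[2], 0.25)  # isolated node

    def test_indicator_embedding_is_sender_presence(self, dependency_data):
        ds, _, graph, _ = dependency_data
        xl = ds.type_onehot()
        assert np.array_equal(indicator_embed(graph, xl), sender_presence(graph, xl))


@pytest.fixture(scope="module")
def small_problem():
    cfg = SimulationConfig(n_cells=250, n_genes=12, seed=40)
    ds, _ = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    splits = split_nodes(ds, 0)
    return ds, graph, splits


class TestNonlinearModel:
    def test_permuting_cells_permutes_predictions(self, small_problem):
        ds, graph, _ = small_problem
        model = NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), seed=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_cells)
        assert np.allclose(model.predict(perm), model.predict()[perm])

    def test_same_seed_same_predictions(self, small_problem):
        ds, graph, _ = small_problem
        a = NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), seed=3)
        b = NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), seed=3)
        assert np.array_equal(a.predict(), b.predict())

    def test_nonspatial_baseline_ignores_resolution(self, small_problem):
        ds, graph, _ = small_problem
        small = build_graph(ds, 10.0)
        a = NonlinearNCEM(ds, small, NicheEncoderConfig(depth=1), spatial=False, seed=2)
        b = NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), spatial=False, seed=2)
        assert np.array_equal(a.predict(), b.predict())

    def test_spatial_model_beats_nonspatial_on_planted_data(self, small_problem):
        ds, graph, splits = small_problem
        tc = TrainingConfig(max_epochs=600, learning_rate=0.05, nodes_per_image=400)
        wins = 0
        for seed in range(3):
            _, _, s_sp = fit_nl_ncem(ds, graph, NicheEncoderConfig(depth=0),
                                     tc, splits=splits, seed=seed)
            _, _, s_ns = fit_nl_ncem(ds, None, NicheEncoderConfig(depth=1),
                                     tc, splits=splits, spatial=False, seed=seed)
            wins += s_sp["test_r2"] > s_ns["test_r2"]
        assert wins >= 2


class TestTrainingLoop:
    def _model(self, small_problem, seed=0):
        ds, graph, splits = small_problem
        return NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), seed=seed), splits

    def test_early_stopping_bounds_epoch_count(self, small_problem):
        model, splits = self._model(small_problem)
        # a zero learning rate never improves validation after epoch 0
        cfg = TrainingConfig(learning_rate=1e-30, max_epochs=400,
                             early_stopping_patience=100, nodes_per_image=64)
        hist = train(model, splits, cfg)
        assert len(hist.epochs) <= 101 + 1

    def test_scheduler_halves_learning_rate_on_plateau(self, small_problem):
        model, splits = self._model(small_problem)
        cfg = TrainingConfig(learning_rate=1e-30, max_epochs=60,
                             scheduler_patience=20, early_stopping_patience=100,
                             nodes_per_image=64)
        hist = train(model, splits, cfg)
        lrs = hist.learning_rates()
        assert lrs[0] == pytest.approx(1e-30)
        assert lrs[-1] < lrs[0]  # halved at least once after the plateau

    def test_identical_seeds_reproduce_losses(self, small_problem):
        ds, graph, splits = small_problem
        cfg = TrainingConfig(learning_rate=0.05, max_epochs=30, nodes_per_image=64)
        runs = []
        for _ in range(2):
            model = NonlinearNCEM(ds, graph, NicheEncoderConfig(depth=1), seed=9)
            runs.append(train(model, splits, cfg).epochs["train_loss"].to_numpy())
        assert np.array_equal(runs[0], runs[1])

    def test_empty_validation_rejected(self, small_problem):
        model, splits = self._model(small_problem)
        import copy

        bad = copy.deepcopy(splits)
        bad.role[bad.role == "validation"] = "train"
        with pytest.raises(ValueError):
            train(model, bad, TrainingConfig(max_epochs=5))

    def test_grid_selection_prefers_best_validation(self, small_problem):
        ds, graph, splits = small_problem
        tc = TrainingConfig(max_epochs=150, nodes_per_image=256)
        model, hist, summary = fit_nl_ncem(ds, graph, NicheEncoderConfig(depth=1), tc,
                                           lr_grid=[0.05, 0.005], splits=splits, seed=1)
        grid = summary["grid"]
        # the selected model carries the best validation R2 of the grid
        from ncem import r_squared

        mu = ds.expression[splits.train].mean(axis=0)
        _, val_r2 = r_squared(ds.expression[splits.validation],
                              model.predict(splits.validation), mu)
        assert val_r2 == pytest.approx(grid["val_r2"].max())


class TestLinearSubsumption:
    def test_zero_depth_indicator_matches_ols_linear_model(self, small_problem):
        from ncem import build_design, fit_ols, r_squared
        from ncem.linear import DesignMatrix

        ds, graph, splits = small_problem
        tc = TrainingConfig(max_epochs=4000, learning_rate=0.05, nodes_per_image=400)
        _, _, summary = fit_nl_ncem(ds, graph, NicheEncoderConfig(depth=0), tc,
                                    splits=splits, seed=0)
        d = build_design(ds, graph, "interaction")
        tr, te = splits.train, splits.test
        sub = DesignMatrix(d.values[tr], d.column_provenance, d.model_variant,
                           d.type_levels, d.domain_levels)
        fit = fit_ols(sub, ds.expression[tr])
        mu = ds.expression[tr].mean(axis=0)
        _, pooled = r_squared(ds.expression[te], d.values[te] @ fit.coefficients, mu)
        assert abs(summary["test_r2"] - pooled) < 0.01
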