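"""Design matrices, OLS fitting, Wald inference, likelihood and R2."""

import numpy as np
import pytest
from scipy import stats
from scipy.sparse import csr_matrix

from ncem import (
    SpatialDataset,
    build_design,
    build_graph,
    fit_ols,
    gaussian_ll,
    r_squared,
    resolution_screen,
    sender_presence,
    simulate_dependency,
    simulate_null,
    split_nodes,
    wald_test,
    SimulationConfig,
)
from ncem.core import CellGraph
from ncem.linear import DesignMatrix


def _graph_from_edges(n, edges, resolution=10.0):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return CellGraph(adjacency=csr_matrix(a), resolution=resolution)


def _random_design(rng, n=50, p=7):
    x = rng.normal(size=(n, p))
    return DesignMatrix(
        values=x,
        column_provenance=[("interaction", "A", "B")] * p,
        model_variant="interaction",
        type_levels=np.array(["A", "B"]),
        domain_levels=np.array(["i"]),
    )


class TestSenderPresence:
    def test_single_neighbor_marks_its_type(self):
        types = np.array([[1, 0], [0, 1]], dtype=float)  # A, B
        g = _graph_from_edges(2, [(0, 1)])
        xs = sender_presence(g, types)
        assert xs[0].tolist() == [0.0, 1.0]
        assert xs[1].tolist() == [1.0, 0.0]

    def test_isolated_cell_has_empty_niche(self):
        types = np.array([[1, 0], [0, 1], [1, 0]], dtype=float)
        g = _graph_from_edges(3, [(0, 1)])
        assert sender_presence(g, types)[2].tolist() == [0.0, 0.0]

    def test_three_clique_brute_force(self):
        # cells typed A, A, B all mutually adjacent
        types = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        g = _graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])
        xs = sender_presence(g, types)
        assert xs[0].tolist() == [1.0, 1.0]
        assert xs[1].tolist() == [1.0, 1.0]
        assert xs[2].tolist() == [1.0, 0.0]


class TestBuildDesign:
    def _two_cell_dataset(self):
        return SpatialDataset(
            expression=np.ones((2, 1)),
            coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
            cell_type=np.array(["A", "B"]),
            domain=np.array(["i", "i"]),
            gene_names=np.array(["g"]),
        )

    def test_interaction_row_is_receiver_major_outer_product(self):
        ds = self._two_cell_dataset()
        g = _graph_from_edges(2, [(0, 1)])
        d = build_design(ds, g, "interaction")
        # cell 0: type A with one B neighbour -> [1,0 | 0,1,0,0 | 1]
        assert d.values[0].tolist() == [1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0]
        assert d.column_provenance[3] == ("interaction", "A", "B")

    def test_baseline_width_is_types_plus_domains(self, dependency_data):
        ds, _, _, _ = dependency_data
        d = build_design(ds, None, "baseline")
        assert d.n_columns == ds.n_types + ds.n_domains

    def test_global_sender_width(self, dependency_data):
        ds, _, graph, _ = dependency_data
        d = build_design(ds, graph, "global_sender")
        assert d.n_columns == 2 * ds.n_types + ds.n_domains

    def test_empty_graph_reduces_interaction_to_baseline_fit(self):
        rng = np.random.default_rng(0)
        ds = SpatialDataset(
            expression=rng.uniform(0, 5, (30, 3)),
            coords=rng.uniform(0, 10, (30, 2)),
            cell_type=rng.choice(["A", "B"], 30),
            domain=np.array(["i"] * 30),
            gene_names=np.array(["g0", "g1", "g2"]),
        )
        g = _graph_from_edges(30, [])
        inter = fit_ols(build_design(ds, g, "interaction"), ds.expression)
        base = fit_ols(build_design(ds, None, "baseline"), ds.expression)
        assert np.allclose(inter.predict(), base.predict(), atol=1e-8)

    def test_unknown_variant_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            build_design(tiny_dataset, None, "fancy")


class TestFitOls:
    def test_exact_recovery_without_noise(self, rng):
        d = _random_design(rng)
        beta_true = rng.normal(size=(7, 3))
        fit = fit_ols(d, d.values @ beta_true)
        assert np.allclose(fit.coefficients, beta_true, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        d = _random_design(rng, n=50, p=7)
        y = d.values @ rng.normal(size=(7, 4)) + rng.normal(size=(50, 4))
        fit = fit_ols(d, y)
        x = d.values
        beta_ref = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta_ref
        sigma2 = (resid**2).sum(axis=0) / (50 - 7)
        se_ref = np.sqrt(np.outer(np.diag(np.linalg.inv(x.T @ x)), sigma2))
        assert np.allclose(fit.coefficients, beta_ref, rtol=1e-8)
        assert np.allclose(fit.standard_errors, se_ref, rtol=1e-8)

    def test_duplicated_columns_flagged_nontestable(self, rng):
        x = rng.normal(size=(40, 3))
        x = np.hstack([x, x[:, [0]]])  # duplicate first column
        d = DesignMatrix(x, [("interaction", "A", "B")] * 4, "interaction",
                         np.array(["A", "B"]), np.array(["i"]))
        fit = fit_ols(d, rng.normal(size=(40, 2)))
        assert not fit.testable[0] and not fit.testable[3]
        assert fit.testable[1] and fit.testable[2]

    def test_minimum_norm_solution_on_rank_deficient_design(self, rng):
        x = rng.normal(size=(30, 2))
        x = np.hstack([x, x.sum(axis=1, keepdims=True)])
        d = DesignMatrix(x, [("interaction", "A", "B")] * 3, "interaction",
                         np.array(["A", "B"]), np.array(["i"]))
        y = rng.normal(size=(30, 1))
        fit = fit_ols(d, y)
        beta_ref = np.linalg.pinv(x) @ y
        assert np.allclose(fit.coefficients, beta_ref, atol=1e-10)


class TestWaldTest:
    def test_zero_coefficient_gives_p_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 2))
        d = DesignMatrix(x, [("interaction", "A", "B")] * 2, "interaction",
                         np.array(["A", "B"]), np.array(["i"]))
        y = rng.normal(size=(40, 1))
        fit = fit_ols(d, y)
        fit.coefficients[0, 0] = 0.0
        table = wald_test(fit)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_p_values_match_t_distribution_oracle(self, rng):
        for _ in range(20):
            beta = rng.normal()
            se = rng.uniform(0.1, 2.0)
            dof = int(rng.integers(3, 200))
            p_ref = 2 * stats.t.sf(abs(beta / se), df=dof)
            # the implementation computes exactly this statistic
            x = np.eye(2)
            d = DesignMatrix(x, [("interaction", "A", "B")] * 2, "interaction",
                             np.array(["A", "B"]), np.array(["i"]))
            fit = fit_ols(d, np.zeros((2, 1)))
            fit.coefficients = np.array([[beta], [0.0]])
            fit.standard_errors = np.array([[se], [1.0]])
            fit.rank = 2
            fit.n_obs = dof + 2  # dof = n_obs - rank
            table = wald_test(fit)
            assert table.loc[0, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_null_simulation_controls_false_discoveries(self):
        cfg = SimulationConfig(n_cells=800, n_genes=300, n_types=1, seed=3)
        ds, _ = simulate_null(cfg)
        graph = build_graph(ds, cfg.interaction_radius)
        fit = fit_ols(build_design(ds, graph, "interaction"), ds.expression,
                      gene_names=ds.gene_names)
        table = wald_test(fit)
        frac = (table["q"] < 0.05).mean()
        m = len(table)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)

    def test_null_p_values_are_uniform(self):
        cfg = SimulationConfig(n_cells=800, n_genes=400, n_types=1, seed=9)
        ds, _ = simulate_null(cfg)
        graph = build_graph(ds, cfg.interaction_radius)
        fit = fit_ols(build_design(ds, graph, "interaction"), ds.expression,
                      gene_names=ds.gene_names)
        table = wald_test(fit)
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01


class TestGaussianLikelihood:
    def test_perfect_fit_unit_sigma(self):
        y = np.zeros((4, 3))
        assert gaussian_ll(y, y, np.ones(3)) == pytest.approx(-np.log(np.sqrt(2 * np.pi)))

    def test_unit_residual_single_entry(self):
        assert gaussian_ll(np.array([[1.0]]), np.array([[0.0]]), np.array([1.0])) == (
            pytest.approx(-np.log(np.sqrt(2 * np.pi)) - 0.5)
        )

    def test_larger_residuals_decrease_likelihood(self, rng):
        y = rng.normal(size=(10, 3))
        y_hat = y + rng.normal(scale=0.5, size=y.shape)
        sigma = np.ones(3)
        assert gaussian_ll(y, 2 * y_hat - y, sigma) < gaussian_ll(y, y_hat, sigma)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_ll(np.ones((1, 1)), np.ones((1, 1)), np.array([0.0]))


class TestRSquared:
    def test_perfect_prediction_is_one(self, rng):
        y = rng.normal(size=(5, 3))
        per_cell, pooled = r_squared(y, y, y.mean(axis=0))
        assert np.allclose(per_cell, 1.0) and pooled == 1.0

    def test_predicting_train_means_scores_zero(self, rng):
        y = rng.normal(size=(20, 4))
        mu = y.mean(axis=0)
        _, pooled = r_squared(y, np.broadcast_to(mu, y.shape), mu)
        assert pooled == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        y = rng.normal(size=(10, 3))
        y_hat = rng.normal(size=(10, 3))
        mu = rng.normal(size=3)
        per_cell, pooled = r_squared(y, y_hat, mu)
        ref = 1 - ((y - y_hat) ** 2).sum(1) / ((y - mu) ** 2).sum(1)
        assert np.allclose(per_cell, ref, atol=1e-12)
        assert pooled == pytest.approx(
            1 - ((y - y_hat) ** 2).sum() / ((y - mu) ** 2).sum(), abs=1e-12
        )


class TestModelNesting:
    def test_added_columns_never_hurt_training_fit(self, dependency_data):
        ds, _, graph, _ = dependency_data
        y = ds.expression
        mu = y.mean(axis=0)
        r2 = {}
        for variant in ("baseline", "global_sender", "interaction"):
            fit = fit_ols(build_design(ds, graph, variant), y)
            _, r2[variant] = r_squared(y, fit.predict(), mu)
        assert r2["baseline"] <= r2["global_sender"] + 1e-12
        assert r2["global_sender"] <= r2["interaction"] + 1e-12


class TestResolutionScreen:
    def test_baseline_constant_and_peak_near_true_radius(self):
        cfg = SimulationConfig(n_cells=700, n_genes=40, interaction_radius=50.0, seed=4)
        ds, _ = simulate_dependency(cfg)
        grid = [15.0, 30.0, 50.0, 80.0, 130.0]
        table = resolution_screen(ds, grid, seeds=(0, 1))
        base = table.groupby("resolution")["baseline_r2"].mean()
        assert base.nunique() == 1  # graph-free baseline ignores resolution
        best = table["best_resolution"].iloc[0]
        assert best in (30.0, 50.0, 80.0)

    def test_requires_multiple_resolutions_and_seeds(self, dependency_data):
        ds, _, _, _ = dependency_data
        with pytest.raises(ValueError):
            resolution_screen(ds, [10.0], seeds=(0, 1))
        with pytest.raises(ValueError):
            resolution_screen(ds, [10.0, 20.0], seeds=(0,))
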