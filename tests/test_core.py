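"""Radius graphs, splits, size factors, variance decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncem import (
    SpatialDataset,
    build_graph,
    log_transform,
    resolution_grid,
    size_factors,
    split_nodes,
    variance_decomposition,
)


def _dataset(coords, domain=None, expr=None, types=None):
    n = len(coords)
    return SpatialDataset(
        expression=np.ones((n, 1)) if expr is None else np.asarray(expr, dtype=float),
        coords=np.asarray(coords, dtype=float),
        cell_type=np.array(["t"] * n if types is None else types),
        domain=np.array(["i"] * n if domain is None else domain),
        gene_names=np.array(["g0"]) if expr is None else np.array(
            [f"g{j}" for j in range(np.asarray(expr).shape[1])]
        ),
    )


class TestBuildGraph:
    def test_distance_threshold_is_inclusive(self):
        ds = _dataset([[0, 0], [3, 4]])  # distance exactly 5
        g = build_graph(ds, 5.0)
        assert g.adjacency[0, 1] == 1 and g.adjacency[1, 0] == 1

    def test_distance_beyond_threshold_gives_no_edge(self):
        ds = _dataset([[0, 0], [3, 4]])
        g = build_graph(ds, 4.9)
        assert g.adjacency.nnz == 0
        assert g.degree.tolist() == [0, 0]

    def test_single_cell_graph_is_empty(self):
        g = build_graph(_dataset([[0, 0]]), 5.0)
        assert g.adjacency.nnz == 0 and g.degree.tolist() == [0]

    def test_edges_never_cross_images(self):
        ds = _dataset([[0, 0], [1, 0]], domain=["a", "b"])
        assert build_graph(ds, 100.0).adjacency.nnz == 0

    def test_rows_of_normalized_adjacency_sum_to_one(self, dependency_data):
        ds, _, graph, _ = dependency_data
        rowsums = np.asarray(graph.normalized_adjacency.sum(axis=1)).ravel()
        connected = graph.degree > 0
        assert np.allclose(rowsums[connected], 1.0, atol=1e-12)
        assert np.all(rowsums[~connected] == 0.0)

    def test_zero_diagonal_and_symmetry(self, dependency_data):
        _, _, graph, _ = dependency_data
        a = graph.adjacency
        assert a.diagonal().sum() == 0
        assert (a != a.T).nnz == 0

    def test_edge_sets_nest_with_growing_radius(self, rng):
        coords = rng.uniform(0, 100, size=(60, 2))
        ds = _dataset(coords)
        small = build_graph(ds, 15.0).adjacency
        large = build_graph(ds, 30.0).adjacency
        # every small-radius edge survives at the larger radius
        assert ((large - small) < 0).nnz == 0

    def test_rejects_nonpositive_resolution(self, tiny_dataset):
        with pytest.raises(ValueError):
            build_graph(tiny_dataset, 0.0)


class TestResolutionGrid:
    def test_mean_degrees_increase_along_grid(self, rng):
        coords = np.array([[10.0 * i, 10.0 * j] for i in range(6) for j in range(6)])
        ds = _dataset(coords)
        grid = resolution_grid(ds, 3)
        degrees = [build_graph(ds, r).mean_degree for r in grid]
        assert all(b > a for a, b in zip(degrees, degrees[1:]))

    def test_reference_radius_always_present(self, rng):
        coords = rng.uniform(0, 200, size=(50, 2))
        grid = resolution_grid(_dataset(coords), 4)
        assert np.any(np.isclose(grid, 10.0))

    def test_two_distant_cells_reach_connecting_radius(self):
        ds = _dataset([[0, 0], [100, 0]])
        grid = resolution_grid(ds, 3, max_mean_degree=1.0)
        assert grid.max() >= 100.0

    def test_degenerate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            resolution_grid(_dataset([[1, 1], [1, 1], [1, 1]]), 3)


class TestSplitNodes:
    def test_sizes_for_hundred_cells(self):
        s = split_nodes(100, seed=0)
        assert len(s.test) == 10 and len(s.validation) == 9 and len(s.train) == 81

    def test_same_seed_reproduces_assignment(self):
        a, b = split_nodes(137, seed=5), split_nodes(137, seed=5)
        assert np.array_equal(a.role, b.role)

    def test_matches_reference_permutation_sampling(self):
        # documented algorithm: permute with default_rng(seed), first block test
        n, seed = 1000, 11
        s = split_nodes(n, seed)
        perm = np.random.default_rng(seed).permutation(n)
        assert set(s.test) == set(perm[:100])
        assert set(s.validation) == set(perm[100:190])

    @pytest.mark.parametrize("n", range(10, 201))
    def test_partition_proportions_hold(self, n):
        s = split_nodes(n, seed=1)
        n_test = int(np.floor(0.10 * n + 0.5))
        n_val = int(np.floor(0.10 * (n - n_test) + 0.5))
        assert len(s.test) == n_test
        assert len(s.validation) == n_val
        assert len(s.train) == n - n_test - n_val

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            split_nodes(9, seed=0)


class TestSizeFactors:
    def test_hand_computed_example(self):
        ds = _dataset([[0, 0], [1, 0]], expr=[[1, 1], [3, 3]])
        assert np.allclose(size_factors(ds), [0.5, 1.5])

    def test_identical_cells_get_unit_factors(self):
        ds = _dataset([[0, 0], [1, 0], [2, 0]], expr=np.full((3, 4), 2.0))
        assert np.allclose(size_factors(ds), 1.0)

    def test_mean_is_one_on_random_data(self, rng):
        expr = rng.uniform(0.1, 5.0, size=(30, 6))
        ds = _dataset(rng.uniform(0, 10, size=(30, 2)), expr=expr)
        assert np.isclose(size_factors(ds).mean(), 1.0, atol=1e-12)

    def test_zero_total_cell_is_named(self):
        ds = _dataset([[0, 0], [1, 0]], expr=[[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="1"):
            size_factors(ds)


class TestVarianceDecomposition:
    def test_hand_computed_two_type_example(self):
        ds = _dataset(
            [[0, 0], [1, 0], [2, 0], [3, 0]],
            expr=[[0.0], [2.0], [4.0], [6.0]],
            types=["a", "a", "b", "b"],
        )
        vd = variance_decomposition(ds)
        assert vd.intra_type_ss == pytest.approx(4.0)
        assert vd.inter_type_ss == pytest.approx(16.0)
        assert vd.gene_ss == pytest.approx(0.0)
        assert vd.total_ss == pytest.approx(20.0)

    def test_constant_dataset_has_zero_components(self):
        ds = _dataset([[0, 0], [1, 0]], expr=np.full((2, 3), 5.0), types=["a", "b"])
        vd = variance_decomposition(ds)
        assert vd.total_ss == vd.intra_type_ss == vd.inter_type_ss == vd.gene_ss == 0.0

    def test_singleton_types_have_zero_intra(self, rng):
        expr = rng.uniform(0, 5, size=(4, 3))
        ds = _dataset(rng.uniform(0, 9, (4, 2)), expr=expr, types=list("abcd"))
        assert variance_decomposition(ds).intra_type_ss == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 25),
        j=st.integers(1, 8),
        l=st.integers(1, 4),
    )
    def test_components_sum_to_total(self, seed, n, j, l):
        r = np.random.default_rng(seed)
        expr = r.uniform(0, 10, size=(n, j))
        types = [f"t{k}" for k in r.integers(0, l, size=n)]
        ds = _dataset(r.uniform(0, 50, (n, 2)), expr=expr, types=types)
        vd = variance_decomposition(ds)
        total = vd.intra_type_ss + vd.inter_type_ss + vd.gene_ss
        assert total == pytest.approx(vd.total_ss, rel=1e-9, abs=1e-9)
        if vd.total_ss > 0:
            assert sum(vd.fractions.values()) == pytest.approx(1.0, rel=1e-9)


class TestLogTransform:
    def test_values_and_roundtrip(self, rng):
        expr = rng.uniform(0, 20, size=(10, 4))
        expr[0, 0] = 0.0
        expr[0, 1] = np.e - 1.0
        ds = _dataset(rng.uniform(0, 10, (10, 2)), expr=expr)
        out = log_transform(ds)
        assert out.expression[0, 0] == 0.0
        assert out.expression[0, 1] == pytest.approx(1.0)
        assert out.log1p_applied
        assert np.allclose(np.expm1(out.expression), expr, atol=1e-12)

    def test_negative_expression_rejected(self):
        ds = _dataset([[0, 0], [1, 1]], expr=[[1.0], [-0.5]])
        with pytest.raises(ValueError):
            log_transform(ds)
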