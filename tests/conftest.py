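import numpy as np
import pytest

from ncem import SimulationConfig, SpatialDataset, build_graph, simulate_dependency


@pytest.fixture(scope="session")
def tiny_dataset():
    """Five hand-placed cells, two types, two images."""
    return SpatialDataset(
        expression=np.array(
            [[1.0, 2.0], [3.0, 1.0], [0.5, 4.0], [2.0, 2.0], [1.0, 1.0]]
        ),
        coords=np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0], [0.0, 0.0], [1.0, 0.0]]),
        cell_type=np.array(["A", "B", "A", "B", "A"]),
        domain=np.array(["img0", "img0", "img0", "img1", "img1"]),
        gene_names=np.array(["g1", "g2"]),
    )


@pytest.fixture(scope="session")
def dependency_data():
    """Seeded two-type tissue with planted niche effects (shared across tests)."""
    cfg = SimulationConfig(n_cells=500, n_genes=40, seed=7)
    ds, truth = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    return ds, truth, graph, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
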