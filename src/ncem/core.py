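"""Core containers and spatial-graph machinery for node-centric expression models.

A node-centric expression model (NCEM) predicts a cell's expression vector from
its own type, the composition of its spatial niche (all cells within a radius
``resolution`` in the same tissue image), and batch/domain covariates.  This
module holds the dataset container, the radius-graph construction, train/
validation/test partitioning, size-factor scaling, the log transform, and the
decomposition of total expression variance into intra-cell-type,
inter-cell-type and gene components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = [
    "SpatialDataset",
    "CellGraph",
    "SplitAssignment",
    "VarianceDecomposition",
    "build_graph",
    "resolution_grid",
    "split_nodes",
    "size_factors",
    "variance_decomposition",
    "log_transform",
]


def _one_hot(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    idx = {lv: i for i, lv in enumerate(levels)}
    out = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        out[i, idx[lab]] = 1.0
    return out


@dataclass
class SpatialDataset:
    """Cells-by-genes expression with 2-D coordinates, type and domain labels.

    Parameters
    ----------
    expression
        ``(N, J)`` non-negative expression matrix (cells x genes).
    coords
        ``(N, 2)`` spatial coordinates in micrometres.
    cell_type
        Length-``N`` categorical type labels (``L`` unique types).
    domain
        Length-``N`` image / patient / batch labels (``C`` unique domains).
        Edges of the cell graph never cross domain boundaries.
    gene_names
        Length-``J`` unique gene identifiers.
    condition
        Optional length-``N`` condition labels (e.g. genotype).
    """

    expression: np.ndarray
    coords: np.ndarray
    cell_type: np.ndarray
    domain: np.ndarray
    gene_names: np.ndarray
    condition: np.ndarray | None = None
    log1p_applied: bool = False

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_type = np.asarray(self.cell_type)
        self.domain = np.asarray(self.domain)
        self.gene_names = np.asarray(self.gene_names)
        n, j = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be (N, 2)={n, 2}, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.cell_type) != n or len(self.domain) != n:
            raise ValueError("cell_type and domain must have one entry per cell")
        if len(self.gene_names) != j:
            raise ValueError("gene_names length must match number of genes")
        if len(set(self.gene_names)) != j:
            raise ValueError("gene_names must be unique")
        # lexicographic level order keeps one-hot layouts reproducible
        self.type_levels = np.array(sorted(set(self.cell_type.tolist())))
        self.domain_levels = np.array(sorted(set(self.domain.tolist())))

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_types(self) -> int:
        return len(self.type_levels)

    @property
    def n_domains(self) -> int:
        return len(self.domain_levels)

    def type_onehot(self) -> np.ndarray:
        """``(N, L)`` one-hot encoding of cell types (columns sorted by label)."""
        return _one_hot(self.cell_type, self.type_levels)

    def domain_onehot(self) -> np.ndarray:
        """``(N, C)`` one-hot encoding of domain labels."""
        return _one_hot(self.domain, self.domain_levels)

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            expression=self.expression.copy(),
            coords=self.coords.copy(),
            cell_type=self.cell_type.copy(),
            domain=self.domain.copy(),
            gene_names=self.gene_names.copy(),
            condition=None if self.condition is None else np.asarray(self.condition).copy(),
            log1p_applied=self.log1p_applied,
        )


@dataclass
class CellGraph:
    """Radius-thresholded spatial adjacency of cells, per image.

    ``adjacency`` is binary, symmetric, zero-diagonal; an edge links two cells
    of the same domain at Euclidean distance <= ``resolution``.
    ``normalized_adjacency`` is the row-normalised matrix D^-1 A used by graph
    convolutions; rows of isolated nodes are all zero.
    """

    adjacency: csr_matrix
    resolution: float
    degree: np.ndarray = field(init=False)
    normalized_adjacency: csr_matrix = field(init=False)

    def __post_init__(self) -> None:
        a = csr_matrix(self.adjacency)
        self.adjacency = a
        self.degree = np.asarray(a.sum(axis=1)).ravel().astype(int)
        inv = np.zeros(a.shape[0])
        nz = self.degree > 0
        inv[nz] = 1.0 / self.degree[nz]
        d_inv = csr_matrix((inv, (np.arange(a.shape[0]), np.arange(a.shape[0]))), shape=a.shape)
        self.normalized_adjacency = d_inv @ a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean())

    def edge_list(self, coords: np.ndarray | None = None) -> pd.DataFrame:
        """Edges as a table with columns ``source``, ``target``, ``distance``."""
        coo = self.adjacency.tocoo()
        mask = coo.row < coo.col
        src, tgt = coo.row[mask], coo.col[mask]
        if coords is None:
            dist = np.full(len(src), np.nan)
        else:
            dist = np.linalg.norm(coords[src] - coords[tgt], axis=1)
        return pd.DataFrame({"source": src, "target": tgt, "distance": dist})


def build_graph(dataset: SpatialDataset, resolution: float) -> CellGraph:
    """Build the binary radius graph at neighbourhood size ``resolution`` (um).

    Cells i != j are adjacent iff they share a domain (image) and their
    Euclidean distance is <= resolution (inclusive threshold).
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    if not np.all(np.isfinite(dataset.coords)):
        raise ValueError("coordinates must be finite")
    n = dataset.n_cells
    rows: list[int] = []
    cols: list[int] = []
    for dom in dataset.domain_levels:
        idx = np.flatnonzero(dataset.domain == dom)
        if len(idx) < 2:
            continue
        tree = cKDTree(dataset.coords[idx])
        for a, b in tree.query_pairs(resolution):
            rows.extend((idx[a], idx[b]))
            cols.extend((idx[b], idx[a]))
    data = np.ones(len(rows))
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    adj.data[:] = 1.0  # collapse any duplicates
    return CellGraph(adjacency=adj, resolution=float(resolution))


def _mean_degree_at(coords: np.ndarray, domain: np.ndarray, r: float) -> float:
    total = 0
    for dom in np.unique(domain):
        idx = np.flatnonzero(domain == dom)
        if len(idx) < 2:
            continue
        tree = cKDTree(coords[idx])
        total += 2 * len(tree.query_pairs(r))
    return total / len(coords)


def resolution_grid(
    dataset: SpatialDataset,
    n_points: int,
    max_mean_degree: float = 15.0,
    include_reference: bool = True,
) -> np.ndarray:
    """Monotone grid of neighbourhood radii spanning the dataset's degree range.

    The smallest radius yields a sparse graph (mean degree around 0-1), the
    largest a mean degree of about ``max_mean_degree``; the 10 um reference
    radius is always included.  Radii are geometrically spaced.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    coords = dataset.coords
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate coordinates: all cells at the same position")
    # radius with mean degree ~1: bisect on the empirical degree curve
    lo, hi = 1e-6, 1.0
    while _mean_degree_at(coords, dataset.domain, hi) < max_mean_degree:
        hi *= 2.0
        if hi > 1e9:
            break
    r_max = hi
    # refine r_max toward the target mean degree
    a, b = lo, hi
    for _ in range(40):
        mid = 0.5 * (a + b)
        if _mean_degree_at(coords, dataset.domain, mid) < max_mean_degree:
            a = mid
        else:
            b = mid
    r_max = b
    a, b = 1e-6, r_max
    for _ in range(40):
        mid = 0.5 * (a + b)
        if _mean_degree_at(coords, dataset.domain, mid) < 1.0:
            a = mid
        else:
            b = mid
    r_min = max(b, 1e-3)
    if r_min >= r_max:
        r_min = r_max / 10.0
    grid = np.geomspace(r_min, r_max, n_points)
    if include_reference and not np.any(np.isclose(grid, 10.0)):
        grid = np.sort(np.append(grid, 10.0))
    return grid


@dataclass
class SplitAssignment:
    """Cell-level train/validation/test partition.

    10% of all cells (pooled across images) form the test set; 10% of the
    remainder the validation set; sizes use round-half-up.
    """

    role: np.ndarray
    seed: int

    @property
    def train(self) -> np.ndarray:
        return np.flatnonzero(self.role == "train")

    @property
    def validation(self) -> np.ndarray:
        return np.flatnonzero(self.role == "validation")

    @property
    def test(self) -> np.ndarray:
        return np.flatnonzero(self.role == "test")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_nodes(dataset: SpatialDataset | int, seed: int) -> SplitAssignment:
    """Draw the 10% test / 10%-of-rest validation partition, uniformly pooled.

    Accepts either a dataset or a plain cell count.  The assignment is a
    deterministic function of ``seed``: cells are permuted with
    ``numpy.random.default_rng(seed)`` and the first block becomes the test
    set, the next block the validation set.
    """
    n = dataset if isinstance(dataset, (int, np.integer)) else dataset.n_cells
    if n < 10:
        raise ValueError("need at least 10 cells for a non-empty test set")
    n_test = _round_half_up(0.10 * n)
    n_val = _round_half_up(0.10 * (n - n_test))
    perm = np.random.default_rng(seed).permutation(n)
    role = np.full(n, "train", dtype=object)
    role[perm[:n_test]] = "test"
    role[perm[n_test : n_test + n_val]] = "validation"
    return SplitAssignment(role=role, seed=int(seed))


def size_factors(dataset: SpatialDataset) -> np.ndarray:
    """Per-cell total-count scaling factors, sf_i = total_i / mean total.

    Model predictions are multiplied cell-wise by sf_i when node-size output
    scaling is enabled; the mean over cells is exactly 1.
    """
    totals = dataset.expression.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        raise ValueError(f"cells with zero total counts: {zero[:10].tolist()}")
    return totals / totals.mean()


@dataclass
class VarianceDecomposition:
    """Total sum of squares split into intra-type, inter-type and gene parts.

    With type-gene means ybar_{k,j}, gene means ybar_j and the grand mean,
    sum_ij (y_ij - ybar)^2 decomposes exactly into the three components.
    """

    intra_type_ss: float
    inter_type_ss: float
    gene_ss: float
    total_ss: float

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total_ss if self.total_ss > 0 else 1.0
        return {
            "intra_type": self.intra_type_ss / t,
            "inter_type": self.inter_type_ss / t,
            "gene": self.gene_ss / t,
        }


def variance_decomposition(dataset: SpatialDataset) -> VarianceDecomposition:
    """Decompose total expression variance around type/gene/grand means."""
    y = dataset.expression
    grand = y.mean()
    gene_mean = y.mean(axis=0)  # ybar_j
    type_gene_mean = np.vstack(
        [y[dataset.cell_type == t].mean(axis=0) for t in dataset.type_levels]
    )
    type_idx = np.searchsorted(dataset.type_levels, dataset.cell_type)
    own_mean = type_gene_mean[type_idx]  # ybar_{k(i), j}
    intra = float(((y - own_mean) ** 2).sum())
    inter = float(((own_mean - gene_mean) ** 2).sum())
    gene = float(((np.broadcast_to(gene_mean, y.shape) - grand) ** 2).sum())
    total = float(((y - grand) ** 2).sum())
    return VarianceDecomposition(intra, inter, gene, total)


def log_transform(dataset: SpatialDataset) -> SpatialDataset:
    """Return a copy with log(1 + y) expression; records the flag."""
    if np.any(dataset.expression < 0):
        raise ValueError("expression must be non-negative for log transform")
    out = dataset.copy()
    out.expression = np.log1p(out.expression)
    out.log1p_applied = True
    return out
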