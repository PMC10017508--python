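"""Synthetic spatial expression data with known ground-truth niche effects.

Three generators cover the validation designs used throughout the package:

* ``simulate_null`` — one cell type, i.i.d. Gaussian expression around gene
  means drawn U(0, 10): no spatial dependency, for type-I calibration.
* ``simulate_dependency`` — two cell types; for half of the genes an additive
  effect drawn U(4, 6) is applied when the respective other type is present
  within ``interaction_radius``: planted niche effects for power/recovery.
* ``simulate_segmentation_error`` — misplaced segment boundaries, modelled by
  transferring a fraction of a cell's abundance vector to a random neighbour.
* ``simulate_spots`` — cells binned into square capture spots, emulating the
  deconvoluted spot-transcriptomics input format.

Tissues are random-geometric by default: cells uniform in a square whose side
is chosen so the radius graph at ``interaction_radius`` hits a target mean
degree.  A pre-existing tissue (coordinates + domains) can be supplied
instead.  All generators are deterministic given ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellGraph, SpatialDataset, build_graph
from .linear import sender_presence
from .spots import DeconvolutedSpots

__all__ = [
    "SimulationConfig",
    "simulate_null",
    "simulate_dependency",
    "simulate_lr_dependency",
    "simulate_segmentation_error",
    "simulate_spots",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-tissue generators.

    Defaults follow the validation design used for the linear models: gene
    means uniform on (0, 10), half of the genes carrying niche effects with
    sizes uniform on (4, 6), unit Gaussian noise.
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_types: int = 2
    n_domains: int = 1
    mean_expression_range: tuple[float, float] = (0.0, 10.0)
    dependent_gene_fraction: float = 0.5
    effect_size_range: tuple[float, float] = (4.0, 6.0)
    noise_sd: float = 1.0
    interaction_radius: float = 50.0
    target_mean_degree: float = 4.0
    asymmetric: bool = False
    zoned: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dependent_gene_fraction <= 1.0:
            raise ValueError("dependent_gene_fraction must be in [0, 1]")
        lo, hi = self.effect_size_range
        if hi < lo:
            raise ValueError("invalid effect_size_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _tissue(config: SimulationConfig, rng: np.random.Generator):
    """Random-geometric tissue: uniform coordinates per domain.

    The square side is set so the expected degree of the radius graph at
    ``interaction_radius`` is about ``target_mean_degree``.
    """
    n = config.n_cells
    per_dom = np.full(config.n_domains, n // config.n_domains)
    per_dom[: n % config.n_domains] += 1
    coords = np.empty((n, 2))
    domain = np.empty(n, dtype=object)
    start = 0
    for d, nd in enumerate(per_dom):
        area = (nd - 1) * np.pi * config.interaction_radius**2 / config.target_mean_degree
        side = float(np.sqrt(max(area, 1.0)))
        coords[start : start + nd] = rng.uniform(0.0, side, size=(nd, 2))
        domain[start : start + nd] = f"image_{d}"
        start += nd
    return coords, domain


def _gene_names(j: int) -> np.ndarray:
    return np.array([f"gene_{k}" for k in range(j)])


def simulate_null(config: SimulationConfig):
    """One cell type, no spatial dependency.

    Expression is gene mean plus i.i.d. Gaussian noise; the ground truth
    records zero effects.  Returns ``(dataset, ground_truth)`` where
    ground_truth holds the drawn gene means and an empty effect table.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mean_expression_range
    # gene means are the first draw so that equal seeds give equal means
    # across generator designs
    means = rng.uniform(lo, hi, size=config.n_genes)
    coords, domain = _tissue(config, rng)
    y = means[None, :] + rng.normal(0.0, config.noise_sd, size=(config.n_cells, config.n_genes))
    ds = SpatialDataset(
        expression=y,
        coords=coords,
        cell_type=np.full(config.n_cells, "type_0", dtype=object),
        domain=domain,
        gene_names=_gene_names(config.n_genes),
    )
    truth = {
        "gene_means": means,
        "effects": pd.DataFrame(columns=["gene", "receiver", "sender", "effect"]),
        "interaction_radius": config.interaction_radius,
    }
    return ds, truth


def simulate_dependency(
    config: SimulationConfig,
    coords: np.ndarray | None = None,
    domain: np.ndarray | None = None,
):
    """Two cell types with planted niche effects on half of the genes.

    Cell types are assigned uniformly at random (or in two spatial zones if
    ``config.zoned``).  For each dependent gene and each receiver type, an
    additive effect drawn from ``effect_size_range`` raises the mean whenever
    the other type is present within ``interaction_radius`` of the cell.
    With ``config.asymmetric`` only receiver ``type_1`` responds to sender
    ``type_0`` (a purely directed coupling).

    Returns ``(dataset, ground_truth)``; the ground-truth effect table has one
    row per (gene, receiver, sender) with the planted effect size.
    """
    if config.n_types != 2:
        raise ValueError("the dependency design uses exactly 2 cell types")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mean_expression_range
    j = config.n_genes
    # one mean per gene, shared by both types and drawn first: types differ
    # only through their niche response, so the zero-effect limit matches the
    # null design seed-for-seed
    means = np.tile(rng.uniform(lo, hi, size=j), (2, 1))
    if coords is None:
        coords, domain = _tissue(config, rng)
    coords = np.asarray(coords, dtype=float)
    domain = np.asarray(domain)
    n = len(coords)
    if config.zoned:
        split = np.median(coords[:, 0])
        type_idx = (coords[:, 0] > split).astype(int)
    else:
        type_idx = rng.integers(0, 2, size=n)
    labels = np.array(["type_0", "type_1"], dtype=object)
    cell_type = labels[type_idx]
    n_dep = int(round(config.dependent_gene_fraction * j))
    dep_genes = rng.choice(j, size=n_dep, replace=False)
    e_lo, e_hi = config.effect_size_range
    # effect[r] applies to receiver type r when the other type is a neighbour
    effects = np.zeros((2, j))
    effects[1, dep_genes] = rng.uniform(e_lo, e_hi, size=n_dep)
    if not config.asymmetric:
        effects[0, dep_genes] = rng.uniform(e_lo, e_hi, size=n_dep)

    ds_tmp = SpatialDataset(
        expression=np.zeros((n, 1)),
        coords=coords,
        cell_type=cell_type,
        domain=domain,
        gene_names=np.array(["_"]),
    )
    graph = build_graph(ds_tmp, config.interaction_radius)
    onehot = ds_tmp.type_onehot()
    presence = sender_presence(graph, onehot)  # (N, 2)
    other = 1 - type_idx
    other_present = presence[np.arange(n), other]  # 1 iff the other type is a neighbour

    # expression follows the stated law exactly (no truncation), so OLS
    # coefficient estimates are calibrated against the planted effects
    y = means[type_idx] + other_present[:, None] * effects[type_idx]
    y = y + rng.normal(0.0, config.noise_sd, size=(n, j))
    ds = SpatialDataset(
        expression=y,
        coords=coords,
        cell_type=cell_type,
        domain=domain,
        gene_names=_gene_names(j),
    )
    rows = []
    for r in (0, 1):
        s = 1 - r
        for g in dep_genes:
            if effects[r, g] != 0:
                rows.append((f"gene_{g}", labels[r], labels[s], effects[r, g]))
    truth = {
        "gene_means": means,
        "effects": pd.DataFrame(rows, columns=["gene", "receiver", "sender", "effect"]),
        "dependent_genes": np.sort(dep_genes),
        "interaction_radius": config.interaction_radius,
    }
    return ds, truth


def simulate_lr_dependency(
    config: SimulationConfig,
    n_pairs: int = 5,
    n_targets: int = 10,
    lr_effect: float = 3.0,
):
    """Ligand-driven niche effects for the receptor-activity kernel model.

    Two cell types; gene layout: genes 2k / 2k+1 are the receptor / ligand of
    pair k, the next ``n_targets`` genes are targets, the rest bystanders.
    Only pair 0 is active: its ligand is expressed highly by sender
    ``type_1`` cells and barely elsewhere, so the kernel latent
    z_0 = receptor_expr * sum of neighbour ligand varies with niche
    composition.  Target-gene means shift by ``lr_effect`` times the
    standardised true latent; distractor pairs have spatially uniform ligand
    expression and no downstream effect.

    Returns ``(dataset, ground_truth)`` with the pair list, the active pair
    index (0) and the target genes.
    """
    rng = np.random.default_rng(config.seed)
    coords, domain = _tissue(config, rng)
    n, j = config.n_cells, config.n_genes
    if j < 2 * n_pairs + n_targets:
        raise ValueError("n_genes too small for the requested pairs and targets")
    type_idx = rng.integers(0, 2, size=n)
    labels = np.array(["type_0", "type_1"], dtype=object)
    cell_type = labels[type_idx]
    lo, hi = config.mean_expression_range
    means = np.broadcast_to(rng.uniform(lo, hi, size=j), (n, j)).copy()
    # receptors moderately expressed everywhere; true ligand marks the sender type
    for k in range(n_pairs):
        means[:, 2 * k] = 5.0
        means[:, 2 * k + 1] = 5.0
    means[:, 1] = np.where(type_idx == 1, 8.0, 0.5)
    y = means + rng.normal(0.0, config.noise_sd, size=(n, j))

    ds_tmp = SpatialDataset(
        expression=np.zeros((n, 1)), coords=coords, cell_type=cell_type,
        domain=domain, gene_names=np.array(["_"]),
    )
    graph = build_graph(ds_tmp, config.interaction_radius)
    z_true = y[:, 0] * np.asarray(graph.adjacency @ y[:, 1])
    sd = z_true.std()
    z_std = (z_true - z_true.mean()) / (sd if sd > 0 else 1.0)
    targets = np.arange(2 * n_pairs, 2 * n_pairs + n_targets)
    y[:, targets] = y[:, targets] + lr_effect * z_std[:, None]
    ds = SpatialDataset(
        expression=y, coords=coords, cell_type=cell_type, domain=domain,
        gene_names=_gene_names(j),
    )
    pairs = [(f"gene_{2 * k}", f"gene_{2 * k + 1}") for k in range(n_pairs)]
    truth = {
        "pairs": pairs,
        "active_pair": 0,
        "target_genes": targets,
        "interaction_radius": config.interaction_radius,
    }
    return ds, truth


def simulate_segmentation_error(
    dataset: SpatialDataset,
    cell_fraction: float,
    transfer_fraction: float,
    seed: int,
    graph: CellGraph | None = None,
    resolution: float | None = None,
) -> SpatialDataset:
    """Misplaced segmentation boundaries between neighbouring cells.

    A fraction of cells is selected at random; each transfers
    ``transfer_fraction`` of its current abundance vector to one uniformly
    chosen graph neighbour.  Per-image totals are conserved exactly; selected
    cells without neighbours are skipped with a warning.
    """
    if not 0.0 <= cell_fraction <= 1.0 or not 0.0 < transfer_fraction <= 1.0:
        raise ValueError("fractions must lie in (0, 1]")
    if graph is None:
        if resolution is None:
            raise ValueError("supply a graph or a resolution")
        graph = build_graph(dataset, resolution)
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    n = dataset.n_cells
    n_sel = int(round(cell_fraction * n))
    selected = rng.choice(n, size=n_sel, replace=False)
    adj = graph.adjacency
    skipped = 0
    for i in selected:
        nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        if len(nbrs) == 0:
            skipped += 1
            continue
        m = int(rng.choice(nbrs))
        moved = transfer_fraction * out.expression[i]
        out.expression[i] -= moved
        out.expression[m] += moved
    if skipped:
        warnings.warn(f"{skipped} selected cells had no neighbours and were skipped")
    return out


def simulate_spots(
    config: SimulationConfig,
    spot_size: float | None = None,
):
    """Cells binned into square capture spots, as deconvolution would yield.

    A dependency tissue (or a null tissue for ``n_types == 1``) is generated
    and partitioned into a square grid of side ``spot_size`` (default 1.5x the
    interaction radius, so a spot approximates a niche).  Per-spot type
    abundances are true cell counts; the (spot, type) expression vector is the
    within-spot mean of that type's cells.  Empty spots are dropped.

    Returns ``(spots, dataset, ground_truth)``.
    """
    if config.n_types == 1:
        ds, truth = simulate_null(config)
    else:
        ds, truth = simulate_dependency(config)
    if spot_size is None:
        spot_size = 1.5 * config.interaction_radius
    levels = ds.type_levels
    l, j = len(levels), ds.n_genes
    bins = np.floor(ds.coords / spot_size).astype(int)
    keys = [(d, bx, by) for d, (bx, by) in zip(ds.domain, bins)]
    uniq = sorted(set(keys))
    spot_of = {k: i for i, k in enumerate(uniq)}
    s = len(uniq)
    expr = np.zeros((s, l, j))
    comp = np.zeros((s, l))
    coords = np.zeros((s, 2))
    type_idx = np.searchsorted(levels, ds.cell_type)
    for i, k in enumerate(keys):
        sp = spot_of[k]
        expr[sp, type_idx[i]] += ds.expression[i]
        comp[sp, type_idx[i]] += 1
        coords[sp] += ds.coords[i]
    counts = comp.sum(axis=1, keepdims=True)
    coords /= np.where(counts > 0, counts, 1.0)
    mask = comp > 0
    with np.errstate(invalid="ignore"):
        expr = np.divide(expr, np.where(mask[:, :, None], comp[:, :, None], 1.0))
    spots = DeconvolutedSpots(
        spot_type_expression=expr,
        spot_composition=comp,
        spot_coords=coords,
        presence_mask=mask,
        type_levels=levels,
        gene_names=ds.gene_names,
    )
    return spots, ds, truth
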