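"""Readers, writers, configuration and run manifests.

Expression comes in as MTX (cells x genes, with a gene-name sidecar TSV) or a
dense CSV/TSV with genes as columns; cell metadata is a TSV with required
columns ``x``, ``y``, ``cell_type``, ``image`` (optional ``cell_id`` for
joining, optional ``condition``).  All tabular outputs are TSV with stable
column order; floats round-trip at 17 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

from .core import SpatialDataset
from .spots import DeconvolutedSpots

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_spots",
    "write_table",
    "read_config",
    "RunManifest",
]

FLOAT_FORMAT = "%.17g"
REQUIRED_META = ("x", "y", "cell_type", "image")


def _read_expression(path: Path, genes_path: Path | None):
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path)
        expr = np.asarray(mat.todense() if issparse(mat) else mat, dtype=float)
        if genes_path is None:
            genes = np.array([f"gene_{j}" for j in range(expr.shape[1])])
        else:
            genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
        return expr, genes
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return frame.to_numpy(dtype=float), frame.columns.to_numpy()


def read_dataset(
    expression_path,
    metadata_path,
    genes_path=None,
) -> SpatialDataset:
    """Load and validate a spatial dataset from disk.

    Metadata rows are joined to matrix rows by ``cell_id`` when present
    (order-independent), otherwise by position.  Distinct errors flag missing
    columns, row-count mismatches and duplicate cell identifiers.
    """
    expr, genes = _read_expression(Path(expression_path), genes_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    missing = [c for c in REQUIRED_META if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if len(meta) != expr.shape[0]:
        raise ValueError(
            f"dimension mismatch: {expr.shape[0]} matrix rows vs {len(meta)} metadata rows"
        )
    if "cell_id" in meta.columns:
        if meta["cell_id"].duplicated().any():
            dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()[:5]
            raise ValueError(f"duplicate cell identifiers: {dups}")
        meta = meta.sort_values("cell_id", kind="stable").reset_index(drop=True)
    condition = meta["condition"].to_numpy() if "condition" in meta.columns else None
    return SpatialDataset(
        expression=expr,
        coords=meta[["x", "y"]].to_numpy(dtype=float),
        cell_type=meta["cell_type"].to_numpy(),
        domain=meta["image"].to_numpy(),
        gene_names=genes,
        condition=condition,
    )


def write_dataset(dataset: SpatialDataset, out_dir, graph=None) -> dict[str, Path]:
    """Write expression (MTX + genes TSV), metadata TSV and optional edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    from scipy.sparse import csr_matrix

    mmwrite(out / "expression.mtx", csr_matrix(dataset.expression))
    paths["expression"] = out / "expression.mtx"
    pd.Series(dataset.gene_names).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    paths["genes"] = out / "genes.tsv"
    meta = pd.DataFrame(
        {
            "cell_id": np.arange(dataset.n_cells),
            "x": dataset.coords[:, 0],
            "y": dataset.coords[:, 1],
            "cell_type": dataset.cell_type,
            "image": dataset.domain,
        }
    )
    if dataset.condition is not None:
        meta["condition"] = dataset.condition
    meta.to_csv(out / "cells.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    paths["metadata"] = out / "cells.tsv"
    if graph is not None:
        graph.edge_list(dataset.coords).to_csv(
            out / "edges.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        paths["edges"] = out / "edges.tsv"
    return paths


def read_spots(expression_path, composition_path) -> DeconvolutedSpots:
    """Load deconvoluted spot data from long-format TSVs.

    ``expression_path``: columns spot_id, cell_type, gene, value.
    ``composition_path``: wide table, spot_id index x cell-type columns.
    """
    long = pd.read_csv(expression_path, sep="\t")
    comp = pd.read_csv(composition_path, sep="\t", index_col=0)
    spots = sorted(comp.index)
    types = sorted(comp.columns)
    genes = sorted(long["gene"].unique())
    s_idx = {v: i for i, v in enumerate(spots)}
    t_idx = {v: i for i, v in enumerate(types)}
    g_idx = {v: i for i, v in enumerate(genes)}
    expr = np.zeros((len(spots), len(types), len(genes)))
    mask = np.zeros((len(spots), len(types)), dtype=bool)
    for row in long.itertuples(index=False):
        s, t, g = s_idx[row.spot_id], t_idx[row.cell_type], g_idx[row.gene]
        expr[s, t, g] = row.value
        mask[s, t] = True
    return DeconvolutedSpots(
        spot_type_expression=expr,
        spot_composition=comp.loc[spots, types].to_numpy(dtype=float),
        spot_coords=np.zeros((len(spots), 2)),
        presence_mask=mask,
        type_levels=np.array(types),
        gene_names=np.array(genes),
    )


def write_table(frame: pd.DataFrame, path) -> Path:
    """TSV writer with the package-wide float format and stable columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_config(path) -> dict:
    """YAML run configuration (resolution(s), scaling flags, seed, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    command: str
    config: dict
    seeds: list[int]
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        self._t0 = time.monotonic()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def mark(self, stage: str) -> None:
        self.timings[stage] = time.monotonic() - self._t0

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
            "package_version": self.package_version,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
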