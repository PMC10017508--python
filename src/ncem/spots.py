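"""Linear NCEM for deconvoluted spot transcriptomics.

Multi-cell capture spots (e.g. Visium) are deconvoluted upstream into
per-spot, per-cell-type expression vectors and per-spot type abundances.
Here every (spot, type) expression vector is one observation and the spot's
inferred composition is its niche: the design row for target type k in spot s
is [one-hot(k) | outer(one-hot(k), composition_s) | covariates_s], so the
interaction block carries continuous abundances rather than binary presence.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import split_nodes
from .linear import DesignMatrix, LinearFit, fit_ols, r_squared

__all__ = [
    "DeconvolutedSpots",
    "build_spot_design",
    "fit_spot_ncem",
    "coefficient_stability",
    "SpotGraphNCEM",
]


@dataclass
class DeconvolutedSpots:
    """Deconvolution output: per-(spot, type) expression and spot composition.

    ``spot_type_expression`` is (S, L, J); row (s, k) is meaningful only where
    ``presence_mask[s, k]`` is set.  ``spot_composition`` holds non-negative
    cell-type abundances per spot (not necessarily proportions).
    """

    spot_type_expression: np.ndarray
    spot_composition: np.ndarray
    spot_coords: np.ndarray
    presence_mask: np.ndarray
    type_levels: np.ndarray
    gene_names: np.ndarray
    spot_covariates: np.ndarray | None = None
    covariate_levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_type_expression = np.asarray(self.spot_type_expression, dtype=float)
        self.spot_composition = np.asarray(self.spot_composition, dtype=float)
        self.presence_mask = np.asarray(self.presence_mask, dtype=bool)
        s, l, j = self.spot_type_expression.shape
        if self.spot_composition.shape != (s, l):
            raise ValueError("composition must be (S, L)")
        if np.any(self.spot_composition < 0):
            raise ValueError("negative abundances in spot composition")
        if self.presence_mask.shape != (s, l):
            raise ValueError("presence mask must be (S, L)")
        if self.spot_covariates is None:
            self.spot_covariates = np.ones((s, 1))
            self.covariate_levels = np.array(["intercept"])

    @property
    def n_spots(self) -> int:
        return self.spot_type_expression.shape[0]

    @property
    def n_types(self) -> int:
        return self.spot_type_expression.shape[1]

    @property
    def n_genes(self) -> int:
        return self.spot_type_expression.shape[2]

    def long_rows(self) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Observed (spot, type) rows: spot index, type index and metadata."""
        spots, types = np.nonzero(self.presence_mask)
        meta = pd.DataFrame(
            {"spot": spots, "cell_type": self.type_levels[types], "type_index": types}
        )
        return spots, types, meta

    def long_expression(self) -> np.ndarray:
        spots, types, _ = self.long_rows()
        return self.spot_type_expression[spots, types]


def build_spot_design(
    data: DeconvolutedSpots,
    variant: str = "interaction",
    normalize_composition: bool = False,
) -> DesignMatrix:
    """Design over observed (spot, type) rows with the spot as the niche.

    The composition block is identical for all target types of one spot; the
    baseline variant drops it and keeps only [one-hot(k) | covariates].
    """
    if variant not in ("baseline", "interaction"):
        raise ValueError("variant must be 'baseline' or 'interaction'")
    comp = data.spot_composition
    if normalize_composition:
        totals = comp.sum(axis=1, keepdims=True)
        comp = np.divide(comp, np.where(totals > 0, totals, 1.0))
    spots, types, _ = data.long_rows()
    l = data.n_types
    xl = np.zeros((len(spots), l))
    xl[np.arange(len(spots)), types] = 1.0
    prov: list[tuple] = [("receiver_type", t) for t in data.type_levels]
    blocks = [xl]
    if variant == "interaction":
        comp_rows = comp[spots]
        xts = (xl[:, :, None] * comp_rows[:, None, :]).reshape(len(spots), l * l)
        blocks.append(xts)
        prov += [("interaction", r, s) for r in data.type_levels for s in data.type_levels]
    xc = data.spot_covariates[spots]
    blocks.append(xc)
    prov += [("domain", c) for c in data.covariate_levels]
    return DesignMatrix(
        values=np.hstack(blocks),
        column_provenance=prov,
        model_variant=variant,
        type_levels=data.type_levels,
        domain_levels=data.covariate_levels,
    )


def fit_spot_ncem(
    data: DeconvolutedSpots,
    seeds=(0, 1, 2),
    normalize_composition: bool = False,
    min_spots_per_type: int = 3,
) -> tuple[LinearFit, pd.DataFrame]:
    """Spot NCEM vs composition-blind baseline on held-out spots.

    Fits the interaction model by OLS on the full data (for inference) and,
    per cross-validation seed, scores NCEM and baseline on a held-out 10% of
    observation rows: pooled test R2 and per-receiver-type R2 (types observed
    in fewer than ``min_spots_per_type`` spots are excluded with a warning).
    """
    if data.n_types < 2:
        raise ValueError("need at least 2 cell types")
    design = build_spot_design(data, "interaction", normalize_composition)
    base = build_spot_design(data, "baseline", normalize_composition)
    y = data.long_expression()
    spots, types, meta = data.long_rows()
    fit_full = fit_ols(design, y, gene_names=data.gene_names)

    spots_per_type = pd.Series(spots).groupby(pd.Series(types)).nunique()
    reportable = {
        k for k, v in spots_per_type.items() if v >= min_spots_per_type
    }
    dropped = set(range(data.n_types)) - reportable
    if dropped:
        warnings.warn(
            "types observed in fewer than "
            f"{min_spots_per_type} spots excluded from per-type R2: "
            f"{[data.type_levels[k] for k in sorted(dropped)]}"
        )
    rows = []
    for s in seeds:
        split = split_nodes(len(y), s)
        tr, te = split.train, split.test
        mu = y[tr].mean(axis=0)
        scores = {}
        for name, d in (("ncem", design), ("baseline", base)):
            sub = DesignMatrix(d.values[tr], d.column_provenance, d.model_variant,
                               d.type_levels, d.domain_levels)
            f = fit_ols(sub, y[tr], gene_names=data.gene_names)
            y_hat = d.values[te] @ f.coefficients
            _, pooled = r_squared(y[te], y_hat, mu)
            scores[name] = (pooled, y_hat)
        rows.append({"seed": s, "cell_type": "all",
                     "ncem_r2": scores["ncem"][0], "baseline_r2": scores["baseline"][0],
                     "delta_r2": scores["ncem"][0] - scores["baseline"][0]})
        for k in sorted(reportable):
            mask = types[te] == k
            if mask.sum() < 2:
                continue
            _, p_n = r_squared(y[te][mask], scores["ncem"][1][mask], mu)
            _, p_b = r_squared(y[te][mask], scores["baseline"][1][mask], mu)
            rows.append({"seed": s, "cell_type": data.type_levels[k],
                         "ncem_r2": p_n, "baseline_r2": p_b, "delta_r2": p_n - p_b})
    return fit_full, pd.DataFrame(rows)


class SpotGraphNCEM:
    """Nonlinear spot model: spots as graph nodes, composition as features.

    Spots within ``resolution`` of each other (by spot coordinates) are
    adjacent; the encoder sees a spot's own composition and the mean
    composition of neighbouring spots, and the decoder predicts the
    (spot, type) expression vector from the spot latent plus the target-type
    one-hot.  An optional mode — dependencies *between* niches rather than
    within them.  Trains with the shared neural loop (``ncem.neural.train``).
    """

    def __init__(
        self,
        data: DeconvolutedSpots,
        resolution: float,
        hidden_width: int = 16,
        latent_dim: int = 8,
        seed: int = 0,
    ):
        from scipy.sparse import csr_matrix
        from scipy.spatial import cKDTree

        from .autodiff import Tensor
        from .neural import MLP

        self.data = data
        rng = np.random.default_rng(seed)
        coords = data.spot_coords
        tree = cKDTree(coords)
        pairs = tree.query_pairs(resolution)
        n = data.n_spots
        rows = [i for i, j in pairs] + [j for i, j in pairs]
        cols = [j for i, j in pairs] + [i for i, j in pairs]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
        comp = data.spot_composition
        self.features = np.hstack([comp, inv[:, None] * (adj @ comp)])
        spots, types, _ = data.long_rows()
        self._spots, self._types = spots, types
        l, j = data.n_types, data.n_genes
        self.y = data.long_expression()
        self.type_onehot = np.zeros((len(spots), l))
        self.type_onehot[np.arange(len(spots)), types] = 1.0
        self.covs = data.spot_covariates[spots]
        self.encoder = MLP([self.features.shape[1], hidden_width, latent_dim], rng)
        self.decoder = MLP(
            [latent_dim + l + self.covs.shape[1], hidden_width, j], rng
        )
        self.log_sigma = Tensor(np.zeros((1, j)), requires_grad=True)
        self._params = self.encoder.params() + self.decoder.params() + [self.log_sigma]

    def params(self):
        return self._params

    def forward(self, idx=None):
        from .autodiff import Tensor, concat

        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        z = self.encoder.forward(self.features[self._spots[idx]])
        return self.decoder.forward(
            concat([z, Tensor(self.type_onehot[idx]), Tensor(self.covs[idx])])
        )

    def loss(self, idx=None):
        from .autodiff import Tensor

        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        y_hat = self.forward(idx)
        resid2 = (Tensor(self.y[idx]) - y_hat) ** 2.0
        ll = (
            -0.5 * np.log(2 * np.pi)
            - self.log_sigma
            - 0.5 * resid2 * (self.log_sigma * -2.0).exp()
        )
        nll = -ll.mean()
        if not np.isfinite(nll.data):
            raise FloatingPointError("non-finite training loss")
        return nll

    def predict(self, idx=None):
        return self.forward(idx).data


def coefficient_stability(fit_full: LinearFit, fit_sub: LinearFit) -> pd.DataFrame:
    """R2 between interaction coefficient vectors over genes, per type pair.

    For each ordered (sender, receiver) pair the subsampled fit's coefficient
    vector b is compared against the full fit's a via
    R2 = 1 - sum_j (a_j - b_j)^2 / sum_j (a_j - mean(a))^2.
    """
    if not np.array_equal(fit_full.gene_names, fit_sub.gene_names):
        raise ValueError("gene sets of the two fits differ")
    prov_full = fit_full.design.column_provenance
    prov_sub = {p: i for i, p in enumerate(fit_sub.design.column_provenance)}
    rows = []
    for i, p in enumerate(prov_full):
        if p[0] != "interaction":
            continue
        if p not in prov_sub:
            raise ValueError(f"pair {p} missing from subsampled fit")
        a = fit_full.coefficients[i]
        b = fit_sub.coefficients[prov_sub[p]]
        tot = ((a - a.mean()) ** 2).sum()
        r2 = 1.0 - ((a - b) ** 2).sum() / tot if tot > 0 else np.nan
        rows.append({"receiver": p[1], "sender": p[2], "r2": r2})
    return pd.DataFrame(rows)
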