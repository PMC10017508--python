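"""Ligand-receptor graph-kernel NCEM.

Instead of categorical niche composition, each cell is embedded into a
K-dimensional receptor-activity space, one latent unit per ligand-receptor
pair: z_ik = sum over neighbours m of f_R(receptor expression of cell i) *
f_L(ligand expression of neighbour m).  A fully connected decoder maps
[z, domain] to the full expression vector; the nonspatial baseline feeds the
index cell's own receptor expression through the same decoder.  Differential
receptor activity between cells with and without a given sender type in the
niche is ranked by a two-sample t-test per latent unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .autodiff import Tensor, concat, sparse_matmul
from .core import CellGraph, SpatialDataset, SplitAssignment, split_nodes
from .linear import r_squared, sender_presence
from .neural import MLP, TrainingConfig, train

__all__ = [
    "LigandReceptorMap",
    "ReceptorActivity",
    "lr_kernel",
    "LigandReceptorNCEM",
    "fit_lr_ncem",
    "differential_receptor_activity",
    "sender_presence_groups",
]


@dataclass
class LigandReceptorMap:
    """Ligand-receptor pairs resolved to gene indices of a dataset."""

    receptors: np.ndarray  # gene indices r(k)
    ligands: np.ndarray  # gene indices l(k)
    names: list[tuple[str, str]]

    @classmethod
    def from_names(cls, pairs, gene_names) -> "LigandReceptorMap":
        """Resolve (receptor, ligand) gene-name pairs; unresolved names error."""
        gene_names = list(gene_names)
        index = {g: i for i, g in enumerate(gene_names)}
        missing = sorted(
            {g for pair in pairs for g in pair if g not in index}
        )
        if missing:
            raise ValueError(f"genes not in dataset: {missing}")
        seen = set()
        rs, ls, names = [], [], []
        for r, l in pairs:
            if (r, l) in seen:
                continue
            seen.add((r, l))
            rs.append(index[r])
            ls.append(index[l])
            names.append((r, l))
        return cls(np.asarray(rs), np.asarray(ls), names)

    @property
    def n_pairs(self) -> int:
        return len(self.receptors)


@dataclass
class ReceptorActivity:
    """Per-cell receptor-activity latents, one column per LR pair."""

    z: np.ndarray
    pairs: list[tuple[str, str]]


def lr_kernel(
    y: np.ndarray,
    graph: CellGraph,
    lr_map: LigandReceptorMap,
    f_r=None,
    f_l=None,
) -> ReceptorActivity:
    """Receptor-activity kernel: receptor on the index cell, ligand on neighbours.

    z_ik = f_R(y_{i, r(k)}) * sum_{m in neighbours(i)} f_L(y_{m, l(k)}).
    Default transforms are the identity; isolated cells get z = 0.
    """
    y = np.asarray(y, dtype=float)
    f_r = f_r or (lambda x: x)
    f_l = f_l or (lambda x: x)
    rec = f_r(y[:, lr_map.receptors])  # (N, K)
    lig = f_l(y[:, lr_map.ligands])  # (N, K)
    z = rec * (graph.adjacency @ lig)
    return ReceptorActivity(z=z, pairs=list(lr_map.names))


class LigandReceptorNCEM:
    """Decoder over the receptor-activity latents (or the receptor baseline).

    ``spatial=False`` gives the nonspatial baseline: the decoder input is the
    index cell's own receptor expression instead of the graph kernel.  With
    ``learn_transforms`` the per-pair transforms become softplus(w x + b)
    with learned scalars, and gradients flow through the kernel.
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        graph: CellGraph,
        lr_map: LigandReceptorMap,
        hidden_width: int = 16,
        depth: int = 1,
        spatial: bool = True,
        learn_transforms: bool = False,
        seed: int = 0,
    ):
        if lr_map.n_pairs == 0:
            raise ValueError("need at least one ligand-receptor pair")
        self.dataset = dataset
        self.graph = graph
        self.lr_map = lr_map
        self.spatial = spatial
        self.learn_transforms = learn_transforms and spatial
        rng = np.random.default_rng(seed)
        self.y = dataset.expression
        self.xc = dataset.domain_onehot()
        n, j = self.y.shape
        k = lr_map.n_pairs
        self._rec = self.y[:, lr_map.receptors]
        self._lig = self.y[:, lr_map.ligands]
        # decoder inputs are z-scored internally: kernel latents scale with
        # expression x degree and would otherwise dwarf the covariates
        self._norm: tuple[np.ndarray, np.ndarray] | None = None
        self._params: list[Tensor] = []
        if self.learn_transforms:
            self.w_r = Tensor(np.ones((1, k)), requires_grad=True)
            self.b_r = Tensor(np.zeros((1, k)), requires_grad=True)
            self.w_l = Tensor(np.ones((1, k)), requires_grad=True)
            self.b_l = Tensor(np.zeros((1, k)), requires_grad=True)
            self._params += [self.w_r, self.b_r, self.w_l, self.b_l]
        elif spatial:
            self.z_const = lr_kernel(self.y, graph, lr_map).z
        hidden = [hidden_width] * max(depth, 1)
        self.decoder = MLP([k + self.xc.shape[1], *hidden, j], rng)
        self.log_sigma = Tensor(np.zeros((1, j)), requires_grad=True)
        self._params += self.decoder.params() + [self.log_sigma]

    def params(self) -> list[Tensor]:
        return self._params

    def _standardize(self, z: Tensor) -> Tensor:
        if self._norm is None:
            if not self.spatial:
                ref = self._rec
            elif self.learn_transforms:
                ref = np.logaddexp(0.0, self._rec) * (
                    self.graph.adjacency @ np.logaddexp(0.0, self._lig)
                )
            else:
                ref = self.z_const
            sd = ref.std(axis=0)
            self._norm = (ref.mean(axis=0), np.where(sd > 0, sd, 1.0))
        mu, sd = self._norm
        return (z - mu) * (1.0 / sd)

    def _latent(self, idx: np.ndarray):
        if not self.spatial:
            return self._standardize(Tensor(self._rec[idx]))
        if not self.learn_transforms:
            return self._standardize(Tensor(self.z_const[idx]))
        rec = (Tensor(self._rec) * self.w_r + self.b_r).softplus()
        lig = (Tensor(self._lig) * self.w_l + self.b_l).softplus()
        pooled = sparse_matmul(self.graph.adjacency, lig)
        z = rec * pooled
        sub = Tensor(z.data[idx], _parents=(z,), _backward=lambda g: (_scatter(g, idx, z.shape),))
        return self._standardize(sub)

    def forward(self, idx: np.ndarray | None = None) -> Tensor:
        idx = np.arange(self.y.shape[0]) if idx is None else np.asarray(idx)
        return self.decoder.forward(concat([self._latent(idx), Tensor(self.xc[idx])]))

    def loss(self, idx: np.ndarray | None = None) -> Tensor:
        idx = np.arange(self.y.shape[0]) if idx is None else np.asarray(idx)
        y_hat = self.forward(idx)
        resid2 = (Tensor(self.y[idx]) - y_hat) ** 2.0
        ll = -0.5 * np.log(2 * np.pi) - self.log_sigma - 0.5 * resid2 * (self.log_sigma * -2.0).exp()
        nll = -ll.mean()
        if not np.isfinite(nll.data):
            raise FloatingPointError("non-finite training loss")
        return nll

    def predict(self, idx: np.ndarray | None = None) -> np.ndarray:
        return self.forward(idx).data

    def receptor_activity(self) -> ReceptorActivity:
        if not self.spatial:
            raise ValueError("the nonspatial baseline has no graph kernel")
        if self.learn_transforms:
            rec = np.logaddexp(0.0, self._rec * self.w_r.data + self.b_r.data)
            lig = np.logaddexp(0.0, self._lig * self.w_l.data + self.b_l.data)
            z = rec * (self.graph.adjacency @ lig)
        else:
            z = self.z_const
        return ReceptorActivity(z=z, pairs=list(self.lr_map.names))


def _scatter(g: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape)
    out[idx] = g
    return out


def fit_lr_ncem(
    dataset: SpatialDataset,
    graph: CellGraph,
    lr_map: LigandReceptorMap,
    training_config: TrainingConfig | None = None,
    splits: SplitAssignment | None = None,
    hidden_width: int = 16,
    depth: int = 1,
    learn_transforms: bool = False,
    seed: int = 0,
) -> dict:
    """Train the LR-kernel NCEM and the receptor-expression baseline.

    Both models share the decoder architecture and the splits; the summary
    reports the pooled test R2 of each (against training gene means).
    """
    training_config = training_config or TrainingConfig()
    splits = splits or split_nodes(dataset, seed)
    out = {}
    for name, spatial in (("lr_ncem", True), ("baseline", False)):
        model = LigandReceptorNCEM(
            dataset, graph, lr_map, hidden_width, depth,
            spatial=spatial, learn_transforms=learn_transforms, seed=seed,
        )
        hist = train(model, splits, training_config, domain=dataset.domain)
        mu = dataset.expression[splits.train].mean(axis=0)
        _, pooled = r_squared(dataset.expression[splits.test], model.predict(splits.test), mu)
        out[name] = {"model": model, "history": hist, "test_r2": pooled}
    out["delta_r2"] = out["lr_ncem"]["test_r2"] - out["baseline"]["test_r2"]
    return out


def sender_presence_groups(
    dataset: SpatialDataset,
    graph: CellGraph,
    receiver,
    sender,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of receiver-type cells with / without the sender in the niche."""
    xl = dataset.type_onehot()
    pres = sender_presence(graph, xl)
    s_col = int(np.flatnonzero(dataset.type_levels == sender)[0])
    recv = dataset.cell_type == receiver
    with_mask = recv & (pres[:, s_col] > 0)
    without_mask = recv & (pres[:, s_col] == 0)
    return np.flatnonzero(with_mask), np.flatnonzero(without_mask)


def differential_receptor_activity(
    activity: ReceptorActivity | np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    pairs: list | None = None,
) -> pd.DataFrame:
    """Two-sample t-test per latent unit, BH-corrected, ranked by p.

    ``group_a`` / ``group_b`` are cell indices (e.g. receiver cells with and
    without a sender type in the niche).  Returns a table with columns
    receptor, ligand, t, p, q, mean_with, mean_without, sorted by p.
    """
    z = activity.z if isinstance(activity, ReceptorActivity) else np.asarray(activity)
    if pairs is None:
        pairs = activity.pairs if isinstance(activity, ReceptorActivity) else [
            (f"unit_{k}", "") for k in range(z.shape[1])
        ]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    za, zb = z[np.asarray(group_a)], z[np.asarray(group_b)]
    t, p = stats.ttest_ind(za, zb, axis=0, equal_var=True)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "receptor": [r for r, _ in pairs],
            "ligand": [l for _, l in pairs],
            "t": t,
            "p": p,
            "q": q,
            "mean_with": za.mean(axis=0),
            "mean_without": zb.mean(axis=0),
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)
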