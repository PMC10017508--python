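"""Conditional variational autoencoder NCEM.

Models cell-intrinsic latent states z alongside the niche: the amortised
posterior q(z | Y, type, niche embedding, domain) and the decoder
p(Y | z, type, niche embedding, domain) share the conditioning set, and the
objective is the negative Gaussian log-likelihood plus the KL divergence of
the posterior from a standard-normal prior.  Because the encoder sees the
expression vector itself, reconstruction is far easier than for the
deterministic models — but niche information can hide inside z, so a spatial
advantage over the nonspatial CVAE is not guaranteed.  Style transfer decodes
one cell's latent state under another cell's conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .core import CellGraph, SpatialDataset, SplitAssignment, split_nodes
from .linear import gaussian_ll, r_squared
from .neural import MLP, TrainingConfig, train, indicator_embed

__all__ = [
    "CvaeConfig",
    "kl_divergence",
    "cvae_loss",
    "CvaeNCEM",
    "fit_cvae",
    "style_transfer",
]


@dataclass
class CvaeConfig:
    """Architecture and objective weights of the CVAE."""

    latent_dim: int = 8
    hidden_width: int = 32
    depth: int = 1
    kl_weight: float = 1.0
    target_cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent dimension must be >= 1")


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-node KL of a diagonal Gaussian posterior from the N(0, I) prior.

    KL_i = 0.5 * sum_d (mu_id^2 + var_id - 1 - log var_id); zero exactly when
    the posterior equals the prior.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=-1)


def cvae_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    sigma: np.ndarray,
    mu: np.ndarray,
    logvar: np.ndarray,
    kl_weight: float = 1.0,
) -> float:
    """Negative mean data log-likelihood plus the KL term.

    The KL is averaged per node and divided by the gene count so both terms
    share the 1/(N*J) normalisation of the likelihood.
    """
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("non-finite posterior parameters")
    j = np.asarray(y).shape[1]
    return -gaussian_ll(y, y_hat, sigma) + kl_weight * float(
        kl_divergence(mu, logvar).mean()
    ) / j


class CvaeNCEM:
    """CVAE over node expression conditioned on type, niche and domain.

    ``spatial=False`` drops the niche embedding from both encoder and decoder
    (the nonspatial CVAE baseline).  ``target_cell_type`` restricts training
    and evaluation to one receiver type, the mitigation for the
    non-identifiability between the latent space and cell-type variation.
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        graph: CellGraph | None,
        config: CvaeConfig | None = None,
        spatial: bool = True,
        seed: int = 0,
    ):
        self.config = config or CvaeConfig()
        self.spatial = spatial
        cfg = self.config
        xl_full = dataset.type_onehot()
        embed_full = (
            indicator_embed(graph, xl_full) if spatial else np.zeros((dataset.n_cells, 0))
        )
        if cfg.target_cell_type is not None:
            keep = np.flatnonzero(dataset.cell_type == cfg.target_cell_type)
            if len(keep) == 0:
                raise ValueError(f"no cells of type {cfg.target_cell_type!r}")
        else:
            keep = np.arange(dataset.n_cells)
        self.cell_index = keep
        self.y = dataset.expression[keep]
        self.xl = xl_full[keep]
        self.xc = dataset.domain_onehot()[keep]
        self.embed = embed_full[keep]
        self.domain = dataset.domain[keep]
        self.dataset = dataset
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(seed + 1)
        n, j = self.y.shape
        cond_dim = self.xl.shape[1] + self.embed.shape[1] + self.xc.shape[1]
        hidden = [cfg.hidden_width] * max(cfg.depth, 1)
        self.enc_trunk = MLP([j + cond_dim, *hidden], rng)
        self.enc_mu = MLP([hidden[-1], cfg.latent_dim], rng)
        self.enc_logvar = MLP([hidden[-1], cfg.latent_dim], rng)
        # start with a tight posterior (var ~ e^-3): the reparameterised
        # sample then tracks the mean early in training, which keeps the
        # gradient signal through z from being drowned by sampling noise
        self.enc_logvar.biases[-1].data[...] = -3.0
        self.decoder = MLP([cfg.latent_dim + cond_dim, *hidden, j], rng)
        self.log_sigma = Tensor(np.zeros((1, j)), requires_grad=True)
        self._params = (
            self.enc_trunk.params()
            + self.enc_mu.params()
            + self.enc_logvar.params()
            + self.decoder.params()
            + [self.log_sigma]
        )

    def params(self) -> list[Tensor]:
        return self._params

    def _conditions(self, idx: np.ndarray) -> Tensor:
        parts = [Tensor(self.xl[idx])]
        if self.embed.shape[1]:
            parts.append(Tensor(self.embed[idx]))
        parts.append(Tensor(self.xc[idx]))
        return concat(parts)

    def encode(self, idx: np.ndarray) -> tuple[Tensor, Tensor]:
        cond = self._conditions(idx)
        h = self.enc_trunk.forward(concat([Tensor(self.y[idx]), cond]))
        # the trunk's last layer is linear; rectify before the heads
        h = h.relu()
        return self.enc_mu.forward(h), self.enc_logvar.forward(h)

    def decode(self, z: Tensor, idx: np.ndarray) -> Tensor:
        return self.decoder.forward(concat([z, self._conditions(idx)]))

    def loss(self, idx: np.ndarray | None = None, sample: bool = True) -> Tensor:
        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        mu, logvar = self.encode(idx)
        if sample:
            eps = self._rng.standard_normal(mu.shape)
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        y_hat = self.decode(z, idx)
        resid2 = (Tensor(self.y[idx]) - y_hat) ** 2.0
        ll = -0.5 * np.log(2 * np.pi) - self.log_sigma - 0.5 * resid2 * (self.log_sigma * -2.0).exp()
        j = self.y.shape[1]
        kl = 0.5 * ((mu**2.0) + logvar.exp() - 1.0 - logvar).sum(axis=1).mean()
        total = -ll.mean() + (self.config.kl_weight / j) * kl
        if not np.isfinite(total.data):
            raise FloatingPointError("non-finite training loss")
        return total

    def val_loss(self, idx: np.ndarray | None = None) -> Tensor:
        """Deterministic objective at the posterior mean, for monitoring."""
        return self.loss(idx, sample=False)

    def posterior_mean(self, idx: np.ndarray | None = None) -> np.ndarray:
        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        mu, _ = self.encode(idx)
        return mu.data

    def predict(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Reconstruction from the posterior mean (no sampling)."""
        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        mu, _ = self.encode(idx)
        return self.decode(mu, idx).data

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma.data.ravel())


def fit_cvae(
    dataset: SpatialDataset,
    graph: CellGraph | None,
    config: CvaeConfig | None = None,
    training_config: TrainingConfig | None = None,
    splits: SplitAssignment | None = None,
    spatial: bool = True,
    seed: int = 0,
    lr_grid=None,
) -> tuple[CvaeNCEM, object, dict]:
    """Train the CVAE and report posterior-mean reconstruction R2 on test cells.

    With ``lr_grid`` one model per learning rate is trained and the one with
    the best (posterior-mean) validation loss is kept; diverging grid members
    are discarded.
    """
    training_config = training_config or TrainingConfig()
    lr_grid = list(lr_grid) if lr_grid is not None else [training_config.learning_rate]
    first = CvaeNCEM(dataset, graph, config, spatial=spatial, seed=seed)
    splits = splits or split_nodes(len(first.y), seed)
    best = None
    for lr in lr_grid:
        cfg = TrainingConfig(
            learning_rate=lr,
            max_epochs=training_config.max_epochs,
            scheduler_patience=training_config.scheduler_patience,
            scheduler_factor=training_config.scheduler_factor,
            early_stopping_patience=training_config.early_stopping_patience,
            nodes_per_image=training_config.nodes_per_image,
            seed=training_config.seed,
        )
        model = CvaeNCEM(dataset, graph, config, spatial=spatial, seed=seed)
        try:
            hist = train(model, splits, cfg, domain=model.domain)
        except FloatingPointError:
            continue
        # grid members are compared on validation reconstruction R2
        mu_train = model.y[splits.train].mean(axis=0)
        _, val_r2 = r_squared(
            model.y[splits.validation], model.predict(splits.validation), mu_train
        )
        if best is None or val_r2 > best[2]:
            best = (model, hist, val_r2)
    if best is None:
        raise FloatingPointError("training diverged at every learning rate in the grid")
    model, hist, _ = best
    mu_train = model.y[splits.train].mean(axis=0)
    _, pooled = r_squared(model.y[splits.test], model.predict(splits.test), mu_train)
    return model, hist, {"reconstruction_r2": pooled}


def style_transfer(
    model: CvaeNCEM,
    source_cell: int,
    target_cell: int,
    sample: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Decode the source cell's latent state under the target cell's conditions.

    Uses the posterior mean by default; with ``sample=True`` one latent draw
    from the posterior is decoded (seeded).  Indices refer to the model's
    (possibly type-restricted) cell set.
    """
    n = len(model.y)
    for c in (source_cell, target_cell):
        if not 0 <= c < n:
            raise IndexError(f"cell index {c} out of range [0, {n})")
    mu, logvar = model.encode(np.array([source_cell]))
    z = mu.data
    if sample:
        eps = np.random.default_rng(seed).standard_normal(z.shape)
        z = z + np.exp(0.5 * logvar.data) * eps
    return model.decode(Tensor(z), np.array([target_cell])).data[0]
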