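"""Nonlinear node-centric expression models and the shared training loop.

A nonlinear NCEM encodes a cell's niche either with the parameter-free
indicator aggregator (binary per-type presence among neighbours, excluding the
index cell) or a one-layer graph convolution softmax(ReLU(Abar X_l W)), feeds
[type one-hot, niche embedding, domain one-hot] through an encoder MLP into a
latent state z, and decodes [z, type, domain] to the expression mean; the
gene-wise noise SD is a free positive parameter.  With the indicator
aggregator and no hidden layers the model degenerates to a single linear map
on the interaction design and is the linear NCEM trained by gradient descent.

The training loop (Adam, reduce-on-plateau scheduler, early stopping, node
subsampling per image per step) is shared by the LR-kernel and CVAE models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, concat
from .core import CellGraph, SpatialDataset, SplitAssignment, size_factors, split_nodes
from .linear import build_design, r_squared, sender_presence

__all__ = [
    "NicheEncoderConfig",
    "TrainingConfig",
    "MLP",
    "gcn_embed",
    "indicator_embed",
    "NonlinearNCEM",
    "train",
    "fit_nl_ncem",
]


@dataclass
class NicheEncoderConfig:
    """Architecture of the niche encoder and decoder stacks."""

    aggregator: str = "indicator"  # "indicator" or "gcn"
    hidden_width: int = 16
    depth: int = 1
    activation: str = "relu"
    latent_dim: int = 8
    gcn_width: int = 8  # H, dimension of the learned GCN node representation

    def __post_init__(self) -> None:
        if self.aggregator not in ("indicator", "gcn"):
            raise ValueError("aggregator must be 'indicator' or 'gcn'")
        if self.aggregator == "gcn" and self.gcn_width < 1:
            raise ValueError("gcn embedding width must be >= 1")


@dataclass
class TrainingConfig:
    """Adam schedule: reduce-on-plateau scheduler and early stopping."""

    learning_rate: float = 0.05
    max_epochs: int = 500
    scheduler_patience: int = 20
    scheduler_factor: float = 0.5
    early_stopping_patience: int = 100
    nodes_per_image: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheduler_patience <= 0 or self.early_stopping_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


LR_GRID = (0.5, 0.05, 0.005)


def gcn_embed(abar, xl: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One-layer graph convolution softmax(ReLU(Abar X_l W)), per-node softmax.

    Rows of the embedding sum to one; isolated nodes (all-zero Abar row) get
    the uniform embedding 1/H.
    """
    pre = np.maximum(np.asarray(abar @ xl) @ w, 0.0)
    e = np.exp(pre - pre.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def indicator_embed(graph: CellGraph, xl: np.ndarray) -> np.ndarray:
    """Binary per-type presence among neighbours; alias of sender_presence."""
    return sender_presence(graph, xl)


class MLP:
    """Fully connected stack with a linear output layer.

    Weights use a small symmetric init scaled by 1/sqrt(fan_in) from the
    provided generator, so runs are reproducible from the seed alone.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator, activation: str = "relu"):
        self.activation = activation
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros((1, fan_out)), requires_grad=True))

    def params(self) -> list[Tensor]:
        return self.weights + self.biases

    def forward(self, x) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.tanh() if self.activation == "tanh" else h.relu()
        return h


class NonlinearNCEM:
    """Deterministic nonlinear NCEM (or its nonspatial twin).

    ``spatial=False`` removes the niche embedding from the encoder input and
    yields the nonspatial neural baseline.  ``scale_node_size`` multiplies
    predictions cell-wise by the size factors.
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        graph: CellGraph | None,
        config: NicheEncoderConfig | None = None,
        spatial: bool = True,
        scale_node_size: bool = False,
        seed: int = 0,
    ):
        self.config = config or NicheEncoderConfig()
        self.dataset = dataset
        self.graph = graph
        self.spatial = spatial
        rng = np.random.default_rng(seed)
        self.xl = dataset.type_onehot()
        self.xc = dataset.domain_onehot()
        self.y = dataset.expression
        n, j = self.y.shape
        l, c = self.xl.shape[1], self.xc.shape[1]
        self.sf = size_factors(dataset)[:, None] if scale_node_size else None
        self.log_sigma = Tensor(np.zeros((1, j)), requires_grad=True)
        self._params: list[Tensor] = [self.log_sigma]
        self.gcn_w: Tensor | None = None
        cfg = self.config

        if spatial and graph is None:
            raise ValueError("spatial model needs a cell graph")
        self._linear_mode = spatial and cfg.depth == 0 and cfg.aggregator == "indicator"
        if self._linear_mode:
            # zero-depth indicator model: a single linear map on the
            # interaction design (receiver one-hot x niche indicator), i.e.
            # the linear NCEM trained by gradient descent
            design = build_design(dataset, graph, "interaction")
            self.design_values = design.values
            self.w_lin = Tensor(
                rng.normal(0.0, 0.01, size=(design.values.shape[1], j)), requires_grad=True
            )
            self._params.append(self.w_lin)
            return
        if spatial:
            if cfg.aggregator == "indicator":
                self.embed_const = indicator_embed(graph, self.xl)
                embed_dim = l
            else:
                self.h0 = np.asarray(graph.normalized_adjacency @ self.xl)
                self.gcn_w = Tensor(
                    rng.normal(0.0, 1.0 / np.sqrt(l), size=(l, cfg.gcn_width)),
                    requires_grad=True,
                )
                self._params.append(self.gcn_w)
                embed_dim = cfg.gcn_width
        else:
            embed_dim = 0
        enc_in = l + embed_dim + c
        hidden = [cfg.hidden_width] * max(cfg.depth, 1)
        self.encoder = MLP([enc_in, *hidden, cfg.latent_dim], rng, cfg.activation)
        self.decoder = MLP([cfg.latent_dim + l + c, *hidden, j], rng, cfg.activation)
        self._params += self.encoder.params() + self.decoder.params()

    def params(self) -> list[Tensor]:
        return self._params

    def _embedding(self, idx: np.ndarray):
        if self.config.aggregator == "indicator":
            return Tensor(self.embed_const[idx])
        pre = (Tensor(self.h0[idx]) @ self.gcn_w).relu()
        return pre.softmax(axis=1)

    def forward(self, idx: np.ndarray | None = None) -> Tensor:
        n = self.y.shape[0]
        idx = np.arange(n) if idx is None else np.asarray(idx)
        if self._linear_mode:
            out = Tensor(self.design_values[idx]) @ self.w_lin
        else:
            parts = [Tensor(self.xl[idx])]
            if self.spatial:
                parts.append(self._embedding(idx))
            parts.append(Tensor(self.xc[idx]))
            z = self.encoder.forward(concat(parts))
            out = self.decoder.forward(concat([z, Tensor(self.xl[idx]), Tensor(self.xc[idx])]))
        if self.sf is not None:
            out = out * self.sf[idx]
        return out

    def loss(self, idx: np.ndarray | None = None) -> Tensor:
        """Negative mean Gaussian log-likelihood on the indexed cells."""
        n = self.y.shape[0]
        idx = np.arange(n) if idx is None else np.asarray(idx)
        y_hat = self.forward(idx)
        resid2 = (Tensor(self.y[idx]) - y_hat) ** 2.0
        ll = (
            -0.5 * np.log(2 * np.pi)
            - self.log_sigma
            - 0.5 * resid2 * (self.log_sigma * -2.0).exp()
        )
        nll = -ll.mean()
        if not np.isfinite(nll.data):
            raise FloatingPointError("non-finite training loss; check inputs and learning rate")
        return nll

    def predict(self, idx: np.ndarray | None = None) -> np.ndarray:
        return self.forward(idx).data

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma.data.ravel())


def nl_ncem_forward(model: NonlinearNCEM) -> tuple[np.ndarray, np.ndarray]:
    """Predicted means for all cells and the gene-wise noise SDs."""
    return model.predict(), model.sigma


@dataclass
class TrainingHistory:
    epochs: pd.DataFrame
    best_epoch: int
    best_val_loss: float

    def learning_rates(self) -> np.ndarray:
        return self.epochs["lr"].to_numpy()


def train(
    model,
    splits: SplitAssignment,
    config: TrainingConfig,
    domain: np.ndarray | None = None,
) -> TrainingHistory:
    """Optimize the model's loss with Adam, scheduler and early stopping.

    Each step samples ``nodes_per_image`` training cells from every image
    (all images in one batch).  Validation loss is monitored every epoch; the
    learning rate halves after ``scheduler_patience`` non-improving epochs,
    training stops after ``early_stopping_patience``, and the parameters of
    the best validation epoch are restored.  Deterministic given the seed.
    """
    val_idx = splits.validation
    if len(val_idx) == 0:
        raise ValueError("empty validation set")
    train_idx = splits.train
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    if domain is None:
        domain = getattr(model, "dataset", None)
        domain = domain.domain if domain is not None else np.zeros(0)
    dom_train = np.asarray(domain)[train_idx] if len(np.asarray(domain)) else None

    best_val = np.inf
    best_state = [p.data.copy() for p in model.params()]
    best_epoch = 0
    plateau = 0
    since_best = 0
    rows = []
    for epoch in range(config.max_epochs):
        if dom_train is not None and len(dom_train):
            batch = []
            for d in np.unique(dom_train):
                pool = train_idx[dom_train == d]
                k = min(config.nodes_per_image, len(pool))
                batch.append(rng.choice(pool, size=k, replace=False))
            batch = np.concatenate(batch)
        else:
            k = min(config.nodes_per_image, len(train_idx))
            batch = rng.choice(train_idx, size=k, replace=False)
        opt.zero_grad()
        loss = model.loss(batch)
        loss.backward()
        opt.step()
        # stochastic objectives expose a deterministic val_loss for monitoring
        monitor = getattr(model, "val_loss", model.loss)
        val_loss = float(monitor(val_idx).data)
        rows.append({"epoch": epoch, "train_loss": float(loss.data),
                     "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.params()]
            best_epoch = epoch
            plateau = 0
            since_best = 0
        else:
            plateau += 1
            since_best += 1
            if plateau >= config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                plateau = 0
            if since_best >= config.early_stopping_patience:
                break
    for p, s in zip(model.params(), best_state):
        p.data[...] = s
    return TrainingHistory(pd.DataFrame(rows), best_epoch, best_val)


def fit_nl_ncem(
    dataset: SpatialDataset,
    graph: CellGraph | None,
    encoder_config: NicheEncoderConfig | None = None,
    training_config: TrainingConfig | None = None,
    lr_grid=None,
    splits: SplitAssignment | None = None,
    spatial: bool = True,
    seed: int = 0,
) -> tuple[NonlinearNCEM, TrainingHistory, dict]:
    """Train across a learning-rate grid and keep the best-validation model.

    Returns the selected model, its training history, and a summary with the
    pooled test R2 (against training gene means) per grid member and for the
    winner.
    """
    training_config = training_config or TrainingConfig()
    lr_grid = list(lr_grid) if lr_grid is not None else [training_config.learning_rate]
    splits = splits or split_nodes(dataset, seed)
    mu = dataset.expression[splits.train].mean(axis=0)
    best = None
    grid_rows = []
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
        model = NonlinearNCEM(dataset, graph, encoder_config, spatial=spatial, seed=seed)
        try:
            hist = train(model, splits, cfg, domain=dataset.domain)
        except FloatingPointError:
            grid_rows.append({"lr": lr, "val_loss": np.inf, "val_r2": -np.inf})
            continue
        # grid members are compared on validation R2
        _, val_r2 = r_squared(
            dataset.expression[splits.validation], model.predict(splits.validation), mu
        )
        grid_rows.append({"lr": lr, "val_loss": hist.best_val_loss, "val_r2": val_r2})
        if best is None or val_r2 > best[3]:
            best = (model, hist, lr, val_r2)
    if best is None:
        raise FloatingPointError("training diverged at every learning rate in the grid")
    model, hist, lr, _ = best
    _, pooled = r_squared(
        dataset.expression[splits.test], model.predict(splits.test), mu
    )
    summary = {"test_r2": pooled, "selected_lr": lr, "grid": pd.DataFrame(grid_rows)}
    return model, hist, summary
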