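"""Linear node-centric expression models.

The interaction-variant linear NCEM predicts expression as Yhat = X_D beta with
X_D = (X_l | X_TS | X_c): receiver-type one-hots, receiver x sender interaction
indicators (outer product of the index cell's one-hot type with the binary
sender-presence summary of its niche), and domain one-hots.  Coefficients of
the interaction block are tested gene-wise with a Wald test and BH-corrected;
significant interaction coefficients are the raw material of type-coupling
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CellGraph, SpatialDataset, build_graph, split_nodes

__all__ = [
    "DesignMatrix",
    "LinearFit",
    "sender_presence",
    "build_design",
    "fit_ols",
    "wald_test",
    "gaussian_ll",
    "r_squared",
    "resolution_screen",
]

VARIANTS = ("baseline", "global_sender", "interaction")


def sender_presence(graph: CellGraph, types: np.ndarray) -> np.ndarray:
    """Binary (N, L) niche summary: 1 iff some neighbour has the sender type.

    The index cell itself is excluded (the adjacency has zero diagonal), so a
    cell's own type never marks sender presence.
    """
    types = np.asarray(types, dtype=float)
    if types.shape[0] != graph.n_cells:
        raise ValueError("types and graph must cover the same cells")
    return (graph.adjacency @ types > 0).astype(float)


@dataclass
class DesignMatrix:
    """Predictor block with per-column provenance.

    ``column_provenance`` entries are tuples: ``("receiver_type", type)``,
    ``("sender_presence", type)``, ``("interaction", receiver, sender)`` or
    ``("domain", label)``.  Interaction columns are laid out receiver-major:
    pair (r, s) sits at column offset r*L + s within the interaction block.
    """

    values: np.ndarray
    column_provenance: list[tuple]
    model_variant: str
    type_levels: np.ndarray
    domain_levels: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def interaction_columns(self) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.column_provenance) if p[0] == "interaction"],
            dtype=int,
        )


def build_design(
    dataset: SpatialDataset,
    graph: CellGraph | None,
    variant: str = "interaction",
) -> DesignMatrix:
    """Assemble (X_l | spatial block | X_c) for the requested model variant.

    ``baseline`` uses no spatial block, ``global_sender`` appends the raw
    sender-presence indicators, ``interaction`` appends the receiver-major
    flattened outer product of receiver one-hot and sender presence.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    xl = dataset.type_onehot()
    xc = dataset.domain_onehot()
    levels = dataset.type_levels
    prov: list[tuple] = [("receiver_type", t) for t in levels]
    blocks = [xl]
    if variant != "baseline":
        if graph is None:
            raise ValueError("spatial variants need a cell graph")
        xs = sender_presence(graph, xl)
        if variant == "global_sender":
            blocks.append(xs)
            prov += [("sender_presence", t) for t in levels]
        else:
            l = len(levels)
            xts = (xl[:, :, None] * xs[:, None, :]).reshape(len(xl), l * l)
            blocks.append(xts)
            prov += [("interaction", r, s) for r in levels for s in levels]
    blocks.append(xc)
    prov += [("domain", d) for d in dataset.domain_levels]
    return DesignMatrix(
        values=np.hstack(blocks),
        column_provenance=prov,
        model_variant=variant,
        type_levels=levels,
        domain_levels=dataset.domain_levels,
    )


@dataclass
class LinearFit:
    """OLS fit of one design against all genes.

    ``coefficients`` is (P, J); standard errors come from the gene-wise
    residual variance times the diagonal of the generalised inverse of
    X'X.  ``sigma`` is the maximum-likelihood residual SD per gene
    (denominator N), used by the Gaussian likelihood.  ``testable`` flags
    columns whose coefficients admit a Wald test (observed and not exactly
    collinear with other columns).
    """

    design: DesignMatrix
    coefficients: np.ndarray
    standard_errors: np.ndarray
    sigma: np.ndarray
    rank: int
    n_obs: int
    testable: np.ndarray
    gene_names: np.ndarray
    p_values: pd.DataFrame | None = None
    q_values: pd.DataFrame | None = None

    @property
    def dof(self) -> int:
        return self.n_obs - self.rank

    def predict(self, design_values: np.ndarray | None = None) -> np.ndarray:
        x = self.design.values if design_values is None else design_values
        return x @ self.coefficients


def _flag_nontestable(x: np.ndarray, rank: int) -> np.ndarray:
    """Columns lying in the span of the others (or all-zero) are not testable."""
    p = x.shape[1]
    testable = np.ones(p, dtype=bool)
    zero = ~np.any(x != 0, axis=0)
    testable[zero] = False
    if rank < p:
        for c in np.flatnonzero(~zero):
            others = np.delete(x, c, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                testable[c] = False
    return testable


def fit_ols(design: DesignMatrix, y: np.ndarray, gene_names=None) -> LinearFit:
    """Gene-wise ordinary least squares with minimum-norm rank handling.

    Coefficients minimise the squared error per gene; rank-deficient designs
    get the minimum-norm solution and the affected columns are flagged
    non-testable.  Standard errors use sigma2_j * diag(pinv(X'X)) with the
    unbiased residual variance (denominator N - rank).
    """
    x = design.values
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if y.shape[0] != n:
        raise ValueError("design and response row counts differ")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = (resid**2).sum(axis=0)
    dof = max(n - rank, 1)
    sigma2_unbiased = rss / dof
    sigma_ml = np.sqrt(rss / n)
    xtx_pinv_diag = np.diag(np.linalg.pinv(x.T @ x, hermitian=True))
    se = np.sqrt(np.clip(np.outer(xtx_pinv_diag, sigma2_unbiased), 0.0, None))
    testable = _flag_nontestable(x, rank)
    if gene_names is None:
        gene_names = np.array([f"gene_{j}" for j in range(y.shape[1])])
    return LinearFit(
        design=design,
        coefficients=beta,
        standard_errors=se,
        sigma=sigma_ml,
        rank=int(rank),
        n_obs=n,
        testable=testable,
        gene_names=np.asarray(gene_names),
    )


def wald_test(fit: LinearFit, columns: np.ndarray | None = None) -> pd.DataFrame:
    """Two-sided Wald test beta/SE ~ t(N - rank) with joint BH correction.

    By default tests every testable interaction column of the design against
    every gene; q-values are BH-adjusted jointly across all tested
    (column, gene) pairs.  Returns a long table with columns
    receiver, sender, gene, beta, se, t, p, q.  The fit's ``p_values`` /
    ``q_values`` wide frames are populated as a side effect.
    """
    if columns is None:
        columns = fit.design.interaction_columns()
    columns = np.asarray(columns, dtype=int)
    tested = columns[fit.testable[columns]]
    if len(tested) == 0:
        raise ValueError("no testable columns")
    beta = fit.coefficients[tested]
    se = fit.standard_errors[tested]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=fit.dof)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    rows = []
    for i, c in enumerate(tested):
        prov = fit.design.column_provenance[c]
        receiver = prov[1] if len(prov) > 1 else ""
        sender = prov[2] if len(prov) > 2 else ""
        for j, g in enumerate(fit.gene_names):
            rows.append((receiver, sender, g, beta[i, j], se[i, j], tstat[i, j], p[i, j], q[i, j]))
    table = pd.DataFrame(
        rows, columns=["receiver", "sender", "gene", "beta", "se", "t", "p", "q"]
    )
    idx = [fit.design.column_provenance[c] for c in tested]
    fit.p_values = pd.DataFrame(p, index=pd.Index(idx), columns=fit.gene_names)
    fit.q_values = pd.DataFrame(q, index=pd.Index(idx), columns=fit.gene_names)
    return table


def gaussian_ll(y: np.ndarray, y_hat: np.ndarray, sigma: np.ndarray) -> float:
    """Mean Gaussian log-likelihood over cells and genes.

    ll = 1/(N J) sum_ij [ -log(sqrt(2 pi) sigma_j) - 0.5 (y_ij - yhat_ij)^2 / sigma_j^2 ].
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    term = -np.log(np.sqrt(2 * np.pi) * sigma) - 0.5 * (y - y_hat) ** 2 / sigma**2
    return float(term.mean())


def r_squared(
    y_test: np.ndarray,
    y_hat_test: np.ndarray,
    gene_means_train: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Coefficient of determination against training gene means.

    Per cell: R2_i = 1 - sum_j (y_ij - yhat_ij)^2 / sum_j (y_ij - ybar_j)^2
    with ybar_j the training-set gene means; cells with a zero denominator
    are returned as NaN.  Also returns the pooled R2 over all test entries.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_hat_test = np.asarray(y_hat_test, dtype=float)
    mu = np.asarray(gene_means_train, dtype=float)
    res = ((y_test - y_hat_test) ** 2).sum(axis=1)
    tot = ((y_test - mu) ** 2).sum(axis=1)
    per_cell = np.where(tot > 0, 1.0 - res / np.where(tot > 0, tot, 1.0), np.nan)
    pooled_tot = tot.sum()
    pooled = 1.0 - res.sum() / pooled_tot if pooled_tot > 0 else np.nan
    return per_cell, float(pooled)


def _fit_and_score(dataset, design, split):
    """OLS on train rows, pooled R2 on test rows against train gene means."""
    tr, te = split.train, split.test
    sub = DesignMatrix(
        values=design.values[tr],
        column_provenance=design.column_provenance,
        model_variant=design.model_variant,
        type_levels=design.type_levels,
        domain_levels=design.domain_levels,
    )
    fit = fit_ols(sub, dataset.expression[tr], gene_names=dataset.gene_names)
    y_hat = design.values[te] @ fit.coefficients
    mu = dataset.expression[tr].mean(axis=0)
    _, pooled = r_squared(dataset.expression[te], y_hat, mu)
    return pooled


def resolution_screen(
    dataset: SpatialDataset,
    resolutions,
    variant: str = "interaction",
    seeds=(0, 1, 2),
) -> pd.DataFrame:
    """Held-out R2 of the NCEM and the nonspatial baseline per radius.

    For each resolution and cross-validation seed the NCEM (``variant``) and
    the baseline are fitted on the same train split and scored on the same
    test cells; the baseline ignores the graph, so its score is constant in
    the resolution.  The returned frame carries per-(resolution, seed) test
    R2 values, delta_r2 = ncem - baseline, and the two-sided paired t-test
    p-value comparing the best resolution's NCEM against the baseline across
    seeds (column ``paired_t_p``, identical in every row).
    """
    resolutions = np.asarray(list(resolutions), dtype=float)
    seeds = list(seeds)
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions")
    if len(seeds) < 2:
        raise ValueError("need at least 2 cross-validation seeds for the paired test")
    splits = {s: split_nodes(dataset, s) for s in seeds}
    base_design = build_design(dataset, None, "baseline")
    base_r2 = {s: _fit_and_score(dataset, base_design, splits[s]) for s in seeds}
    rows = []
    for r in resolutions:
        graph = build_graph(dataset, r)
        design = build_design(dataset, graph, variant)
        for s in seeds:
            ncem_r2 = _fit_and_score(dataset, design, splits[s])
            rows.append(
                {
                    "resolution": r,
                    "seed": s,
                    "ncem_r2": ncem_r2,
                    "baseline_r2": base_r2[s],
                    "delta_r2": ncem_r2 - base_r2[s],
                }
            )
    out = pd.DataFrame(rows)
    mean_by_res = out.groupby("resolution")["ncem_r2"].mean()
    best = mean_by_res.idxmax()
    a = out.loc[out["resolution"] == best].set_index("seed")["ncem_r2"]
    b = pd.Series(base_r2)
    t_p = stats.ttest_rel(a.loc[b.index], b).pvalue
    out["best_resolution"] = best
    out["paired_t_p"] = t_p
    return out
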