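"""Standard synthetic validation benchmarks.

Each function regenerates its inputs from a seed, runs one part of the
package end to end and returns summary metrics.  The problem sizes are the
package's standard desk-scale validation conditions: tissues of a few
hundred to a few thousand cells with the default generator settings (gene
means U(0, 10), niche effects U(4, 6) on half the genes, unit noise).
"""

from __future__ import annotations

import numpy as np

from .core import build_graph, split_nodes, variance_decomposition
from .cvae import CvaeConfig, fit_cvae
from .interpret import type_coupling
from .linear import (
    DesignMatrix,
    build_design,
    fit_ols,
    r_squared,
    resolution_screen,
    wald_test,
)
from .lr import (
    LigandReceptorMap,
    differential_receptor_activity,
    lr_kernel,
    sender_presence_groups,
)
from .neural import NicheEncoderConfig, TrainingConfig, fit_nl_ncem
from .simulate import (
    SimulationConfig,
    simulate_dependency,
    simulate_lr_dependency,
    simulate_null,
    simulate_segmentation_error,
    simulate_spots,
)

__all__ = [
    "ols_oracle_error",
    "variance_conservation_error",
    "type_i_error",
    "power_and_recovery",
    "resolution_recovery",
    "linear_subsumption_gap",
    "segmentation_conservation",
    "lr_kernel_exactness",
    "lr_ranking_rate",
    "coupling_directionality",
    "spot_gain",
    "cvae_dominance",
]


def _interaction_design(rng, n, l, c):
    """Random dense design shaped like (X_l | X_TS | X_c)."""
    p = l + l * l + c
    x = rng.normal(size=(n, p))
    prov = (
        [("receiver_type", f"t{k}") for k in range(l)]
        + [("interaction", f"t{r}", f"t{s}") for r in range(l) for s in range(l)]
        + [("domain", f"d{k}") for k in range(c)]
    )
    return DesignMatrix(x, prov, "interaction",
                        np.array([f"t{k}" for k in range(l)]),
                        np.array([f"d{k}" for k in range(c)]))


def ols_oracle_error(seed: int = 0, n: int = 200, l: int = 3, c: int = 2) -> dict:
    """Worst relative error of OLS coefficients/SEs vs a direct normal-equations solve."""
    rng = np.random.default_rng(seed)
    worst_beta, worst_se = 0.0, 0.0
    for _ in range(5):
        d = _interaction_design(rng, n, l, c)
        p = d.n_columns
        y = d.values @ rng.normal(size=(p, 6)) + rng.normal(size=(n, 6))
        fit = fit_ols(d, y)
        x = d.values
        beta_ref = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta_ref
        sigma2 = (resid**2).sum(axis=0) / (n - p)
        se_ref = np.sqrt(np.outer(np.diag(np.linalg.inv(x.T @ x)), sigma2))
        worst_beta = max(worst_beta, float(np.max(
            np.abs(fit.coefficients - beta_ref) / np.maximum(np.abs(beta_ref), 1e-12))))
        worst_se = max(worst_se, float(np.max(np.abs(fit.standard_errors - se_ref) / se_ref)))
    return {"max_rel_error_beta": worst_beta, "max_rel_error_se": worst_se, "n": n}


def variance_conservation_error(seed: int = 0, n_datasets: int = 100) -> dict:
    """Worst relative gap between summed variance components and the total SS."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(5, 60))
        j = int(rng.integers(1, 10))
        l = int(rng.integers(1, 5))
        from .core import SpatialDataset

        ds = SpatialDataset(
            expression=rng.uniform(0, 10, size=(n, j)),
            coords=rng.uniform(0, 100, size=(n, 2)),
            cell_type=np.array([f"t{k}" for k in rng.integers(0, l, size=n)]),
            domain=np.array(["i"] * n),
            gene_names=np.array([f"g{k}" for k in range(j)]),
        )
        vd = variance_decomposition(ds)
        gap = abs(vd.intra_type_ss + vd.inter_type_ss + vd.gene_ss - vd.total_ss)
        worst = max(worst, gap / max(vd.total_ss, 1e-12))
    return {"max_rel_gap": worst, "n": n_datasets}


def type_i_error(seed: int = 0, n_cells: int = 2000, n_genes: int = 500) -> dict:
    """False-discovery rate of the interaction Wald tests on null tissue."""
    cfg = SimulationConfig(n_cells=n_cells, n_genes=n_genes, n_types=1,
                           n_domains=2, seed=seed)
    ds, _ = simulate_null(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    fit = fit_ols(build_design(ds, graph, "interaction"), ds.expression,
                  gene_names=ds.gene_names)
    table = wald_test(fit)
    m = len(table)
    frac = float((table["q"] < 0.05).mean())
    return {
        "fraction_q_lt_05": frac,
        "bound": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / m)),
        "n": m,
    }


def power_and_recovery(seed: int = 0, n_cells: int = 2000, n_genes: int = 500) -> dict:
    """Detection power and coefficient accuracy on planted niche effects."""
    cfg = SimulationConfig(n_cells=n_cells, n_genes=n_genes, seed=seed)
    ds, truth = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    fit = fit_ols(build_design(ds, graph, "interaction"), ds.expression,
                  gene_names=ds.gene_names)
    wald_test(fit)
    eff = truth["effects"]
    detected, z_scores = [], []
    for row in eff.itertuples():
        key = ("interaction", row.receiver, row.sender)
        q = fit.q_values.loc[[key], row.gene].iloc[0]
        i = fit.design.column_provenance.index(key)
        j = int(np.flatnonzero(fit.gene_names == row.gene)[0])
        detected.append(q < 0.05)
        z_scores.append(
            (fit.coefficients[i, j] - row.effect) / fit.standard_errors[i, j]
        )
    z = np.abs(np.array(z_scores))
    return {
        "power_q_lt_05": float(np.mean(detected)),
        "fraction_within_3se": float((z <= 3).mean()),
        "mean_abs_z": float(z.mean()),
        "n": len(eff),
    }


def resolution_recovery(
    seed: int = 0,
    true_radius: float = 50.0,
    grid=(15.0, 30.0, 50.0, 80.0, 130.0),
    n_replicates: int = 3,
) -> dict:
    """How often the screen's argmax lands within one grid step of the
    generating radius."""
    grid = list(grid)
    target = grid.index(true_radius)
    hits = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_cells=800, n_genes=40, interaction_radius=true_radius,
                               seed=seed * 100 + rep)
        ds, _ = simulate_dependency(cfg)
        table = resolution_screen(ds, grid, seeds=(seed, seed + 1))
        best = table["best_resolution"].iloc[0]
        hits += abs(grid.index(best) - target) <= 1
    return {"hits": hits, "n": n_replicates}


def linear_subsumption_gap(seed: int = 0) -> dict:
    """Test-R2 gap between the zero-depth indicator network and OLS."""
    cfg = SimulationConfig(n_cells=400, n_genes=30, seed=seed)
    ds, _ = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    splits = split_nodes(ds, seed)
    tc = TrainingConfig(max_epochs=4000, learning_rate=0.05, nodes_per_image=500)
    _, _, summary = fit_nl_ncem(ds, graph, NicheEncoderConfig(depth=0), tc,
                                splits=splits, seed=seed)
    d = build_design(ds, graph, "interaction")
    tr, te = splits.train, splits.test
    sub = DesignMatrix(d.values[tr], d.column_provenance, d.model_variant,
                       d.type_levels, d.domain_levels)
    fit = fit_ols(sub, ds.expression[tr])
    mu = ds.expression[tr].mean(axis=0)
    _, ols_r2 = r_squared(ds.expression[te], d.values[te] @ fit.coefficients, mu)
    return {"gap": abs(summary["test_r2"] - ols_r2), "ols_r2": ols_r2,
            "network_r2": summary["test_r2"], "n": cfg.n_cells}


def segmentation_conservation(seed: int = 0) -> dict:
    """Per-image total-count drift after simulated segmentation errors."""
    cfg = SimulationConfig(n_cells=1000, n_genes=30, n_domains=2, seed=seed)
    ds, _ = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    worst = 0.0
    for frac in (0.1, 0.5):
        out = simulate_segmentation_error(ds, frac, 0.5, seed=seed, graph=graph)
        for dom in ds.domain_levels:
            m = ds.domain == dom
            before, after = ds.expression[m].sum(), out.expression[m].sum()
            worst = max(worst, abs(after - before) / before)
    return {"max_rel_drift": worst, "n": cfg.n_cells}


def lr_kernel_exactness() -> dict:
    """Exact agreement of the kernel with hand-enumerated toy graphs."""
    from scipy.sparse import csr_matrix
    from .core import CellGraph

    checks = []
    # path graph 0-1-2, receptor gene 0, ligand gene 1
    y = np.array([[2.0, 1.0], [1.0, 3.0], [4.0, 5.0]])
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    g = CellGraph(adjacency=csr_matrix(a), resolution=1.0)
    m = LigandReceptorMap(np.array([0]), np.array([1]), [("g0", "g1")])
    z = lr_kernel(y, g, m).z
    checks.append(np.allclose(z[:, 0], [2 * 3, 1 * (1 + 5), 4 * 3]))
    # 5-node star: hub 0 with leaves 1..4
    y = np.vstack([[1.0, 0.0]] + [[0.0, float(k)] for k in range(1, 5)])
    a = np.zeros((5, 5))
    a[0, 1:] = a[1:, 0] = 1.0
    g = CellGraph(adjacency=csr_matrix(a), resolution=1.0)
    z = lr_kernel(y, g, m).z
    checks.append(np.allclose(z[0, 0], 1 + 2 + 3 + 4) and np.allclose(z[1:, 0], 0.0))
    return {"all_exact": float(all(checks)), "n": len(checks)}


def lr_ranking_rate(seed: int = 0, n_replicates: int = 20) -> dict:
    """Fraction of replicates in which the planted pair tops the ranking."""
    firsts = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_cells=400, n_genes=40, seed=seed * 1000 + rep)
        ds, truth = simulate_lr_dependency(cfg)
        graph = build_graph(ds, cfg.interaction_radius)
        lr_map = LigandReceptorMap.from_names(truth["pairs"], ds.gene_names)
        act = lr_kernel(ds.expression, graph, lr_map)
        ga, gb = sender_presence_groups(ds, graph, "type_0", "type_1")
        tab = differential_receptor_activity(act, ga, gb)
        firsts += (tab.loc[0, "receptor"], tab.loc[0, "ligand"]) == ("gene_0", "gene_1")
    return {"rank_first_rate": firsts / n_replicates, "n": n_replicates}


def coupling_directionality(seed: int = 0) -> dict:
    """L1-coupling ratio for a purely directed planted effect (A -> B)."""
    cfg = SimulationConfig(n_cells=1500, n_genes=60, asymmetric=True, seed=seed)
    ds, _ = simulate_dependency(cfg)
    graph = build_graph(ds, cfg.interaction_radius)
    fit = fit_ols(build_design(ds, graph, "interaction"), ds.expression,
                  gene_names=ds.gene_names)
    wald_test(fit)
    table = type_coupling(fit, min_genes=0).set_index(["sender", "receiver"])
    forward = table.loc[("type_0", "type_1"), "l1_norm"]
    reverse = table.loc[("type_1", "type_0"), "l1_norm"]
    return {"ratio": float(forward / max(reverse, 1e-9)), "forward_l1": float(forward),
            "reverse_l1": float(reverse), "n": cfg.n_cells}


def spot_gain(seed: int = 0) -> dict:
    """Held-out R2 advantage of spot NCEM over the composition-blind baseline."""
    from .spots import fit_spot_ncem

    cfg = SimulationConfig(n_cells=1500, n_genes=40, interaction_radius=40.0, seed=seed)
    spots, _, _ = simulate_spots(cfg)
    _, summary = fit_spot_ncem(spots, seeds=(seed, seed + 1, seed + 2))
    pooled = summary[summary["cell_type"] == "all"]
    return {
        "wins": int((pooled["delta_r2"] > 0).sum()),
        "mean_delta_r2": float(pooled["delta_r2"].mean()),
        "n": len(pooled),
    }


def cvae_dominance(seed: int = 0, n_replicates: int = 3) -> dict:
    """Reconstruction-R2 margin of the CVAE over the deterministic network."""
    margins = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_cells=400, n_genes=30, seed=seed * 100 + rep)
        ds, _ = simulate_dependency(cfg)
        graph = build_graph(ds, cfg.interaction_radius)
        splits = split_nodes(ds, seed + rep)
        tc = TrainingConfig(max_epochs=800, nodes_per_image=500)
        _, _, nl = fit_nl_ncem(
            ds, graph, NicheEncoderConfig(depth=1, hidden_width=16, latent_dim=8),
            tc, lr_grid=(0.05, 0.005), splits=splits, seed=seed + rep,
        )
        # beta < 1 keeps the reconstruction channel open; at beta = 1 the
        # posterior collapses on tissues of this size and reconstruction
        # degenerates to conditional prediction
        tc_cvae = TrainingConfig(max_epochs=3000, nodes_per_image=500)
        _, _, cv = fit_cvae(
            ds, graph, CvaeConfig(latent_dim=32, hidden_width=96, kl_weight=0.1),
            tc_cvae, splits=splits, seed=seed + rep, lr_grid=(0.005, 0.002),
        )
        margins.append(cv["reconstruction_r2"] - nl["test_r2"])
    return {
        "min_margin": float(min(margins)),
        "mean_margin": float(np.mean(margins)),
        "n": n_replicates,
    }
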