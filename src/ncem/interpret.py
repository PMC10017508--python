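"""Biological summaries of fitted linear NCEMs.

Turns the interaction coefficients and their Wald q-values into cell-type
couplings (number of significant genes and L1 norm of their coefficients per
ordered sender-receiver pair), sender/receiver effect matrices, sender
similarity clustering, and Fisher-exact niche-cluster enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .linear import LinearFit, wald_test

__all__ = [
    "type_coupling",
    "sender_effect",
    "receiver_effect",
    "sender_similarity",
    "cluster_enrichment",
]


def _interaction_table(fit: LinearFit) -> pd.DataFrame:
    if fit.design.model_variant != "interaction":
        raise ValueError("type-level summaries need an interaction-variant fit")
    if fit.q_values is None:
        return wald_test(fit)
    cols = fit.design.interaction_columns()
    tested = cols[fit.testable[cols]]
    rows = []
    for c in tested:
        _, r, s = fit.design.column_provenance[c]
        for j, g in enumerate(fit.gene_names):
            rows.append(
                (r, s, g, fit.coefficients[c, j], fit.standard_errors[c, j],
                 fit.p_values.loc[[("interaction", r, s)], g].iloc[0],
                 fit.q_values.loc[[("interaction", r, s)], g].iloc[0])
            )
    return pd.DataFrame(rows, columns=["receiver", "sender", "gene", "beta", "se", "p", "q"])


def type_coupling(
    fit: LinearFit,
    alpha: float = 0.05,
    min_genes: int = 200,
) -> pd.DataFrame:
    """Coupling strength per ordered (sender, receiver) type pair.

    For each pair: the number of genes significant at BH q < ``alpha`` and the
    L1 norm of those significant coefficients.  Pairs with fewer than
    ``min_genes`` significant genes are flagged ``hidden_for_plot`` (they stay
    in the table); sender-receiver combinations never observed in the data
    appear with ``unobservable = True`` and no statistics.
    """
    table = _interaction_table(fit)
    rows = []
    for (r, s), grp in table.groupby(["receiver", "sender"], sort=True):
        sig = grp[grp["q"] < alpha]
        rows.append(
            {
                "sender": s,
                "receiver": r,
                "n_significant_genes": len(sig),
                "l1_norm": float(np.abs(sig["beta"]).sum()),
                "hidden_for_plot": len(sig) < min_genes,
                "unobservable": False,
            }
        )
    observed = {(row["sender"], row["receiver"]) for row in rows}
    for c in fit.design.interaction_columns():
        if not fit.testable[c]:
            _, r, s = fit.design.column_provenance[c]
            if (s, r) not in observed:
                rows.append(
                    {"sender": s, "receiver": r, "n_significant_genes": 0,
                     "l1_norm": np.nan, "hidden_for_plot": True, "unobservable": True}
                )
    return pd.DataFrame(rows).sort_values(["sender", "receiver"]).reset_index(drop=True)


def _effect_slice(fit: LinearFit, fixed: str, value) -> pd.DataFrame:
    table = _interaction_table(fit)
    other = "receiver" if fixed == "sender" else "sender"
    sub = table[table[fixed] == value]
    if sub.empty:
        raise ValueError(f"unknown or unobservable {fixed} type {value!r}")
    beta = sub.pivot(index="gene", columns=other, values="beta")
    q = sub.pivot(index="gene", columns=other, values="q")
    out = pd.concat({"beta": beta, "q": q}, axis=1)
    return out


def sender_effect(fit: LinearFit, sender) -> pd.DataFrame:
    """Genes x receivers effect matrix for one sender type (beta and q)."""
    return _effect_slice(fit, "sender", sender)


def receiver_effect(fit: LinearFit, receiver) -> pd.DataFrame:
    """Genes x senders effect matrix for one receiver type (beta and q)."""
    return _effect_slice(fit, "receiver", receiver)


def top_genes(effect: pd.DataFrame, column, k: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Top-k genes by |coefficient| among significant entries of one column."""
    sub = pd.DataFrame(
        {"beta": effect["beta"][column], "q": effect["q"][column]}
    ).dropna()
    sig = sub[sub["q"] < alpha]
    return sig.reindex(sig["beta"].abs().sort_values(ascending=False).index).head(k)


def _linkage_newick(link: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(link):
        nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{dist:.6g}"
    return nodes[n + len(link) - 1] + ";"


def sender_similarity(fit: LinearFit, receiver) -> tuple[pd.DataFrame, list, str]:
    """Pearson correlation of sender coefficient vectors for one receiver.

    Correlations are over genes; average-linkage hierarchical clustering on
    1 - correlation gives the leaf order and a newick string of the
    dendrogram.  Senders with a constant coefficient vector have undefined
    correlations and are masked (NaN) and excluded from clustering.
    """
    eff = receiver_effect(fit, receiver)["beta"]
    senders = list(eff.columns)
    if len(senders) < 2:
        raise ValueError("need at least 2 observable senders")
    corr = eff.corr(method="pearson")
    valid = [s for s in senders if eff[s].std() > 0]
    if len(valid) < 2:
        return corr, senders, ";"
    dist = 1.0 - corr.loc[valid, valid].to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    order = [valid[i] for i in leaves_list(link)]
    newick = _linkage_newick(link, valid)
    return corr, order, newick


def cluster_enrichment(
    cluster_masks: np.ndarray | dict,
    presence_columns: np.ndarray | dict,
) -> pd.DataFrame:
    """Fisher-exact enrichment of niche composition within expression clusters.

    Each (cluster, sender) combination forms a 2x2 contingency table of
    cluster membership against presence of the sender type in the niche;
    two-sided Fisher exact p-values are BH-corrected jointly.  Degenerate
    tables (an empty margin) get p = 1 and ``degenerate = True``.
    """
    if isinstance(cluster_masks, np.ndarray) and cluster_masks.ndim == 1:
        cluster_masks = {"cluster": cluster_masks}
    if isinstance(presence_columns, np.ndarray) and presence_columns.ndim == 1:
        presence_columns = {"sender": presence_columns}
    rows = []
    for cname, cmask in dict(cluster_masks).items():
        cmask = np.asarray(cmask, dtype=bool)
        for sname, smask in dict(presence_columns).items():
            smask = np.asarray(smask, dtype=bool)
            if len(smask) != len(cmask):
                raise ValueError("masks must have equal length")
            table = np.array(
                [
                    [np.sum(cmask & smask), np.sum(cmask & ~smask)],
                    [np.sum(~cmask & smask), np.sum(~cmask & ~smask)],
                ]
            )
            degenerate = bool((table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any())
            if degenerate:
                odds, p = np.nan, 1.0
            else:
                odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {"cluster": cname, "sender": sname, "odds_ratio": odds,
                 "p": p, "degenerate": degenerate}
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
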