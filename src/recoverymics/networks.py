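"""Sample–sample Spearman correlation networks and centrality analysis.

Nodes are samples; an edge joins two samples whose OTU abundance profiles
are rank-correlated with |rho| above a threshold and a BH-adjusted p below
the FDR level.  Shortest-path computations are purely topological
(unweighted), matching the path-counting definition of betweenness;
eigenvector centrality is computed on the largest connected component by
power iteration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountTable
from .community_tests import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "spearman_matrix",
    "build_network",
    "betweenness_centrality",
    "eigenvector_centrality",
    "centrality_shift_summary",
]


def spearman_matrix(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tie-corrected Spearman rho and t-approximation p over sample pairs.

    Samples whose abundance vector is constant have undefined rank
    correlation; their pairs are NaN (flagged, excluded downstream).
    """
    if table.n_otus < 3:
        raise ValueError("need at least 3 OTUs for rank correlation")
    X = table.counts.astype(float)
    rho, p = stats.spearmanr(X.T)
    if table.n_samples == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    else:
        rho = np.asarray(rho, dtype=float)
        p = np.asarray(p, dtype=float)
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
        p[constant, :] = np.nan
        p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = table.sample_ids
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.5,
    fdr_alpha: float = 0.05,
    node_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Filter edges by |rho| >= rho_min AND BH-adjusted p <= fdr_alpha.

    BH runs over all defined pairs before thresholding.  Every sample is a
    node even if isolated; ``node_attrs`` (indexed by sample id, e.g.
    richness / treatment / habitat / timepoint) are attached when given.
    Edges carry ``rho``, ``p``, ``p_adj`` and ``sign``.
    """
    if not (0.0 <= rho_min <= 1.0):
        raise ValueError("rho_min must be in [0, 1]")
    ids = list(rho.index)
    pairs = [
        (a, b)
        for a, b in itertools.combinations(ids, 2)
        if np.isfinite(rho.loc[a, b]) and np.isfinite(p.loc[a, b])
    ]
    undefined = [
        (a, b)
        for a, b in itertools.combinations(ids, 2)
        if not (np.isfinite(rho.loc[a, b]) and np.isfinite(p.loc[a, b]))
    ]
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.graph["undefined_pairs"] = undefined
    if pairs:
        raw_p = np.array([p.loc[a, b] for a, b in pairs])
        adj = bh_adjust(raw_p)
        for (a, b), pr, pa in zip(pairs, raw_p, adj):
            r = float(rho.loc[a, b])
            if abs(r) >= rho_min and pa <= fdr_alpha:
                g.add_edge(a, b, rho=r, p=float(pr), p_adj=float(pa), sign=int(np.sign(r)))
    if node_attrs is not None:
        for node in g.nodes:
            if node in node_attrs.index:
                for col in node_attrs.columns:
                    g.nodes[node][col] = node_attrs.loc[node, col]
    return g


def _topology(net: nx.Graph, positive_only: bool) -> nx.Graph:
    if not positive_only:
        return net
    keep = [(a, b) for a, b, s in net.edges(data="sign", default=1) if s >= 0]
    sub = nx.Graph()
    sub.add_nodes_from(net.nodes)
    sub.add_edges_from(keep)
    return sub


def betweenness_centrality(net: nx.Graph, positive_only: bool = False) -> pd.Series:
    """Unnormalized pair-counting betweenness (fractional credit on tied
    shortest paths); paths are unweighted; isolated nodes score 0."""
    g = _topology(net, positive_only)
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return pd.Series(bc, name="betweenness").astype(float)


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 1000, positive_only: bool = False
) -> pd.Series:
    """Power-iteration eigenvector centrality on the largest connected
    component, L2-normalized; nodes outside that component are NaN
    (flagged).  The iteration matrix is A + I, which damps bipartite
    oscillation."""
    g = _topology(net, positive_only)
    scores = pd.Series(np.nan, index=list(g.nodes), name="eigenvector", dtype=float)
    if g.number_of_edges() == 0:
        return scores
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    lcc = g.subgraph(components[0])
    try:
        ec = nx.eigenvector_centrality(lcc, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as err:
        raise RuntimeError(f"eigenvector centrality did not converge: {err}") from err
    vec = pd.Series(ec, dtype=float)
    vec /= np.linalg.norm(vec.to_numpy())
    scores.loc[vec.index] = vec
    return scores


def centrality_shift_summary(
    nets: dict[tuple[str, str], nx.Graph], control: str = "Ctrl"
) -> pd.DataFrame:
    """Median/mean centralities per (treatment, timepoint) network plus a
    rank-sum p for each control-vs-treatment contrast at the same time.

    Empty network cells yield flagged rows (NaNs), never dropped.
    """
    per_cell: dict[tuple[str, str], tuple[pd.Series, pd.Series]] = {}
    rows = []
    for (trt, tp), g in sorted(nets.items()):
        if g.number_of_nodes() == 0:
            rows.append(
                {
                    "treatment": trt, "timepoint": tp, "n_nodes": 0, "n_edges": 0,
                    "median_betweenness": np.nan, "mean_betweenness": np.nan,
                    "median_eigenvector": np.nan, "mean_eigenvector": np.nan,
                    "p_vs_control": np.nan, "ok": False,
                }
            )
            continue
        bc = betweenness_centrality(g)
        ec = eigenvector_centrality(g) if g.number_of_edges() else pd.Series(
            np.nan, index=list(g.nodes), dtype=float
        )
        per_cell[(trt, tp)] = (bc, ec)
        rows.append(
            {
                "treatment": trt, "timepoint": tp,
                "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
                "median_betweenness": float(bc.median()),
                "mean_betweenness": float(bc.mean()),
                "median_eigenvector": float(ec.median(skipna=True)),
                "mean_eigenvector": float(ec.mean(skipna=True)),
                "p_vs_control": np.nan, "ok": True,
            }
        )
    out = pd.DataFrame(rows)
    for i, row in out.iterrows():
        trt, tp = row["treatment"], row["timepoint"]
        if trt == control or not row["ok"] or (control, tp) not in per_cell:
            continue
        bc_t = per_cell[(trt, tp)][0].to_numpy()
        bc_c = per_cell[(control, tp)][0].to_numpy()
        if np.unique(np.concatenate([bc_t, bc_c])).size == 1:
            out.loc[i, "p_vs_control"] = 1.0
        else:
            _, p = wilcoxon_rank_sum(bc_c, bc_t)
            out.loc[i, "p_vs_control"] = p
    return out
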