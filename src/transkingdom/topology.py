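"""Edge prioritization and network topology.

Retained OTU-phenotype edges are ranked by S = max_g(a_g) * |median_g(r_g)|
where a_g is the per-group OTU relative abundance and r_g the per-group
Spearman correlation, each first reduced to its median across the two
experiments.  The score favours abundant microbes whose correlation with a
phenotype is strong across treatment groups.  Topology (degree, betweenness
centrality normalized within each connected component) contextualizes the
ranked edges.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["rank_edges", "degree", "betweenness_centrality", "topology_report", "figure_graph"]


def rank_edges(
    edges: pd.DataFrame,
    abundance: dict[str, pd.Series],
    correlation: dict[tuple[str, str], pd.Series],
) -> pd.DataFrame:
    """Score and rank retained OTU-phenotype edges.

    ``edges`` has columns ``otu`` and ``phenotype``; ``abundance`` maps
    OTU -> per-group abundance a_g (already the median across experiments);
    ``correlation`` maps (otu, phenotype) -> per-group rho r_g (median
    across experiments, NaN where undefined — such groups are skipped in
    the median).  Output is sorted by descending S with a dense rank (ties
    share a rank, equal-S edges keep input order); edges whose r_g is
    undefined in every group are unrankable and placed last.
    """
    rows = []
    for _, e in edges.iterrows():
        otu, phen = str(e["otu"]), str(e["phenotype"])
        a = abundance.get(otu)
        r = correlation.get((otu, phen))
        if a is None or r is None:
            raise KeyError(f"missing abundance or correlation trace for ({otu}, {phen})")
        r_valid = r.dropna()
        if len(r_valid) == 0:
            score, med_r = np.nan, np.nan
        else:
            med_r = float(r_valid.median())
            score = float(a.max()) * abs(med_r)
        rows.append(
            {"otu": otu, "phenotype": phen, "max_abundance": float(a.max()),
             "median_correlation": med_r, "score": score}
        )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["rank"] = pd.Series(dtype=int)
        return out
    out = out.sort_values("score", ascending=False, kind="stable", na_position="last")
    ranked = out["score"].rank(method="dense", ascending=False, na_option="bottom")
    out["rank"] = ranked.astype(int)
    return out.reset_index(drop=True)


def figure_graph(graph: nx.Graph) -> nx.Graph:
    """The mixed display network: OTU-phenotype edges plus the phenotype
    edges flagged for visualization."""
    keep = [
        (u, v)
        for u, v, d in graph.edges(data=True)
        if d.get("edge_class") == "otu-phenotype" or d.get("visualization_only")
    ]
    sub = nx.Graph()
    sub.add_nodes_from(graph.nodes(data=True))
    for u, v in keep:
        sub.add_edge(u, v, **graph.edges[u, v])
    return sub


def degree(graph: nx.Graph) -> pd.Series:
    """Undirected incident-edge count per node."""
    return pd.Series(dict(graph.degree()), dtype=int).sort_index()


def betweenness_centrality(graph: nx.Graph) -> pd.Series:
    """Betweenness centrality normalized within each connected component.

    For a node v in a component of n nodes, BC(v) is the sum over ordered
    pairs s != v != t in that component of the fraction of shortest s-t
    paths through v, divided by (n-1)(n-2)/2.  Components with fewer than
    three nodes have BC 0.  Matches the convention of desktop network
    analyzers that treat each component separately, so BC is always in
    [0, 1].
    """
    out: dict = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) < 3:
            out.update({n: 0.0 for n in comp})
        else:
            out.update(nx.betweenness_centrality(sub, normalized=True))
    return pd.Series(out, dtype=float).sort_index()


def topology_report(graph: nx.Graph, mode: str = "figure") -> pd.DataFrame:
    """Per-node degree and betweenness centrality.

    ``mode='figure'`` (default) evaluates the mixed display network —
    OTU-phenotype edges plus visualization-flagged phenotype edges — which
    is the graph whose topology the study reports; ``mode='analysis'``
    uses every retained edge.
    """
    if mode == "figure":
        g = figure_graph(graph)
    elif mode == "analysis":
        g = graph
    else:
        raise ValueError(f"unknown topology mode {mode!r}")
    deg = degree(g)
    bc = betweenness_centrality(g)
    kinds = pd.Series({n: g.nodes[n].get("kind", "") for n in g.nodes})
    return pd.DataFrame({"kind": kinds, "degree": deg, "betweenness": bc}).sort_index()
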