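"""Graph-theoretic characterization of inferred functional networks.

Degrees (binary, in/out on the pair-level directed graph and total on the
undirected projection), Watts-Strogatz clustering and its geometric-mean
weighted variant (edge weights normalized by the graph maximum), betweenness
and closeness centralities, per-node local efficiency, characteristic path
length over connected pairs, density, degree assortativity, and the
reciprocal-connection fraction with its physical-distance distribution.
Connection probability and mean weight as a function of electrode distance
are binned at half the electrode pitch by default.
"""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .functional_connectivity import FunctionalGraph

__all__ = ["node_metrics", "graph_metrics", "distance_profiles"]


def _local_efficiency(g: nx.Graph, node) -> float:
    nbrs = list(g.neighbors(node))
    if len(nbrs) < 2:
        return 0.0
    sub = g.subgraph(nbrs)
    return nx.global_efficiency(sub)


def node_metrics(graph: FunctionalGraph | nx.Graph) -> pd.DataFrame:
    """Per-node metric table on the binary pair-level graphs."""
    if isinstance(graph, FunctionalGraph):
        und = graph.undirected
        dirg = graph.pair_directed
    else:
        und = graph
        dirg = None
    if und.number_of_nodes() == 0:
        raise ValueError("empty graph")
    clustering = nx.clustering(und)
    wclust = nx.clustering(und, weight="weight") if und.number_of_edges() else {
        n: 0.0 for n in und}
    btw = nx.betweenness_centrality(und)
    cls = nx.closeness_centrality(und)
    rows = []
    for node in und.nodes:
        rows.append({
            "unit": node,
            "degree": und.degree(node),
            "in_degree": dirg.in_degree(node) if dirg is not None else np.nan,
            "out_degree": dirg.out_degree(node) if dirg is not None else np.nan,
            "clustering": clustering[node],
            "weighted_clustering": wclust[node],
            "betweenness": btw[node],
            "closeness": cls[node],
            "local_efficiency": _local_efficiency(und, node),
        })
    return pd.DataFrame(rows)


def graph_metrics(graph: FunctionalGraph | nx.Graph) -> dict:
    """Whole-graph metrics on the undirected projection (plus reciprocity on
    the directed pair-level graph when available).

    The characteristic path length L averages shortest-path lengths over
    reachable node pairs only; the fraction of unreachable pairs is reported
    alongside.
    """
    if isinstance(graph, FunctionalGraph):
        und = graph.undirected
        dirg = graph.pair_directed
    else:
        und, dirg = graph, None
    n = und.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")

    lengths = []
    reachable = 0
    total_pairs = n * (n - 1) // 2
    for src, dist in nx.all_pairs_shortest_path_length(und):
        for dst, d in dist.items():
            if dst != src:
                lengths.append(d)
    reachable = len(lengths) // 2
    L = float(np.mean(lengths)) if lengths else float("nan")

    degs = [d for _, d in und.degree()]
    if und.number_of_edges() >= 1 and len(set(degs)) > 1:
        try:
            assort = float(nx.degree_assortativity_coefficient(und))
        except Exception:
            assort = float("nan")
    else:
        assort = float("nan")

    out = {
        "n_nodes": n,
        "n_edges_undirected": und.number_of_edges(),
        "density": nx.density(und),
        "path_length": L,
        "unreachable_pair_fraction":
            1.0 - reachable / total_pairs if total_pairs else float("nan"),
        "assortativity": assort,
        "mean_degree": float(np.mean(degs)) if degs else 0.0,
        "degree_distribution": dict(
            pd.Series(degs).value_counts().sort_index().astype(int)),
    }
    if dirg is not None:
        ordered = dirg.number_of_edges()
        recip = sum(1 for u, v in dirg.edges if dirg.has_edge(v, u))
        out["reciprocal_fraction"] = recip / ordered if ordered else float("nan")
        rd = [dirg[u][v].get("distance_um", np.nan)
              for u, v in dirg.edges if dirg.has_edge(v, u)]
        out["reciprocal_mean_distance_um"] = float(np.mean(rd)) if rd else float("nan")
    return out


def distance_profiles(graph: FunctionalGraph | nx.Graph, layout,
                      bin_um: float = 250.0) -> pd.DataFrame:
    """Connection probability and mean edge weight versus electrode distance.

    Every unordered unit pair on distinct electrodes is a candidate; per
    distance bin the table reports the fraction of candidates carrying an
    undirected functional link and the mean link weight (NaN when the bin has
    no links).
    """
    und = graph.undirected if isinstance(graph, FunctionalGraph) else graph
    nodes = list(und.nodes)
    if any("x" not in und.nodes[n] for n in nodes):
        raise ValueError("node positions required for distance profiles")
    rows = []
    for u, v in itertools.combinations(nodes, 2):
        dx = und.nodes[u]["x"] - und.nodes[v]["x"]
        dy = und.nodes[u]["y"] - und.nodes[v]["y"]
        d = float(np.hypot(dx, dy))
        if d <= 0:
            continue
        connected = und.has_edge(u, v)
        w = und[u][v]["weight"] if connected else np.nan
        rows.append((d, connected, w))
    df = pd.DataFrame(rows, columns=["distance_um", "connected", "weight"])
    if df.empty:
        return pd.DataFrame(columns=["bin_center_um", "n_pairs", "n_connected",
                                     "p_connect", "mean_weight"])
    df["bin"] = (df["distance_um"] // bin_um).astype(int)
    out = []
    for b, grp in df.groupby("bin"):
        conn = grp["connected"].sum()
        out.append({
            "bin_center_um": (b + 0.5) * bin_um,
            "n_pairs": len(grp),
            "n_connected": int(conn),
            "p_connect": conn / len(grp),
            "mean_weight": grp.loc[grp["connected"], "weight"].mean()
            if conn else np.nan,
        })
    prof = pd.DataFrame(out)
    prof.attrs["mean_connection_length_um"] = float(
        df.loc[df["connected"], "distance_um"].mean()) if df["connected"].any() \
        else float("nan")
    return prof
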