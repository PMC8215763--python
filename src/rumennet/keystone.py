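"""Keystone-taxon identification by node removal and Borda rank aggregation.

For every node, the five network measures are computed on the full graph and
again after removing that node (the cluster partition is held fixed — deltas
must isolate the removed node's structural contribution, so no re-clustering).
A node whose loss disrupts the community structure should *reduce*
transitivity and density while *increasing* modularity, average path length
and eigenvector centralization; nodes are ranked per measure in that
direction within their cluster (average ranks on ties), and the Borda score
is the plain sum of the five ranks — lowest sum is the strongest keystone
candidate.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import MEASURES, all_measures, partition_from_labels

#: rank direction per measure: -1 ranks the most negative delta first
#: (disruption reduces the measure), +1 the most positive first.
MEASURE_DIRECTIONS = {
    "transitivity": -1,
    "density": -1,
    "modularity": +1,
    "average_path_length": +1,
    "eigenvector_centralization": +1,
}

#: deltas are rounded to this many decimals before ranking so that ties
#: between structurally equivalent nodes are well-defined
DELTA_DECIMALS = 9


def removal_deltas(
    graph: nx.Graph,
    node: str,
    partition: list[set] | None = None,
    scope: str = "full",
) -> dict[str, float]:
    """Five-measure delta vector (removal graph minus full graph) for ``node``.

    ``scope="full"`` computes measures on the complete network; with
    ``scope="subgraph"`` they are computed on the node's cluster subgraph.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    if graph.number_of_nodes() == 1:
        raise ValueError("cannot remove the last node of the graph")
    if partition is None:
        partition = partition_from_labels(graph)
    if scope == "subgraph":
        cluster = next((c for c in partition if node in c), None)
        if cluster is None:
            raise ValueError(f"node {node!r} not covered by the partition")
        graph = graph.subgraph(cluster).copy()
        partition = [set(cluster)]
        if graph.number_of_nodes() == 1:
            raise ValueError("cannot remove the last node of the cluster subgraph")
    elif scope != "full":
        raise ValueError(f"unknown scope {scope!r}")

    full = all_measures(graph, partition)
    reduced = graph.copy()
    reduced.remove_node(node)
    red_part = [c - {node} for c in partition if c - {node}]
    removed = all_measures(reduced, red_part)
    return {m: removed[m] - full[m] for m in MEASURES}


def rank_candidates(deltas: pd.DataFrame, measure: str) -> pd.Series:
    """Directional average ranks for one measure over candidate deltas.

    Transitivity and density rank the most *negative* delta first; modularity,
    average path length and eigenvector centralization rank the most
    *positive* delta first.
    """
    if measure not in MEASURE_DIRECTIONS:
        raise KeyError(f"unknown measure {measure!r}")
    vals = np.round(deltas[measure].to_numpy(dtype=float), DELTA_DECIMALS)
    if MEASURE_DIRECTIONS[measure] > 0:
        vals = -vals  # most positive delta gets rank 1
    return pd.Series(rankdata(vals, method="average"), index=deltas.index)


def _directional_ranks(deltas: pd.DataFrame) -> pd.DataFrame:
    ranks = {}
    for m in MEASURES:
        sign = MEASURE_DIRECTIONS[m]
        vals = np.round(deltas[m].to_numpy(dtype=float), DELTA_DECIMALS)
        # sign < 0: ascending (most negative first); sign > 0: descending
        ranks[f"rank_{m}"] = rankdata(vals if sign < 0 else -vals, method="average")
    return pd.DataFrame(ranks, index=deltas.index)


def keystone_report(
    graph: nx.Graph,
    top_k: int = 2,
    scope: str = "full",
) -> pd.DataFrame:
    """Per-cluster node-removal report with Borda aggregation.

    Returns one row per clustered node with its cluster, the five deltas, the
    five directional ranks, ``borda_score`` (sum of the five ranks),
    ``overall_rank`` within the cluster (1 = strongest candidate; ties share
    the smallest rank and are flagged in ``tied``) and an ``is_keystone`` flag
    for the ``top_k`` best-ranked nodes per cluster.  Rows are ordered by
    (cluster, borda score, node id); the id order breaks ties for output only.
    """
    partition = partition_from_labels(graph)
    clusters = sorted(
        {d["cluster"] for _, d in graph.nodes(data=True) if d.get("cluster") is not None}
    )
    frames = []
    for cl in clusters:
        members = sorted(n for n, d in graph.nodes(data=True) if d.get("cluster") == cl)
        deltas = pd.DataFrame(
            [removal_deltas(graph, n, partition=partition, scope=scope) for n in members],
            index=pd.Index(members, name="family"),
        )
        ranks = _directional_ranks(deltas)
        borda = ranks.sum(axis=1).rename("borda_score")
        overall = pd.Series(
            rankdata(borda.to_numpy(), method="min"), index=borda.index, name="overall_rank"
        ).astype(int)
        tied = borda.duplicated(keep=False).rename("tied")
        rec = pd.concat([deltas.add_prefix("delta_"), ranks, borda, overall, tied], axis=1)
        rec.insert(0, "cluster", cl)
        rec = rec.sort_values(["borda_score", "family"], kind="mergesort")
        rec["is_keystone"] = [i < top_k for i in range(len(rec))]
        frames.append(rec)
    if not frames:
        cols = (["cluster"] + [f"delta_{m}" for m in MEASURES]
                + [f"rank_{m}" for m in MEASURES]
                + ["borda_score", "overall_rank", "tied", "is_keystone"])
        return pd.DataFrame(columns=cols, index=pd.Index([], name="family"))
    return pd.concat(frames)


def top_keystones(report: pd.DataFrame) -> dict[str, list[str]]:
    """Flagged keystone families per cluster, in Borda order."""
    out: dict[str, list[str]] = {}
    flagged = report[report["is_keystone"]]
    for cl, rows in flagged.groupby("cluster", sort=True):
        out[str(cl)] = list(rows.index)
    return out
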