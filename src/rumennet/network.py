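"""Signed family co-occurrence network and the five network-level measures.

Edges connect taxonomic families whose expression profiles have
|Spearman rho| > 0.7 and Benjamini-Hochberg adjusted p < 0.1 (both
thresholds configurable).  Community ("cluster") detection runs by greedy
modularity agglomeration on the positive-edge subgraph: negative edges mark
antagonism *between* temporal sub-microbiomes, so including them in the
community skeleton would fuse the very clusters they separate.  The unsigned
skeleton remains available via ``edges="all"``.

The five measures used by the keystone stage:

* transitivity: 3 * triangles / connected triples (0 without triples);
* density: 2E / (N(N-1)) (0 for N < 2);
* modularity of a partition: Q = sum_c [ e_c/m - (d_c/2m)^2 ] (0 when the
  graph has no edges);
* average path length: mean shortest-path distance over reachable ordered
  pairs (0 if none are reachable; a "penalize" mode counts unreachable pairs
  at distance N);
* eigenvector centralization: sum_i (c_max - c_i) / (N - 1) with eigenvector
  centralities scaled so the maximum is 1.  The centrality vector is pinned to
  a deterministic representative of the dominant eigenspace of the adjacency
  matrix — the projection of the all-ones vector — which stays well-defined on
  disconnected graphs where the leading eigenvalue is degenerate (these arise
  constantly during node removal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FamilyMatrix

MEASURES = (
    "transitivity",
    "density",
    "modularity",
    "average_path_length",
    "eigenvector_centralization",
)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise family Spearman correlations with raw and BH-adjusted p."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame

    @property
    def families(self) -> list[str]:
        return list(self.rho.index)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (tiny n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def spearman_correlations(fm: FamilyMatrix, p_method: str = "t") -> CorrelationMatrix:
    """All-pairs Spearman rho with p-values and BH adjustment.

    Ranks use mid-rank ties.  With ``p_method="t"`` the p-value comes from the
    t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of
    freedom; ``p_method="exact"`` enumerates rank permutations (n <= 8 only).
    Constant families yield undefined correlations, recorded as missing.  The
    BH adjustment runs over the strict upper triangle.
    """
    vals = fm.values
    n = vals.shape[1]
    if n < 4:
        raise ValueError("Spearman correlation network requires >= 4 samples")
    if p_method not in ("t", "exact"):
        raise ValueError(f"unknown p_method {p_method!r}")
    if p_method == "exact" and n > 8:
        raise ValueError("exact permutation p only supported for n <= 8 samples")

    ranks = vals.rank(axis=1).to_numpy()
    constant = vals.nunique(axis=1).to_numpy() <= 1
    z = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((z**2).sum(axis=1))
    denom[constant] = np.nan
    rho = (z @ z.T) / np.outer(denom, denom)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    fams = list(vals.index)
    if p_method == "exact":
        x = vals.to_numpy()
        for i, j in combinations(range(len(fams)), 2):
            if not np.isnan(rho[i, j]):
                p[i, j] = p[j, i] = _spearman_exact_p(x[i], x[j])

    iu = np.triu_indices(len(fams), k=1)
    p_adj = np.full_like(p, np.nan)
    flat = p[iu]
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.sum():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    p_adj[iu] = adj
    p_adj.T[iu] = adj

    idx = pd.Index(fams, name="family")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=idx),
    )


def build_network(
    cm: CorrelationMatrix,
    fm: FamilyMatrix,
    rho_min: float = 0.7,
    alpha: float = 0.1,
    threshold_on: str = "abs",
) -> nx.Graph:
    """Threshold the correlation matrix into a signed family graph.

    An edge exists iff |rho| > ``rho_min`` (or rho > rho_min with
    ``threshold_on="positive"``) and adjusted p < ``alpha``; its sign is the
    sign of rho.  Node weight is the family's total scaled expression.
    """
    if set(cm.families) != set(fm.families):
        raise ValueError("correlation matrix and family matrix cover different families")
    if threshold_on not in ("abs", "positive"):
        raise ValueError(f"unknown threshold_on {threshold_on!r}")
    g = nx.Graph()
    totals = fm.values.sum(axis=1)
    for fam in cm.families:
        g.add_node(fam, total_expression=float(totals[fam]), cluster=None)
    fams = cm.families
    for i, j in combinations(range(len(fams)), 2):
        rho = cm.rho.iat[i, j]
        padj = cm.p_adj.iat[i, j]
        if np.isnan(rho) or np.isnan(padj):
            continue
        strength = abs(rho) if threshold_on == "abs" else rho
        if strength > rho_min and padj < alpha:
            g.add_edge(
                fams[i], fams[j],
                rho=float(rho), p_adj=float(padj),
                sign="+" if rho >= 0 else "-",
            )
    return g


def detect_clusters(graph: nx.Graph, seed: int = 0, edges: str = "positive") -> nx.Graph:
    """Greedy modularity clustering; returns a copy with ``cluster`` labels.

    ``edges="positive"`` (default) detects communities on the positive-edge
    subgraph; ``edges="all"`` uses the full unsigned skeleton.  Tie-breaking
    is made deterministic by inserting nodes and edges in sorted order; the
    seed is accepted for interface stability.  Cluster ids ``C1, C2, ...`` are
    assigned to communities of two or more nodes, ordered by their
    lexicographically smallest member; isolated and singleton nodes keep
    ``cluster=None``.  The modularity Q of the labelled partition (singletons
    as their own communities) on the full unsigned graph is stored as a graph
    attribute.
    """
    if edges not in ("positive", "all"):
        raise ValueError(f"unknown edges mode {edges!r}")
    del seed  # deterministic by construction
    g = graph.copy()
    skel = nx.Graph()
    skel.add_nodes_from(sorted(g.nodes))
    eligible = sorted(
        (u, v) for u, v, d in g.edges(data=True)
        if edges == "all" or d.get("sign", "+") == "+"
    )
    skel.add_edges_from((min(u, v), max(u, v)) for u, v in eligible)

    if skel.number_of_edges() == 0:
        communities: list[set] = []
    else:
        active = skel.subgraph([n for n in skel if skel.degree(n) > 0])
        communities = [set(c) for c in nx.community.greedy_modularity_communities(active)]
    communities = [c for c in communities if len(c) >= 2]
    communities.sort(key=lambda c: min(c))
    for n in g.nodes:
        g.nodes[n]["cluster"] = None
    for ci, comm in enumerate(communities, start=1):
        for n in comm:
            g.nodes[n]["cluster"] = f"C{ci}"
    part = partition_from_labels(g)
    g.graph["n_clusters"] = len(communities)
    g.graph["modularity"] = modularity(g, part) if g.number_of_nodes() else float("nan")
    return g


def partition_from_labels(graph: nx.Graph) -> list[set]:
    """Partition implied by node ``cluster`` labels; unlabelled nodes become
    singleton communities."""
    by_label: dict[str, set] = {}
    singles = []
    for n, d in graph.nodes(data=True):
        lab = d.get("cluster")
        if lab is None:
            singles.append({n})
        else:
            by_label.setdefault(lab, set()).add(n)
    return [by_label[k] for k in sorted(by_label)] + singles


# ---------------------------------------------------------------------------
# the five measures
# ---------------------------------------------------------------------------

def _require_nonempty(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("measure undefined on the empty graph")


def transitivity(graph: nx.Graph) -> float:
    """Global clustering coefficient: 3 * triangles / connected triples."""
    _require_nonempty(graph)
    return float(nx.transitivity(graph))


def density(graph: nx.Graph) -> float:
    """2E / (N(N-1)); 0 for graphs with fewer than 2 nodes."""
    _require_nonempty(graph)
    return float(nx.density(graph))


def modularity(graph: nx.Graph, partition: list[set]) -> float:
    """Newman modularity of ``partition``; 0 by convention when m = 0."""
    _require_nonempty(graph)
    covered = set().union(*partition) if partition else set()
    if covered != set(graph.nodes):
        raise ValueError("partition must cover every node exactly once")
    if sum(len(c) for c in partition) != graph.number_of_nodes():
        raise ValueError("partition communities overlap")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        sub = graph.subgraph(comm)
        e_c = sub.number_of_edges()
        d_c = sum(d for _, d in graph.degree(comm))
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def average_path_length(graph: nx.Graph, unreachable: str = "ignore") -> float:
    """Mean shortest-path distance over reachable ordered pairs.

    With ``unreachable="penalize"`` every unreachable ordered pair instead
    contributes distance N.  Returns 0 when no pair is reachable.
    """
    _require_nonempty(graph)
    if unreachable not in ("ignore", "penalize"):
        raise ValueError(f"unknown unreachable mode {unreachable!r}")
    n = graph.number_of_nodes()
    total = 0.0
    reached = 0
    for node, dists in nx.all_pairs_shortest_path_length(graph):
        for other, d in dists.items():
            if other != node:
                total += d
                reached += 1
    if unreachable == "penalize":
        all_pairs = n * (n - 1)
        total += (all_pairs - reached) * n
        reached = all_pairs
    return float(total / reached) if reached else 0.0


def eigenvector_centralities(graph: nx.Graph) -> pd.Series:
    """Deterministic eigenvector centralities, scaled to max 1.

    Centralities are the projection of the all-ones vector onto the dominant
    eigenspace of the adjacency matrix (absolute values), which by
    Perron-Frobenius is non-negative and reduces to the usual leading
    eigenvector on connected graphs.  An edgeless graph yields all zeros.
    """
    _require_nonempty(graph)
    nodes = sorted(graph.nodes)
    if graph.number_of_edges() == 0:
        return pd.Series(0.0, index=nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    lam = w[-1]
    space = v[:, np.abs(w - lam) < 1e-10 * max(1.0, abs(lam))]
    ones = np.ones(len(nodes))
    c = np.abs(space @ (space.T @ ones))
    c[c < 1e-12] = 0.0
    if c.max() > 0:
        c = c / c.max()
    return pd.Series(c, index=nodes)


def eigenvector_centralization(graph: nx.Graph) -> float:
    """Freeman-style centralization: sum(c_max - c_i) / (N - 1), max-1 scaled
    scores; 0 for a single node or an edgeless graph."""
    _require_nonempty(graph)
    n = graph.number_of_nodes()
    if n == 1 or graph.number_of_edges() == 0:
        return 0.0
    c = eigenvector_centralities(graph)
    return float((c.max() - c).sum() / (n - 1))


def all_measures(graph: nx.Graph, partition: list[set]) -> dict[str, float]:
    """All five measures as a dict keyed by :data:`MEASURES`."""
    return {
        "transitivity": transitivity(graph),
        "density": density(graph),
        "modularity": modularity(graph, partition),
        "average_path_length": average_path_length(graph),
        "eigenvector_centralization": eigenvector_centralization(graph),
    }
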