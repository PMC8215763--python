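"""Independent brute-force oracles used only by the test suite.

Everything here recomputes quantities from first principles (triple
enumeration, hand BFS, pair-sum modularity, power iteration, subset
enumeration) without touching the implementation's code paths.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def brute_transitivity(g: nx.Graph) -> float:
    nodes = list(g.nodes)
    triangles = 0
    triples = 0
    for a, b, c in combinations(nodes, 3):
        edges = g.has_edge(a, b) + g.has_edge(b, c) + g.has_edge(a, c)
        if edges == 3:
            triangles += 1
            triples += 3
        elif edges == 2:
            triples += 1
    return 3.0 * triangles / triples if triples else 0.0


def brute_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def brute_modularity(g: nx.Graph, partition: list[set]) -> float:
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    comm = {}
    for ci, c in enumerate(partition):
        for n in c:
            comm[n] = ci
    deg = dict(g.degree())
    q = 0.0
    nodes = list(g.nodes)
    for i in nodes:
        for j in nodes:
            if comm[i] == comm[j]:
                a_ij = 1.0 if g.has_edge(i, j) and i != j else 0.0
                q += a_ij - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def brute_apl(g: nx.Graph) -> float:
    """Mean BFS distance over reachable ordered pairs (hand-rolled BFS)."""
    total = 0
    pairs = 0
    for src in g.nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for node, d in dist.items():
            if node != src:
                total += d
                pairs += 1
    return total / pairs if pairs else 0.0


def brute_eigencentralities(g: nx.Graph) -> np.ndarray:
    """Power iteration on A + I from the all-ones vector, scaled to max 1.

    The +I shift makes the iteration converge on bipartite components and
    selects the same dominant eigenspace representative (projection of the
    ones vector) the implementation uses.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if g.number_of_edges() == 0:
        return np.zeros(n)
    a = nx.to_numpy_array(g, nodelist=nodes) + np.eye(n)
    v = np.ones(n)
    for _ in range(20000):
        w = a @ v
        w = w / np.linalg.norm(w)
        if np.linalg.norm(w - v) < 1e-14:
            v = w
            break
        v = w
    v = np.abs(v)
    v[v < 1e-9] = 0.0
    return v / v.max()


def brute_centralization(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n <= 1 or g.number_of_edges() == 0:
        return 0.0
    c = brute_eigencentralities(g)
    return float((c.max() - c).sum() / (n - 1))


def brute_measures(g: nx.Graph, partition: list[set]) -> dict[str, float]:
    return {
        "transitivity": brute_transitivity(g),
        "density": brute_density(g),
        "modularity": brute_modularity(g, partition),
        "average_path_length": brute_apl(g),
        "eigenvector_centralization": brute_centralization(g),
    }


def _average_ranks(values: list[float]) -> list[float]:
    """Average ranks (1 = smallest), computed by sorting from scratch."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


#: -1: most negative delta should rank first; +1: most positive first
ORACLE_DIRECTIONS = {
    "transitivity": -1,
    "density": -1,
    "modularity": +1,
    "average_path_length": +1,
    "eigenvector_centralization": +1,
}


def brute_keystone_table(g: nx.Graph) -> dict[str, dict]:
    """Per-node deltas, directional ranks and Borda scores, from scratch.

    Uses the node ``cluster`` attributes for the partition (unlabelled nodes
    as singletons) and ranks candidates within each cluster.
    """
    labels = {n: g.nodes[n].get("cluster") for n in g.nodes}
    part = {}
    for n, lab in labels.items():
        part.setdefault(lab if lab is not None else ("single", n), set()).add(n)
    partition = list(part.values())
    full = brute_measures(g, partition)

    deltas = {}
    for n in g.nodes:
        h = g.copy()
        h.remove_node(n)
        p2 = [c - {n} for c in partition if c - {n}]
        rem = brute_measures(h, p2)
        deltas[n] = {m: rem[m] - full[m] for m in full}

    out: dict[str, dict] = {}
    clusters = sorted({lab for lab in labels.values() if lab is not None})
    for cl in clusters:
        members = sorted(n for n in g.nodes if labels[n] == cl)
        ranks = {n: {} for n in members}
        for meas, direction in ORACLE_DIRECTIONS.items():
            vals = [round(deltas[n][meas], 9) * (1 if direction < 0 else -1)
                    for n in members]
            for n, r in zip(members, _average_ranks(vals)):
                ranks[n][meas] = r
        for n in members:
            out[n] = {
                "cluster": cl,
                "deltas": deltas[n],
                "ranks": ranks[n],
                "borda": sum(ranks[n].values()),
            }
    return out


def exhaustive_letter_check(edges: set[frozenset], timepoints: list[float],
                            labels: dict[float, str]) -> bool:
    """Verify the letter biconditional by exhaustive subset search.

    Two timepoints must share a letter iff some maximal clique of the
    non-significance graph contains both.  Cliques and maximality are found by
    enumerating every subset.
    """
    def is_clique(sub: tuple) -> bool:
        return all(frozenset((a, b)) in edges for a, b in combinations(sub, 2))

    subsets = []
    n = len(timepoints)
    for mask in range(1, 2**n):
        sub = tuple(timepoints[i] for i in range(n) if mask >> i & 1)
        if is_clique(sub):
            subsets.append(set(sub))
    maximal = [s for s in subsets if not any(s < t for t in subsets)]

    for a, b in combinations(timepoints, 2):
        share = bool(set(labels[a]) & set(labels[b]))
        joint = any(a in m and b in m for m in maximal)
        if share != joint:
            return False
    # every letter must correspond to exactly one maximal clique
    letter_sets = {}
    for t, lab in labels.items():
        for ch in lab:
            letter_sets.setdefault(ch, set()).add(t)
    if len(letter_sets) != len(maximal):
        return False
    return sorted(map(sorted, letter_sets.values())) == sorted(map(sorted, maximal))
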