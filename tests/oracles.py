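"""Independent brute-force oracles used to validate the implementation.

Everything here is computed from first principles (definitional formulas,
exhaustive enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx


def average_ranks(v):
    """Ranks 1..n with ties given the average of their positions."""
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_definitional(x, y):
    """|Pearson correlation of the two average-rank vectors|, by the sums."""
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return 0.0
    return abs(cov / math.sqrt(vx * vy))


def kendall_tau_b_definitional(x, y):
    """|tau-b| by exhaustive enumeration of all C(n,2) sample pairs."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif (dx > 0) == (dy > 0):
            concordant += 1
        else:
            discordant += 1
    total = n * (n - 1) // 2
    denom = math.sqrt((total - ties_x) * (total - ties_y))
    if denom == 0:
        return 0.0
    return abs((concordant - discordant) / denom)


def max_spanning_forest_weight(graph: nx.Graph) -> float:
    """Maximum total weight over all spanning forests, by exhaustive search.

    Per connected component with m nodes, tries every (m-1)-subset of the
    component's edges and keeps the best acyclic spanning one. Intended
    for graphs with <= 7 nodes per component.
    """
    total = 0.0
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        m = sub.number_of_nodes()
        if m < 2:
            continue
        best = None
        edges = list(sub.edges(data="weight"))
        for subset in combinations(edges, m - 1):
            candidate = nx.Graph()
            candidate.add_nodes_from(component)
            candidate.add_weighted_edges_from(subset)
            if nx.is_forest(candidate) and nx.is_connected(candidate):
                weight = sum(w for _, _, w in subset)
                if best is None or weight > best:
                    best = weight
        assert best is not None, "connected component must admit a spanning tree"
        total += best
    return total
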