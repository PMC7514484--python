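"""Greedy topological optimization (step 2).

The ensemble network is pruned to a maximum spanning forest by a
descending-weight Kruskal pass, keeping the most significant edge along
every path. Hubs — nodes whose degree strictly exceeds the mean degree of
the pruned network — then have their pruned incident edges re-evaluated:
a removed edge is re-inserted when its ensemble weight ``w_en`` strictly
exceeds ``th_beta``. Weights are never recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from networkx.utils import UnionFind

from .ensemble import ThresholdConfig, build_ensemble_network
from .measures import ExpressionMatrix, score_all_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "PruneResult",
    "maximum_spanning_forest",
    "detect_hubs",
    "readd_hub_edges",
    "engnet",
]


@dataclass(frozen=True)
class PruneResult:
    """All intermediates of the two-step pipeline, for inspection.

    ``pruned`` is a maximum spanning forest of ``ensemble``; ``final`` is
    ``pruned`` plus the re-inserted hub edges. Invariants:
    ``pruned.edges ⊆ final.edges ⊆ ensemble.edges``.
    """

    ensemble: nx.Graph
    pruned: nx.Graph
    removed_edges: dict[tuple[str, str], float]
    hub_nodes: frozenset[str]
    final: nx.Graph


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


def maximum_spanning_forest(network: nx.Graph) -> nx.Graph:
    """Maximum-weight spanning forest via descending-weight Kruskal.

    Keeps the same node set; within each connected component of ``m``
    nodes exactly ``m - 1`` edges survive, chosen so total weight is
    maximal. Ties are broken lexicographically on the canonical pair, so
    the output is unique and reproducible.
    """
    forest = nx.Graph()
    forest.add_nodes_from(network.nodes)
    edges = sorted(
        (
            (-float(data["weight"]),) + _canonical(u, v)
            for u, v, data in network.edges(data=True)
        ),
    )
    subtrees = UnionFind(network.nodes)
    for neg_w, u, v in edges:
        if subtrees[u] != subtrees[v]:
            subtrees.union(u, v)
            forest.add_edge(u, v, weight=-neg_w)
    return forest


def detect_hubs(pruned: nx.Graph) -> frozenset[str]:
    """Nodes whose degree strictly exceeds the mean degree of ``pruned``."""
    n = pruned.number_of_nodes()
    if n == 0:
        return frozenset()
    mean_degree = 2.0 * pruned.number_of_edges() / n
    return frozenset(
        node for node, degree in pruned.degree() if degree > mean_degree
    )


def readd_hub_edges(
    ensemble: nx.Graph,
    pruned: nx.Graph,
    hubs: frozenset[str],
    th_beta: float,
    inclusive: bool = False,
) -> nx.Graph:
    """Re-insert pruned hub-incident edges whose ``w_en`` exceeds ``th_beta``.

    Weights come from the ensemble step unchanged. The default comparison
    is strict (``w_en > th_beta``); ``inclusive`` switches to ``>=`` for
    sensitivity analysis. Hub–hub edges are considered once (set
    semantics).
    """
    final = pruned.copy()
    readded = 0
    for u, v, data in ensemble.edges(data=True):
        if final.has_edge(u, v):
            continue
        if u not in hubs and v not in hubs:
            continue
        w = float(data["weight"])
        if (w >= th_beta) if inclusive else (w > th_beta):
            final.add_edge(u, v, weight=w)
            readded += 1
    logger.info("re-added %d hub-incident edges above th_beta", readded)
    return final


def engnet(
    matrix: ExpressionMatrix,
    thresholds: ThresholdConfig,
    bins: int | str = "auto",
    inclusive_significance: bool = True,
    inclusive_beta: bool = False,
    keep_isolated: bool = False,
) -> PruneResult:
    """Run the full two-step pipeline on an expression matrix.

    Composes all-pairs scoring, the 2-of-3 vote, maximum-spanning-forest
    pruning, hub detection and hub edge re-insertion; returns every
    intermediate. Fully deterministic.
    """
    scores = score_all_pairs(
        matrix, thresholds, bins=bins, inclusive=inclusive_significance
    )
    ensemble = build_ensemble_network(
        scores, keep_isolated=keep_isolated, gene_universe=matrix.gene_ids
    )
    pruned = maximum_spanning_forest(ensemble)
    removed = {
        _canonical(u, v): float(data["weight"])
        for u, v, data in ensemble.edges(data=True)
        if not pruned.has_edge(u, v)
    }
    hubs = detect_hubs(pruned)
    final = readd_hub_edges(
        ensemble, pruned, hubs, thresholds.th_beta, inclusive=inclusive_beta
    )
    logger.info(
        "pipeline: %d ensemble / %d pruned / %d final edges, %d hubs",
        ensemble.number_of_edges(), pruned.number_of_edges(),
        final.number_of_edges(), len(hubs),
    )
    return PruneResult(
        ensemble=ensemble,
        pruned=pruned,
        removed_edges=removed,
        hub_nodes=hubs,
        final=final,
    )
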