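"""Precision/recall of an inferred network against a gold standard.

Edges are compared as canonical unordered identifier pairs:
TP = inferred ∩ gold, FP = inferred ∖ gold, FN = gold ∖ inferred, with
precision = TP / (TP + FP) and recall = TP / (TP + FN). By default FN is
counted over the full gold standard — the convention that reproduces the
very small recall magnitudes typical when the gold standard is a
database-scale interaction set — with an option to restrict the gold
edges to the measured gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

__all__ = ["GoldStandard", "EvaluationReport", "compare_to_gold"]


@dataclass(frozen=True)
class GoldStandard:
    """An undirected reference edge set (no self-loops, no duplicates)."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GoldStandard":
        canonical = set()
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop in gold standard: {a!r}")
            canonical.add((a, b) if a < b else (b, a))
        return cls(edges=frozenset(canonical))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for edge in self.edges for n in edge)


@dataclass(frozen=True)
class EvaluationReport:
    """TP/FP/FN counts and the derived precision/recall.

    ``precision`` is None (absent) for an empty inferred network;
    ``recall`` is None for an empty gold standard.
    """

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]


def _network_edges(network: nx.Graph) -> set[tuple[str, str]]:
    return {
        (u, v) if u < v else (v, u) for u, v in network.edges()
    }


def compare_to_gold(
    network: nx.Graph,
    gold: GoldStandard,
    restrict_gold: bool = False,
    uppercase: bool = False,
) -> EvaluationReport:
    """Score ``network`` against ``gold``.

    With ``restrict_gold``, gold edges are first filtered to those whose
    endpoints both occur in the network's node set, so FN counts only
    missed edges among measured genes. ``uppercase`` normalizes
    identifiers on both sides before matching; no alias resolution is
    attempted.
    """
    inferred = _network_edges(network)
    gold_edges = set(gold.edges)
    if uppercase:
        inferred = {tuple(sorted((a.upper(), b.upper()))) for a, b in inferred}
        gold_edges = {tuple(sorted((a.upper(), b.upper()))) for a, b in gold_edges}
    if restrict_gold:
        universe = {n.upper() for n in network.nodes} if uppercase else set(network.nodes)
        gold_edges = {e for e in gold_edges if e[0] in universe and e[1] in universe}
    tp = len(inferred & gold_edges)
    fp = len(inferred - gold_edges)
    fn = len(gold_edges - inferred)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return EvaluationReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
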