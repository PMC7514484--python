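"""Majority-vote ensemble network construction (step 1).

A gene pair becomes an edge when at least two of the three measures call
it significant; the edge weight ``w_en`` is the arithmetic mean of all
three measure scores — including any score below its own threshold, so
the weight is independent of the thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .measures import PairScore

logger = logging.getLogger(__name__)

__all__ = ["ThresholdConfig", "vote", "ensemble_weight", "build_ensemble_network"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance thresholds: th1 (Spearman), th2 (Kendall), th3 (NMI),
    and th_beta for hub edge re-insertion. All in [0, 1]."""

    th1: float
    th2: float
    th3: float
    th_beta: float

    def __post_init__(self) -> None:
        for name in ("th1", "th2", "th3", "th_beta"):
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
            object.__setattr__(self, name, v)


def vote(sig_spearman: bool, sig_kendall: bool, sig_nmi: bool) -> bool:
    """Majority vote: the pair is confirmed iff at least two measures
    deem it significant."""
    return (int(sig_spearman) + int(sig_kendall) + int(sig_nmi)) >= 2


def ensemble_weight(v_spearman: float, v_kendall: float, v_nmi: float) -> float:
    """Ensemble edge weight ``w_en``: arithmetic mean of the three scores."""
    return (v_spearman + v_kendall + v_nmi) / 3.0


def build_ensemble_network(
    scores: Iterable[PairScore],
    keep_isolated: bool = False,
    gene_universe: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Assemble the weighted ensemble network from pair scores.

    An edge is present iff the 2-of-3 vote confirms the pair; its weight
    is ``w_en``. By default only genes incident to a confirmed edge are
    kept as nodes (reported node counts then reflect connected genes);
    with ``keep_isolated`` the full ``gene_universe`` is retained.

    Edges are inserted in lexicographic canonical-pair order so output
    is byte-reproducible.
    """
    network = nx.Graph()
    if keep_isolated:
        if gene_universe is None:
            raise ValueError("keep_isolated=True requires a gene_universe")
        network.add_nodes_from(sorted(map(str, gene_universe)))
    confirmed = [
        s for s in scores if vote(s.sig_spearman, s.sig_kendall, s.sig_nmi)
    ]
    confirmed.sort(key=lambda s: (s.gene_a, s.gene_b))
    for s in confirmed:
        network.add_edge(
            s.gene_a, s.gene_b,
            weight=ensemble_weight(s.v_spearman, s.v_kendall, s.v_nmi),
        )
    logger.info(
        "ensemble network: %d nodes, %d edges after 2-of-3 vote",
        network.number_of_nodes(), network.number_of_edges(),
    )
    return network
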