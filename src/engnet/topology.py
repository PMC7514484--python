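"""Scale-free topology diagnostics.

Five statistics characterize whether an inferred network looks like a
sparse, hub-dominated biological network: average clustering coefficient,
characteristic path length (CPL), diameter, graph density, and the
power-law exponent gamma of the degree distribution P(k) ~ k^(-gamma).

All path statistics use the hop metric (edge weights ignored); for
disconnected networks — common here, since the method yields forests
plus hub edges — CPL and diameter are taken over finite pairs only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np

__all__ = [
    "TopologyReport",
    "average_clustering",
    "characteristic_path_length",
    "diameter",
    "graph_density",
    "degree_histogram",
    "fit_power_law_gamma",
    "topology_report",
]


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_clustering: float
    cpl: float
    diameter: int
    density: float
    gamma: Optional[float]
    degree_histogram: dict[int, int]


def _require_nonempty(network: nx.Graph) -> None:
    if network.number_of_nodes() == 0:
        raise ValueError("topology statistics undefined for an empty network")


def average_clustering(network: nx.Graph) -> float:
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    _require_nonempty(network)
    return float(nx.average_clustering(network))


def _finite_path_lengths(network: nx.Graph) -> list[int]:
    lengths: list[int] = []
    for component in nx.connected_components(network):
        if len(component) < 2:
            continue
        sub = network.subgraph(component)
        for source, targets in nx.all_pairs_shortest_path_length(sub):
            for target, dist in targets.items():
                if source < target:
                    lengths.append(dist)
    return lengths


def characteristic_path_length(network: nx.Graph) -> float:
    """Mean shortest-path length (hops) over finite unordered pairs."""
    if network.number_of_nodes() < 2:
        raise ValueError("CPL requires at least 2 nodes")
    lengths = _finite_path_lengths(network)
    if not lengths:
        raise ValueError("no connected pair: CPL undefined")
    return float(np.mean(lengths))


def diameter(network: nx.Graph) -> int:
    """Maximum finite shortest-path length (hops)."""
    if network.number_of_nodes() < 2:
        raise ValueError("diameter requires at least 2 nodes")
    lengths = _finite_path_lengths(network)
    if not lengths:
        raise ValueError("no connected pair: diameter undefined")
    return int(max(lengths))


def graph_density(network: nx.Graph) -> float:
    """2m / (n (n - 1)): fraction of possible edges present."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * network.number_of_edges() / (n * (n - 1))


def degree_histogram(network: nx.Graph) -> dict[int, int]:
    """Mapping degree k -> number of nodes with that degree."""
    return dict(sorted(Counter(d for _, d in network.degree()).items()))


def fit_power_law_gamma(
    histogram: Mapping[int, int],
    method: str = "ls",
) -> Optional[float]:
    """Estimate the degree-distribution exponent gamma.

    ``"ls"`` (default) regresses log count(k) on log k over degrees
    k >= 1 with nonzero count and returns the negated slope — the
    convention of classic network-analysis tools. ``"mle"`` uses the
    continuous-approximation maximum-likelihood estimator
    ``1 + n / sum(ln(k / (kmin - 1/2)))`` for robustness comparisons.

    Returns None when fewer than two usable degrees remain (the
    degenerate case reported as absent).
    """
    ks = np.array(
        sorted(k for k, c in histogram.items() if k >= 1 and c > 0), dtype=float
    )
    if ks.size < 2:
        return None
    counts = np.array([histogram[int(k)] for k in ks], dtype=float)
    if method == "ls":
        slope = np.polyfit(np.log(ks), np.log(counts), 1)[0]
        return float(-slope)
    if method == "mle":
        k_min = ks.min()
        degrees = np.repeat(ks, counts.astype(int))
        denom = np.sum(np.log(degrees / (k_min - 0.5)))
        if denom <= 0:
            return None
        return float(1.0 + degrees.size / denom)
    raise ValueError(f"unknown gamma estimator: {method!r}")


def topology_report(network: nx.Graph, gamma_method: str = "ls") -> TopologyReport:
    """Assemble all five diagnostics plus node/edge counts."""
    _require_nonempty(network)
    hist = degree_histogram(network)
    n = network.number_of_nodes()
    try:
        cpl = characteristic_path_length(network)
        diam = diameter(network)
    except ValueError:
        cpl = math.nan
        diam = 0
    return TopologyReport(
        n_nodes=n,
        n_edges=network.number_of_edges(),
        avg_clustering=average_clustering(network),
        cpl=cpl,
        diameter=diam,
        density=graph_density(network) if n >= 2 else math.nan,
        gamma=fit_power_law_gamma(hist, method=gamma_method),
        degree_histogram=hist,
    )
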