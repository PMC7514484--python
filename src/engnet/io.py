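"""Readers and writers for the package's delimited-text formats.

Expression matrices are genes-in-rows tables (first column = gene id,
first row = sample header; tab or comma delimited, auto-detected).
Networks travel as three-column weighted edge lists (gene_a, gene_b,
w_en with 6-decimal weights) or as SIF for Cytoscape import. Gold
standards are two-column edge lists; extra columns are ignored and
``#`` comment lines skipped.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .evaluation import GoldStandard
from .measures import ExpressionMatrix
from .topology import TopologyReport

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "write_sif",
    "read_gold_standard",
    "write_degree_histogram",
    "topology_row",
]

PathLike = Union[str, Path]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as handle:
        header = handle.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(
    path: PathLike, delimiter: Optional[str] = None
) -> ExpressionMatrix:
    """Read a genes x samples table; duplicate gene identifiers are an error."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene identifiers: {dupes[:5]}")
    try:
        return ExpressionMatrix.from_dataframe(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_expression_matrix(
    matrix: ExpressionMatrix, path: PathLike, delimiter: str = "\t"
) -> None:
    matrix.to_dataframe().to_csv(Path(path), sep=delimiter, index_label="gene")


def write_edge_list(network: nx.Graph, path: PathLike) -> None:
    """Weighted TSV edge list, lexicographic pair order, 6-decimal weights."""
    rows = sorted(
        ((u, v) if u < v else (v, u)) + (float(d["weight"]),)
        for u, v, d in network.edges(data=True)
    )
    with open(Path(path), "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for a, b, w in rows:
            writer.writerow([a, b, f"{w:.6f}"])


def read_edge_list(path: PathLike) -> nx.Graph:
    """Read a weighted edge list back into a graph."""
    network = nx.Graph()
    path = Path(path)
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                weight = float(row[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad weight {row[2]!r}") from None
            network.add_edge(row[0], row[1], weight=weight)
    return network


def write_sif(network: nx.Graph, path: PathLike, interaction: str = "co") -> None:
    """SIF dialect (gene_a <tag> gene_b) for Cytoscape import."""
    rows = sorted((u, v) if u < v else (v, u) for u, v in network.edges())
    with open(Path(path), "w", newline="") as handle:
        for a, b in rows:
            handle.write(f"{a}\t{interaction}\t{b}\n")


def read_gold_standard(path: PathLike, delimiter: Optional[str] = None) -> GoldStandard:
    """Two-column edge list; extra columns ignored, # comments skipped."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    pairs = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter=sep), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            pairs.append((row[0].strip(), row[1].strip()))
    return GoldStandard.from_pairs(pairs)


def write_degree_histogram(histogram: dict[int, int], path: PathLike) -> None:
    with open(Path(path), "w", newline="") as handle:
        for k, count in sorted(histogram.items()):
            handle.write(f"{k}\t{count}\n")


def topology_row(report: TopologyReport) -> dict[str, object]:
    """One summary row (nodes / edges / Clust. Coef / CPL / Diameter /
    Density / Gamma); absent gamma renders as '-'."""
    return {
        "nodes": report.n_nodes,
        "edges": report.n_edges,
        "clust_coef": round(report.avg_clustering, 6),
        "cpl": round(report.cpl, 6),
        "diameter": report.diameter,
        "density": round(report.density, 6),
        "gamma": "-" if report.gamma is None else round(report.gamma, 6),
    }
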