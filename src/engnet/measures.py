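"""Pairwise dependency measures for gene co-expression.

Three measures — Spearman's rho, Kendall's tau-b and normalized mutual
information (NMI) — each mapped onto the dependency scale [0, 1], where 0
means no dependency and 1 total dependency between two expression profiles.
Signed rank correlations are folded by absolute value: in co-expression
analysis a strong negative correlation is as informative as a positive one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PairScore",
    "spearman_score",
    "kendall_score",
    "nmi_score",
    "score_pair",
    "score_all_pairs",
]

#: Minimum number of pairwise-complete samples needed to score a pair.
MIN_SAMPLES = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples numeric expression table.

    Parameters
    ----------
    gene_ids
        Unique, non-empty gene identifiers, one per row.
    sample_ids
        Unique, non-empty sample identifiers, one per column.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        if len(genes) == 0 or any(g == "" for g in genes):
            raise ValueError("gene identifiers must be non-empty")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers")
        if len(samples) == 0 or any(s == "" for s in samples):
            raise ValueError("sample identifiers must be non-empty")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        if len(samples) < MIN_SAMPLES:
            raise ValueError(
                f"at least {MIN_SAMPLES} samples required, got {len(samples)}"
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def profile(self, gene: str) -> np.ndarray:
        """Expression profile (one row) for ``gene``."""
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene identifier: {gene!r}") from None
        return self.values[idx]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes-in-rows DataFrame (index = gene ids)."""
        return cls(
            gene_ids=tuple(map(str, frame.index)),
            sample_ids=tuple(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.gene_ids),
            columns=list(self.sample_ids),
        )


@dataclass(frozen=True)
class PairScore:
    """The three dependency values and significance flags for one gene pair.

    ``gene_a < gene_b`` under lexicographic ordering (undirected pair).
    """

    gene_a: str
    gene_b: str
    v_spearman: float
    v_kendall: float
    v_nmi: float
    sig_spearman: bool
    sig_kendall: bool
    sig_nmi: bool

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError(
                f"pair must be canonically ordered, got ({self.gene_a!r}, {self.gene_b!r})"
            )
        for name in ("v_spearman", "v_kendall", "v_nmi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def scores(self) -> tuple[float, float, float]:
        return (self.v_spearman, self.v_kendall, self.v_nmi)

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.sig_spearman, self.sig_kendall, self.sig_nmi)


# ---------------------------------------------------------------------------
# Input validation helpers
# ---------------------------------------------------------------------------

def _check_profiles(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("expression profiles must be one-dimensional")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"profile length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < MIN_SAMPLES:
        raise ValueError(
            f"profiles need at least {MIN_SAMPLES} samples, got {x.shape[0]}"
        )
    return x, y


def _is_constant(v: np.ndarray) -> bool:
    return bool(np.all(v == v[0]))


# ---------------------------------------------------------------------------
# The three measures
# ---------------------------------------------------------------------------

def spearman_score(x: Sequence[float], y: Sequence[float]) -> float:
    """Absolute Spearman rank correlation, in [0, 1].

    Constant profiles score 0 (no co-expression signal, avoids NaN).
    """
    x, y = _check_profiles(x, y)
    if _is_constant(x) or _is_constant(y):
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(min(abs(rho), 1.0))


def kendall_score(x: Sequence[float], y: Sequence[float]) -> float:
    """Absolute Kendall tau-b (tie-corrected), in [0, 1].

    Tau-b keeps the score reachable to 1 in the presence of ties, which
    are common in expression data. Constant profiles score 0.
    """
    x, y = _check_profiles(x, y)
    if _is_constant(x) or _is_constant(y):
        return 0.0
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(min(abs(tau), 1.0))


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into at most ``n_bins`` equal-frequency bins.

    Interior quantile cut points are used; duplicate cut points (heavy
    ties) simply merge bins, which is the desired behaviour.
    """
    if n_bins <= 1:
        return np.zeros(v.shape[0], dtype=np.intp)
    cuts = np.quantile(v, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    return np.searchsorted(cuts, v, side="right")


def auto_bins(n_samples: int) -> int:
    """Default bin count for NMI discretization: ``ceil(n^(1/3))``.

    The cube-root rule keeps the finite-sample mutual-information bias
    (~ (B-1)^2 / 2n nats) small relative to the marginal entropies, so
    that independent profiles score near 0.
    """
    return max(2, math.ceil(n_samples ** (1.0 / 3.0)))


def nmi_score(
    x: Sequence[float],
    y: Sequence[float],
    bins: int | str = "auto",
) -> float:
    """Normalized mutual information in [0, 1].

    Each profile is discretized independently into ``bins`` equal-frequency
    bins (``"auto"`` = cube-root rule), then
    ``NMI = I(X; Y) / sqrt(H(X) * H(Y))``. The geometric-mean normalizer is
    symmetric and bounds the score by 1. A profile occupying a single bin
    has zero entropy and scores 0.
    """
    x, y = _check_profiles(x, y)
    if bins == "auto":
        n_bins = auto_bins(x.shape[0])
    else:
        n_bins = int(bins)
        if n_bins < 1:
            raise ValueError(f"bins must be >= 1, got {bins}")
    lx = _equal_frequency_bins(x, n_bins)
    ly = _equal_frequency_bins(y, n_bins)
    return _nmi_from_labels(lx, ly)


def _nmi_from_labels(lx: np.ndarray, ly: np.ndarray) -> float:
    n = lx.shape[0]
    kx = int(lx.max()) + 1
    ky = int(ly.max()) + 1
    contingency = np.zeros((kx, ky), dtype=float)
    np.add.at(contingency, (lx, ly), 1.0)
    joint = contingency / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    h_x = float(stats.entropy(px))
    h_y = float(stats.entropy(py))
    if h_x == 0.0 or h_y == 0.0:
        return 0.0
    h_xy = float(stats.entropy(joint.ravel()))
    mi = h_x + h_y - h_xy
    nmi = mi / math.sqrt(h_x * h_y)
    # clip tiny numerical excursions outside [0, 1]
    return float(min(max(nmi, 0.0), 1.0))


# ---------------------------------------------------------------------------
# All-pairs scoring
# ---------------------------------------------------------------------------

def score_pair(
    gene_a: str,
    gene_b: str,
    x: Sequence[float],
    y: Sequence[float],
    thresholds,
    bins: int | str = "auto",
    inclusive: bool = True,
) -> PairScore:
    """Score one gene pair with all three measures and set significance flags.

    A measure deems the pair significant when its score reaches the
    measure's threshold (``v >= th`` by default; strict ``>`` when
    ``inclusive`` is False). Non-finite samples are dropped pairwise; if
    fewer than 3 complete samples remain the pair scores 0 on all measures.
    """
    a, b = (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if not mask.all():
        x, y = x[mask], y[mask]
    if x.shape[0] < MIN_SAMPLES:
        logger.warning(
            "pair (%s, %s): only %d pairwise-complete samples, scoring 0",
            a, b, x.shape[0],
        )
        vs = vk = vn = 0.0
    else:
        vs = spearman_score(x, y)
        vk = kendall_score(x, y)
        vn = nmi_score(x, y, bins=bins)

    def sig(v: float, th: float) -> bool:
        return v >= th if inclusive else v > th

    return PairScore(
        gene_a=a,
        gene_b=b,
        v_spearman=vs,
        v_kendall=vk,
        v_nmi=vn,
        sig_spearman=sig(vs, thresholds.th1),
        sig_kendall=sig(vk, thresholds.th2),
        sig_nmi=sig(vn, thresholds.th3),
    )


def score_all_pairs(
    matrix: ExpressionMatrix,
    thresholds,
    bins: int | str = "auto",
    inclusive: bool = True,
) -> list[PairScore]:
    """Score every unordered gene pair of ``matrix``.

    Returns exactly ``C(G, 2)`` records for ``G`` genes, in lexicographic
    pair order. Deterministic given the same matrix and configuration.
    """
    order = np.argsort(np.asarray(matrix.gene_ids, dtype=object))
    genes = [matrix.gene_ids[i] for i in order]
    rows = matrix.values[order]
    scores: list[PairScore] = []
    for (i, ga), (j, gb) in combinations(enumerate(genes), 2):
        scores.append(
            score_pair(ga, gb, rows[i], rows[j], thresholds,
                       bins=bins, inclusive=inclusive)
        )
    logger.info("scored %d gene pairs over %d genes", len(scores), len(genes))
    return scores


def scores_to_frame(scores: Iterable[PairScore]) -> pd.DataFrame:
    """Tabulate pair scores as a DataFrame (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "gene_a": s.gene_a,
                "gene_b": s.gene_b,
                "v_spearman": s.v_spearman,
                "v_kendall": s.v_kendall,
                "v_nmi": s.v_nmi,
                "sig_spearman": s.sig_spearman,
                "sig_kendall": s.sig_kendall,
                "sig_nmi": s.sig_nmi,
            }
            for s in scores
        ]
    )
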