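"""Synthetic expression matrices with planted co-expressed modules.

Each module's genes load on a shared standard-normal latent profile:
``g_i = sqrt(rho) * latent + sqrt(1 - rho) * eps_i`` gives an expected
pairwise Pearson (and asymptotically Spearman) correlation of ``rho``
within the module. Remaining genes are independent noise. Everything is
reproducible per seed.

The generator emulates the covariance structure of co-expressed gene
groups, not the marginal distribution of real expression data (no
mean-variance trend, counts, dropout or batch structure).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .measures import ExpressionMatrix

__all__ = ["generate_fixture"]


def generate_fixture(
    n_genes: int,
    n_samples: int,
    modules: Sequence[tuple[int, float]] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Generate a genes x samples matrix with planted modules.

    Parameters
    ----------
    n_genes
        Total gene count; module sizes must sum to at most this.
    n_samples
        Samples (columns); at least 3.
    modules
        ``(size, within_correlation)`` per planted module, correlations
        in [0, 1).
    noise_sd
        Standard deviation applied to every gene's profile (a pure scale
        factor; correlations are unaffected).
    seed
        Seed for the pseudo-random generator.

    Gene identifiers are ``M<m>_G<i>`` for module members and ``N_G<i>``
    for background noise genes; sample identifiers are ``S<j>``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    total_module = sum(size for size, _ in modules)
    if total_module > n_genes:
        raise ValueError(
            f"module sizes sum to {total_module} > n_genes = {n_genes}"
        )
    for size, rho in modules:
        if size < 2:
            raise ValueError(f"module size must be >= 2, got {size}")
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"within-correlation must be in [0, 1), got {rho}")

    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for m, (size, rho) in enumerate(modules, start=1):
        latent = rng.standard_normal(n_samples)
        shared = math.sqrt(rho)
        indep = math.sqrt(1.0 - rho)
        for i in range(1, size + 1):
            eps = rng.standard_normal(n_samples)
            rows.append(noise_sd * (shared * latent + indep * eps))
            gene_ids.append(f"M{m}_G{i}")
    for i in range(1, n_genes - total_module + 1):
        rows.append(noise_sd * rng.standard_normal(n_samples))
        gene_ids.append(f"N_G{i}")

    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(f"S{j}" for j in range(1, n_samples + 1)),
        values=np.vstack(rows),
    )
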