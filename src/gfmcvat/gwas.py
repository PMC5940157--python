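"""Marginal per-SNP regression scan of estimated genomic values.

Each segregating SNP is tested by a t-test on the slope from the simple
regression of the line-level genomic values g^ (from the all-SNP GBLUP fit)
on the 0/2 allele counts — the single-marker baseline against which the
set-based results are contrasted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .panel import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class MarginalResult:
    table: pd.DataFrame = field(repr=False)  # snp_id, chrom, pos, beta, t, p
    n_lines: int
    n_tested: int
    threshold: float | None = None


def marginal_scan(g_hat: np.ndarray, panel: GenotypePanel) -> MarginalResult:
    """Simple linear regression of g^ on each SNP's allele counts.

    t = beta^/SE(beta^) with n-2 degrees of freedom, computed through the
    correlation identity t = r sqrt(n-2)/sqrt(1-r^2).  Constant genotype
    columns are skipped with a warning.
    """
    g = np.asarray(g_hat, dtype=float)
    if g.shape[0] != panel.n_lines:
        raise ValueError("g_hat must align with the panel lines")
    n = panel.n_lines
    if n < 3:
        raise ValueError("need at least 3 lines for a slope t-test")
    a = panel.imputed_counts()
    ac = a - a.mean(axis=0, keepdims=True)
    var_a = (ac ** 2).sum(axis=0)
    poly = var_a > 0
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.warning("skipped %d monomorphic SNP(s) in marginal scan", n_skipped)
    gc = g - g.mean()
    ss_g = float(gc @ gc)
    cov = ac[:, poly].T @ gc
    beta = cov / var_a[poly]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(var_a[poly] * ss_g)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame({
        "snp_id": panel.snps["snp_id"].to_numpy()[poly],
        "chrom": panel.snps["chrom"].to_numpy()[poly],
        "pos": panel.snps["pos"].to_numpy()[poly],
        "beta": beta,
        "t": t,
        "p": p,
    })
    return MarginalResult(table=table, n_lines=n, n_tested=int(poly.sum()))


def genomewide_threshold(m_snps: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide significance threshold alpha/m."""
    if m_snps < 1:
        raise ValueError("need at least one test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m_snps
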