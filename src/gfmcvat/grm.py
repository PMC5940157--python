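"""Centered/scaled genotype matrices and genomic relationship matrices.

The relationship matrix is G = WW'/m with column i of W equal to
(a_i - 2 p_i) / sqrt(2 p_i (1 - p_i)), where a_i are minor-allele counts
(0/2 in a fully homozygous panel) and p_i the within-panel minor allele
frequency.  For a homozygous panel the genotype variance at a locus is
4 p (1 - p), twice the Hardy-Weinberg value the scale assumes, so diagonal
elements of G sit near 2 rather than 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel


class GRMError(ValueError):
    pass


@dataclass
class ScaledGenotypes:
    """Line x SNP matrix of standardized allele counts."""

    W: np.ndarray = field(repr=False)
    snp_index: np.ndarray  # panel SNP indices for the columns of W
    line_ids: list[str]

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class GRM:
    """Genomic relationship matrix with the SNP count it was built on."""

    G: np.ndarray = field(repr=False)
    m: int
    line_ids: list[str]
    label: str = "total"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape[0] != self.G.shape[1]:
            raise GRMError("G must be square")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise GRMError("G must be symmetric")

    def mean_diagonal(self) -> float:
        """Average self-relationship; ~2 for fully homozygous 0/2 coding, so a
        model-scale variance component times this equals the phenotypic-scale
        variance the component contributes."""
        return float(np.mean(np.diagonal(self.G)))


def center_scale(panel: GenotypePanel, snp_subset: np.ndarray | None = None) -> ScaledGenotypes:
    """Build the centered and scaled genotype matrix W for a SNP subset.

    Missing genotypes are mean-imputed before centering.  Monomorphic SNPs
    (p_i(1-p_i) = 0) have no defined scale and raise an error naming the SNP.
    """
    if snp_subset is None:
        snp_subset = np.arange(panel.n_snps)
    snp_subset = np.asarray(snp_subset, dtype=int)
    a = panel.imputed_counts()[:, snp_subset]
    p = panel.snps["maf"].to_numpy(dtype=float)[snp_subset]
    bad = np.flatnonzero(p * (1.0 - p) <= 0.0)
    if bad.size:
        names = panel.snps["snp_id"].iloc[snp_subset[bad[:5]]].tolist()
        raise GRMError(f"monomorphic SNP(s) in subset (zero scale): {names}")
    W = (a - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    # re-center: mean imputation plus stored-p centering can leave tiny offsets
    W = W - W.mean(axis=0, keepdims=True)
    return ScaledGenotypes(W=W, snp_index=snp_subset, line_ids=list(panel.line_ids))


def compute_grm(Wm: ScaledGenotypes, label: str = "total") -> GRM:
    """G = WW'/m."""
    if Wm.m < 1:
        raise GRMError("need at least one SNP")
    G = (Wm.W @ Wm.W.T) / Wm.m
    G = (G + G.T) / 2.0
    return GRM(G=G, m=Wm.m, line_ids=list(Wm.line_ids), label=label)


def partition_grm(Wm: ScaledGenotypes, feature_snps: np.ndarray) -> tuple[GRM, GRM]:
    """Split W into feature and remainder GRMs: G_f = W_f W_f'/m_f etc.

    ``feature_snps`` are panel SNP indices; they must be a nonempty strict
    subset of the columns of W.  The returned pair satisfies
    m_f G_f + m_r G_r = m G exactly.
    """
    feature_snps = np.asarray(feature_snps, dtype=int)
    in_feat = np.isin(Wm.snp_index, feature_snps)
    m_f = int(in_feat.sum())
    if m_f == 0:
        raise GRMError("feature SNP set is empty within W")
    if m_f == Wm.m:
        raise GRMError("feature SNP set covers all SNPs; no remainder component")
    Wf = ScaledGenotypes(W=Wm.W[:, in_feat], snp_index=Wm.snp_index[in_feat],
                         line_ids=Wm.line_ids)
    Wr = ScaledGenotypes(W=Wm.W[:, ~in_feat], snp_index=Wm.snp_index[~in_feat],
                         line_ids=Wm.line_ids)
    return compute_grm(Wf, label="feature"), compute_grm(Wr, label="remainder")


# ---------------------------------------------------------------------------
# Persistence: TSV matrix + JSON sidecar with m and label
# ---------------------------------------------------------------------------

def write_grm(grm: GRM, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(grm.G, index=grm.line_ids, columns=grm.line_ids).to_csv(path, sep="\t")
    meta = {"m": grm.m, "label": grm.label, "n_lines": len(grm.line_ids)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_grm(path: str | Path) -> GRM:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return GRM(G=df.to_numpy(dtype=float), m=int(meta["m"]),
               line_ids=[str(x) for x in df.index], label=meta["label"])
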