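"""Genotype panels for fully inbred (homozygous) line collections.

Genotypes are stored as minor-allele counts, so every observed entry is 0 or
2; missing calls are NaN until they are mean-imputed ahead of any matrix
algebra.  Per-SNP metadata (chromosome, 1-based position, minor allele
frequency, Phred quality, call rate) rides along in a DataFrame aligned with
the columns of the allele-count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "maf", "qual", "call_rate"]


class PanelError(ValueError):
    """Raised for malformed or empty genotype panels."""


def _empirical_maf(col: np.ndarray) -> float:
    """Minor-allele frequency of one 0/2-coded column, ignoring NaN."""
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return np.nan
    freq = obs.sum() / (2.0 * obs.size)
    return min(freq, 1.0 - freq)


@dataclass
class GenotypePanel:
    """Homozygous-line biallelic genotypes plus per-SNP metadata.

    Parameters
    ----------
    line_ids
        Ordered line labels (rows of ``allele_counts``).
    snps
        DataFrame with columns ``snp_id, chrom, pos, maf, qual, call_rate``;
        one row per column of ``allele_counts``.  Positions are 1-based and
        strictly increasing within each chromosome.
    allele_counts
        ``n_lines x n_snps`` float array of minor-allele counts in {0, 2},
        NaN for missing calls.
    """

    line_ids: list[str]
    snps: pd.DataFrame
    allele_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.snps = self.snps.reset_index(drop=True)
        self.allele_counts = np.asarray(self.allele_counts, dtype=float)
        if self.allele_counts.shape != (len(self.line_ids), len(self.snps)):
            raise PanelError(
                f"allele_counts shape {self.allele_counts.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        obs = self.allele_counts[~np.isnan(self.allele_counts)]
        if obs.size and not np.isin(obs, (0.0, 2.0)).all():
            raise PanelError("allele counts must be 0 or 2 (homozygous coding)")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise PanelError(f"positions not strictly increasing on {chrom}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def recompute_maf(self) -> None:
        """Refresh the stored per-SNP MAF from the genotype matrix."""
        self.snps["maf"] = [
            _empirical_maf(self.allele_counts[:, j]) for j in range(self.n_snps)
        ]

    def subset_snps(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            line_ids=self.line_ids,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            allele_counts=self.allele_counts[:, idx],
        )

    def imputed_counts(self) -> np.ndarray:
        """Allele counts with missing entries replaced by the per-SNP mean.

        Mean imputation keeps the centered genotype matrix centered, which is
        what the relationship-matrix algebra assumes.
        """
        a = self.allele_counts.copy()
        col_mean = np.nanmean(a, axis=0)
        nan_r, nan_c = np.where(np.isnan(a))
        a[nan_r, nan_c] = col_mean[nan_c]
        return a


@dataclass(frozen=True)
class SNPFilterSpec:
    """Inclusion thresholds for SNPs: MAF >= maf_min, Phred quality strictly
    > qual_min, call rate >= callrate_min."""

    maf_min: float = 0.05
    qual_min: float = 500.0
    callrate_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= self.callrate_min <= 1.0:
            raise ValueError("callrate_min must lie in [0, 1]")


def filter_snps(
    panel: GenotypePanel, spec: SNPFilterSpec = SNPFilterSpec()
) -> tuple[GenotypePanel, dict[str, int]]:
    """Apply the MAF / quality / call-rate inclusion filters.

    Returns the filtered panel and a report dict with per-criterion removal
    counts.  A SNP failing several criteria is attributed to the first failing
    one in the order MAF, quality, call rate (reporting only; retention is the
    conjunction of all three).
    """
    maf = panel.snps["maf"].to_numpy(dtype=float)
    qual = panel.snps["qual"].to_numpy(dtype=float)
    cr = panel.snps["call_rate"].to_numpy(dtype=float)

    fail_maf = ~(maf >= spec.maf_min)
    fail_qual = ~(qual > spec.qual_min)
    fail_cr = ~(cr >= spec.callrate_min)
    keep = ~(fail_maf | fail_qual | fail_cr)

    report = {
        "input": panel.n_snps,
        "removed_maf": int(fail_maf.sum()),
        "removed_qual": int((fail_qual & ~fail_maf).sum()),
        "removed_callrate": int((fail_cr & ~fail_maf & ~fail_qual).sum()),
        "retained": int(keep.sum()),
    }
    if report["retained"] == 0:
        logger.warning("SNP filter retained 0 of %d SNPs", panel.n_snps)
    else:
        logger.info(
            "SNP filter retained %d/%d SNPs (removed: %d MAF, %d quality, %d call rate)",
            report["retained"], report["input"], report["removed_maf"],
            report["removed_qual"], report["removed_callrate"],
        )
    return panel.subset_snps(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# I/O: TSV matrix and VCF
# ---------------------------------------------------------------------------

def write_tsv(panel: GenotypePanel, geno_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a line x SNP allele-count matrix as TSV plus SNP metadata."""
    geno_path = Path(geno_path)
    df = pd.DataFrame(
        panel.allele_counts,
        index=pd.Index(panel.line_ids, name="line_id"),
        columns=panel.snps["snp_id"],
    )
    df.to_csv(geno_path, sep="\t", na_rep="NA")
    if meta_path is None:
        meta_path = geno_path.with_suffix(".snps.tsv")
    panel.snps.to_csv(meta_path, sep="\t", index=False)


def read_tsv(geno_path: str | Path, meta_path: str | Path | None = None) -> GenotypePanel:
    """Read a panel written by :func:`write_tsv`."""
    geno_path = Path(geno_path)
    df = pd.read_csv(geno_path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise PanelError(f"no SNP columns in {geno_path}")
    if meta_path is None:
        meta_path = geno_path.with_suffix(".snps.tsv")
    meta_path = Path(meta_path)
    if meta_path.exists():
        snps = pd.read_csv(meta_path, sep="\t")
    else:
        snps = pd.DataFrame({
            "snp_id": df.columns,
            "chrom": "chr1",
            "pos": np.arange(1, df.shape[1] + 1),
            "maf": np.nan,
            "qual": np.nan,
            "call_rate": np.nan,
        })
    panel = GenotypePanel(
        line_ids=[str(x) for x in df.index],
        snps=snps,
        allele_counts=df.to_numpy(dtype=float),
    )
    if panel.snps["maf"].isna().any():
        panel.recompute_maf()
    if panel.snps["call_rate"].isna().any():
        obs = ~np.isnan(panel.allele_counts)
        panel.snps["call_rate"] = obs.mean(axis=0)
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF with homozygous diploid GTs.

    The minor-allele orientation is not preserved in the REF/ALT labels: the
    ALT allele simply carries the stored count, so 0 -> 0/0 and 2 -> 1/1,
    missing -> ./. — the reader re-orients to the minor allele anyway.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CR,Number=1,Type=Float,Description="Genotype call rate">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.line_ids) + "\n")
        gt_map = {0.0: "0/0", 2.0: "1/1"}
        for j, snp in panel.snps.iterrows():
            gts = [
                "./." if np.isnan(v) else gt_map[v]
                for v in panel.allele_counts[:, j]
            ]
            qual = "." if pd.isna(snp["qual"]) else f"{snp['qual']:.6g}"
            cr = snp["call_rate"]
            info = "." if pd.isna(cr) else f"CR={cr:.6g}"
            fh.write(
                f"{snp['chrom']}\t{int(snp['pos'])}\t{snp['snp_id']}\tA\tT\t"
                f"{qual}\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF of homozygous lines into a :class:`GenotypePanel`.

    Heterozygous-call and multi-allelic records are dropped (with a logged
    count); ALT-allele counts are re-oriented to the minor allele per site,
    ties at 0.5 keeping the reference orientation.  MAF and call rate are
    computed from the data.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, counts = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt (gts012=False default)
        gt = np.asarray(var.gt_types)
        if (gt == 1).any():
            n_dropped += 1
            continue
        col = np.full(len(line_ids), np.nan)
        col[gt == 0] = 0.0
        col[gt == 3] = 2.0
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            n_dropped += 1
            continue
        alt_freq = obs.sum() / (2.0 * obs.size)
        if alt_freq > 0.5:  # re-orient so counts count the minor allele
            col = np.where(np.isnan(col), np.nan, 2.0 - col)
        rows.append({
            "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
            "chrom": var.CHROM,
            "pos": var.POS,
            "maf": min(alt_freq, 1.0 - alt_freq),
            "qual": var.QUAL if var.QUAL is not None else np.nan,
            "call_rate": obs.size / len(line_ids),
        })
        counts.append(col)
    if n_dropped:
        logger.info("dropped %d heterozygous/multi-allelic/empty VCF records", n_dropped)
    if not rows:
        raise PanelError(f"no usable biallelic homozygous SNPs in {path}")
    return GenotypePanel(
        line_ids=line_ids,
        snps=pd.DataFrame(rows),
        allele_counts=np.column_stack(counts),
    )


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypePanel:
    """Dispatch reader: ``format`` is ``'vcf'`` or ``'tsv'``."""
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")
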