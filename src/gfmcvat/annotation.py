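"""SNP-to-gene and gene-to-GO feature maps.

Genes are plain 1-based inclusive intervals on a chromosome (the operational
stand-in for an open reading frame); a SNP belongs to a gene iff it lies on
the same chromosome with start <= pos <= end, and a GO term's SNP set is the
genome-ordered, de-duplicated union of its member genes' SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class FeatureMap:
    """SNP <-> gene and gene <-> GO membership structure.

    ``gene_to_snps`` maps gene id to the ordered panel SNP indices inside the
    gene interval; ``go_to_genes`` maps GO id to its member gene ids.  The
    derived ``go_to_snps`` is the union of member genes' SNP indices, kept in
    genome order with duplicates removed.
    """

    gene_intervals: pd.DataFrame  # gene_id, chrom, start, end (1-based inclusive)
    gene_to_snps: dict[str, np.ndarray]
    go_to_genes: dict[str, list[str]] = field(default_factory=dict)

    def go_to_snps(self, go_id: str) -> np.ndarray:
        genes = self.go_to_genes.get(go_id, [])
        if not genes:
            return np.array([], dtype=int)
        idx = np.concatenate(
            [self.gene_to_snps.get(g, np.array([], dtype=int)) for g in genes]
        )
        return np.unique(idx)  # sorted panel index == genome order

    def go_terms(self) -> list[str]:
        return list(self.go_to_genes)

    def genes_in_go(self, go_id: str) -> list[str]:
        return list(self.go_to_genes.get(go_id, []))


def map_snps_to_genes(panel: GenotypePanel, gene_intervals: pd.DataFrame) -> FeatureMap:
    """Assign every panel SNP to the gene intervals containing it.

    ``gene_intervals`` needs columns ``gene_id, chrom, start, end`` with
    1-based inclusive coordinates.  Overlapping genes each receive the shared
    SNPs.  Intervals on chromosomes absent from the panel are skipped with a
    warning.
    """
    known_chroms = set(panel.snps["chrom"].unique())
    gene_to_snps: dict[str, np.ndarray] = {}
    chrom_pos = {
        chrom: (grp.index.to_numpy(), grp["pos"].to_numpy())
        for chrom, grp in panel.snps.groupby("chrom", sort=False)
    }
    for row in gene_intervals.itertuples(index=False):
        if row.chrom not in known_chroms:
            logger.warning("gene %s on unknown chromosome %s — skipped", row.gene_id, row.chrom)
            continue
        idx, pos = chrom_pos[row.chrom]
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        gene_to_snps[row.gene_id] = idx[lo:hi].astype(int)
    return FeatureMap(
        gene_intervals=gene_intervals.reset_index(drop=True),
        gene_to_snps=gene_to_snps,
    )


def aggregate_genes_to_go(fmap: FeatureMap, go_table: pd.DataFrame) -> FeatureMap:
    """Populate GO-term membership from a (gene_id, go_id) table.

    GO terms whose member genes contribute zero panel SNPs are dropped with a
    log entry.  Row order of ``go_table`` does not affect the result: gene
    lists are sorted.
    """
    go_to_genes: dict[str, list[str]] = {}
    for go_id, grp in go_table.groupby("go_id", sort=True):
        genes = sorted(set(grp["gene_id"]))
        n_snps = sum(
            len(fmap.gene_to_snps.get(g, ())) for g in genes
        )
        if n_snps == 0:
            logger.info("GO term %s has no mapped SNPs — dropped", go_id)
            continue
        go_to_genes[go_id] = genes
    return FeatureMap(
        gene_intervals=fmap.gene_intervals,
        gene_to_snps=fmap.gene_to_snps,
        go_to_genes=go_to_genes,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_bed(gene_intervals: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED (0-based half-open on write)."""
    out = pd.DataFrame({
        "chrom": gene_intervals["chrom"],
        "start": gene_intervals["start"] - 1,
        "end": gene_intervals["end"],
        "name": gene_intervals["gene_id"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED gene intervals, converting to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return pd.DataFrame({
        "gene_id": df["name"].astype(str),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int) + 1,
        "end": df["end"].astype(int),
    })


def read_gff3(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene intervals from GFF3 (already 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
    )
    df = df[df["type"] == feature_type]

    def _gene_id(attrs: str) -> str:
        for part in attrs.split(";"):
            key, _, val = part.partition("=")
            if key.strip() in ("ID", "gene_id", "Name"):
                return val.strip()
        return attrs

    return pd.DataFrame({
        "gene_id": df["attributes"].map(_gene_id),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
    }).reset_index(drop=True)


def write_go_table(go_table: pd.DataFrame, path: str | Path) -> None:
    go_table[["gene_id", "go_id"]].to_csv(path, sep="\t", index=False)


def read_go_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "go_id"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"])
    return df[["gene_id", "go_id"]].astype(str)
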