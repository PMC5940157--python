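"""Synthetic inbred-panel data with a feature-enriched additive architecture.

The generator emulates the study design the analysis assumes: a panel of
~200 fully homozygous lines genotyped at biallelic SNPs (minor-allele counts
0/2) across six chromosome arms, genes tiled as non-overlapping intervals
with GO-term membership, and replicated phenotype records (default 23 per
line) with day/block/plate nuisance fixed effects.  Genetic signal is split
between SNPs inside one designated GO term (variance fraction sigma2_f) and
SNPs elsewhere in the genome (sigma2_r), with residual fraction sigma2_e;
the three fractions sum to one, so phenotypes are on a unit-variance scale.

Causal effects are drawn Gaussian and rescaled so the realized in-sample
component variances equal the configured fractions exactly, which removes
Monte-Carlo slack from parameter-recovery checks.  SNPs are independent by
default; an optional block-copying mode introduces within-block LD for
permutation-calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureMap, aggregate_genes_to_go, map_snps_to_genes, write_bed, write_go_table
from .grm import center_scale
from .panel import GenotypePanel, write_tsv, write_vcf

DEFAULT_CHROMS = ("2L", "2R", "3L", "3R", "4", "X")


class SimulationError(ValueError):
    pass


def _check_dist(spec: tuple, name: str) -> None:
    kind = spec[0]
    if kind == "fixed":
        vals = [spec[1]]
    elif kind == "uniform":
        vals = [spec[1], spec[2]]
        if spec[1] > spec[2]:
            raise SimulationError(f"{name}: uniform bounds out of order")
    else:
        raise SimulationError(f"{name}: unknown distribution kind {kind!r}")
    if name == "maf_spectrum" and any(not 0.0 < v <= 0.5 for v in vals):
        raise SimulationError(f"{name}: mass outside (0, 0.5]")


def _draw(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    if spec[0] == "fixed":
        return np.full(size, float(spec[1]))
    return rng.uniform(spec[1], spec[2], size=size)


@dataclass(frozen=True)
class Architecture:
    """Feature-enriched additive architecture as fractions of total variance.

    ``n_causal_f``/``n_causal_r`` of ``None`` make every SNP in the component
    causal (the infinitesimal architecture the GBLUP/GFBLUP covariance
    assumes); small counts give a sparse architecture.  ``causal_gene``
    restricts the feature-component causal SNPs to one gene, so that gene
    truly drives the term's signal.
    """

    feature_go: str | None = None  # None -> first simulated GO term
    sigma2_f: float = 0.3
    sigma2_r: float = 0.2
    sigma2_e: float = 0.5
    n_causal_f: int | None = None
    n_causal_r: int | None = None
    causal_gene: str | None = None

    def __post_init__(self) -> None:
        total = self.sigma2_f + self.sigma2_r + self.sigma2_e
        if abs(total - 1.0) > 1e-8:
            raise SimulationError("variance fractions must sum to 1")
        if min(self.sigma2_f, self.sigma2_r, self.sigma2_e) < 0:
            raise SimulationError("variance fractions must be nonnegative")
        if self.sigma2_f > 0 and self.n_causal_f is not None and self.n_causal_f < 1:
            raise SimulationError("sigma2_f > 0 needs at least one feature causal SNP")
        if self.sigma2_r > 0 and self.n_causal_r is not None and self.n_causal_r < 1:
            raise SimulationError("sigma2_r > 0 needs at least one remainder causal SNP")


@dataclass(frozen=True)
class SimulationConfig:
    n_lines: int = 200
    n_snps: int = 5000
    chrom_layout: tuple[tuple[str, int], ...] | None = None
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    n_genes: int = 300
    n_go_terms: int = 10
    genes_per_go: tuple = ("fixed", 0)  # 0 -> ceil(n_genes / n_go_terms)
    architecture: Architecture = field(default_factory=Architecture)
    replicates_per_line: int = 23
    n_days: int = 6
    n_blocks: int = 8
    n_plates: int = 12
    fixed_effect_sd: float = 0.5
    ld_block_size: int = 1  # 1 = independent SNPs; >1 copies founder blocks
    frac_low_quality: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for fieldname in ("n_lines", "n_snps", "n_genes", "n_go_terms",
                          "replicates_per_line", "n_days", "n_blocks", "n_plates"):
            if getattr(self, fieldname) < 1:
                raise SimulationError(f"{fieldname} must be >= 1")
        _check_dist(self.maf_spectrum, "maf_spectrum")
        _check_dist(self.genes_per_go, "genes_per_go")
        if self.chrom_layout is not None:
            if sum(n for _, n in self.chrom_layout) != self.n_snps:
                raise SimulationError("chrom_layout SNP counts must sum to n_snps")

    def layout(self) -> tuple[tuple[str, int], ...]:
        if self.chrom_layout is not None:
            return tuple(self.chrom_layout)
        base, extra = divmod(self.n_snps, len(DEFAULT_CHROMS))
        return tuple(
            (c, base + (1 if i < extra else 0))
            for i, c in enumerate(DEFAULT_CHROMS) if base + (1 if i < extra else 0) > 0
        )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype draw."""

    causal_snps: dict[str, np.ndarray]       # component -> panel SNP indices
    effects: dict[str, np.ndarray]           # component -> effects on the W scale
    g_by_component: dict[str, np.ndarray]    # component -> per-line genomic values
    g_total: np.ndarray
    realized_fractions: dict[str, float]
    fixed_effects: dict[str, np.ndarray]     # factor -> per-level values
    feature_go: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.causal_snps:
            for idx, eff in zip(self.causal_snps[comp], self.effects[comp]):
                rows.append({"component": comp, "snp_index": int(idx), "effect": eff})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw homozygous-line genotypes (0/2) with per-SNP metadata.

    Each SNP's population MAF comes from the configured spectrum; genotypes
    are re-oriented afterwards so the stored (empirical) MAF never exceeds
    0.5, ties at 0.5 keeping the sampled orientation.
    """
    rng = np.random.default_rng([config.seed, 0])
    layout = config.layout()
    p = _draw(config.maf_spectrum, config.n_snps, rng)

    if config.ld_block_size <= 1:
        a = 2.0 * (rng.random((config.n_lines, config.n_snps)) < p)
    else:
        a = np.empty((config.n_lines, config.n_snps))
        n_founders = 8
        for start in range(0, config.n_snps, config.ld_block_size):
            stop = min(start + config.ld_block_size, config.n_snps)
            founders = 2.0 * (rng.random((n_founders, stop - start)) < p[start:stop])
            pick = rng.integers(0, n_founders, size=config.n_lines)
            a[:, start:stop] = founders[pick]

    if config.missing_rate > 0:
        a[rng.random(a.shape) < config.missing_rate] = np.nan

    # minor-allele orientation on the realized sample
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(a, axis=0) / 2.0
    flip = freq > 0.5
    a[:, flip] = 2.0 - a[:, flip]

    qual = rng.uniform(550.0, 2000.0, size=config.n_snps)
    if config.frac_low_quality > 0:
        low = rng.random(config.n_snps) < config.frac_low_quality
        qual[low] = rng.uniform(100.0, 500.0, size=int(low.sum()))

    chroms, positions = [], []
    for chrom, n in layout:
        chroms.extend([chrom] * n)
        positions.extend(np.cumsum(rng.integers(50, 150, size=n)).tolist())
    snps = pd.DataFrame({
        "snp_id": [f"{c}_{pos}" for c, pos in zip(chroms, positions)],
        "chrom": chroms,
        "pos": positions,
        "maf": 0.0,
        "qual": qual,
        "call_rate": 1.0 - np.mean(np.isnan(a), axis=0),
    })
    panel = GenotypePanel(line_ids=[f"line_{i+1:03d}" for i in range(config.n_lines)],
                          snps=snps, allele_counts=a)
    panel.recompute_maf()
    return panel


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(panel: GenotypePanel, config: SimulationConfig) -> FeatureMap:
    """Tile non-overlapping gene intervals over the panel and deal genes into
    GO terms (every gene gets at least one term; gaps between genes leave
    some SNPs unannotated)."""
    if panel.n_snps == 0:
        raise SimulationError("empty panel")
    rng = np.random.default_rng([config.seed, 1])

    chrom_sizes = panel.snps.groupby("chrom", sort=False).size()
    total = int(chrom_sizes.sum())
    if total < 2 * config.n_genes:
        raise SimulationError(
            f"n_genes={config.n_genes} too large for {total} SNP positions")

    # allot genes to chromosomes proportionally to their SNP counts
    alloc = np.maximum(1, np.floor(chrom_sizes.to_numpy() / total * config.n_genes)).astype(int)
    while alloc.sum() > config.n_genes:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < config.n_genes:
        alloc[np.argmax(chrom_sizes.to_numpy() / np.maximum(alloc, 1))] += 1

    rows = []
    gene_no = 0
    for (chrom, size), n_genes_c in zip(chrom_sizes.items(), alloc):
        if n_genes_c <= 0:
            continue
        pos = panel.snps.loc[panel.snps["chrom"] == chrom, "pos"].to_numpy()
        if size < 2 * n_genes_c:
            raise SimulationError(f"chromosome {chrom}: too few SNPs for {n_genes_c} genes")
        # alternate gene runs and gaps over the SNP order
        per = size // n_genes_c
        gene_len = max(1, per - max(1, per // 4))  # leave ~25% of SNPs intergenic
        for k in range(n_genes_c):
            start_i = k * per
            end_i = min(start_i + gene_len - 1, size - 1)
            gene_no += 1
            rows.append({
                "gene_id": f"gene_{gene_no:04d}",
                "chrom": chrom,
                "start": int(pos[start_i]),
                "end": int(pos[end_i]),
            })
    gene_intervals = pd.DataFrame(rows)
    fmap = map_snps_to_genes(panel, gene_intervals)

    # GO membership: per-term sizes from the configured distribution
    gene_ids = gene_intervals["gene_id"].tolist()
    default_size = -(-len(gene_ids) // config.n_go_terms)  # ceil
    spec = config.genes_per_go
    if spec == ("fixed", 0):
        spec = ("fixed", default_size)
    sizes = np.maximum(1, np.round(_draw(spec, config.n_go_terms, rng))).astype(int)
    pairs = []
    assigned: set[str] = set()
    for t, sz in enumerate(sizes, start=1):
        go_id = f"GO:{t:07d}"
        members = rng.choice(gene_ids, size=min(sz, len(gene_ids)), replace=False)
        pairs.extend((g, go_id) for g in members)
        assigned.update(members)
    leftovers = [g for g in gene_ids if g not in assigned]
    for i, g in enumerate(leftovers):  # every gene belongs to >= 1 term
        pairs.append((g, f"GO:{(i % config.n_go_terms) + 1:07d}"))
    go_table = pd.DataFrame(pairs, columns=["gene_id", "go_id"])
    return aggregate_genes_to_go(fmap, go_table)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(panel: GenotypePanel, fmap: FeatureMap,
                        config: SimulationConfig,
                        ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Replicated phenotype records with the configured architecture.

    Returns a record table (line_id, replicate, day, block, plate, value)
    and the :class:`SimulationTruth` holding causal SNPs, effects (on the
    centered/scaled genotype scale), per-line genomic values, and the drawn
    day/block/plate fixed effects.
    """
    arch = config.architecture
    rng = np.random.default_rng([config.seed, 2])
    feature_go = arch.feature_go or (fmap.go_terms()[0] if fmap.go_terms() else None)
    if feature_go is None or feature_go not in fmap.go_to_genes:
        raise SimulationError(f"architecture GO term {feature_go!r} not in the feature map")

    maf = panel.snps["maf"].to_numpy(dtype=float)
    usable = np.flatnonzero(maf * (1 - maf) > 0)
    feat_snps = np.intersect1d(fmap.go_to_snps(feature_go), usable)
    # with no feature enrichment the remainder effects are uniform genome-wide
    rest_snps = usable if arch.sigma2_f == 0 else np.setdiff1d(usable, feat_snps)
    feat_pool = feat_snps
    if arch.causal_gene is not None:
        gene_snps = fmap.gene_to_snps.get(arch.causal_gene)
        if gene_snps is None:
            raise SimulationError(f"causal gene {arch.causal_gene!r} not in the feature map")
        feat_pool = np.intersect1d(feat_snps, gene_snps)

    causal, effects, g_by = {}, {}, {}
    n = panel.n_lines
    for comp, frac, pool, k in (
        ("feature", arch.sigma2_f, feat_pool, arch.n_causal_f),
        ("remainder", arch.sigma2_r, rest_snps, arch.n_causal_r),
    ):
        if frac == 0.0:
            causal[comp] = np.array([], dtype=int)
            effects[comp] = np.array([])
            g_by[comp] = np.zeros(n)
            continue
        if len(pool) == 0:
            raise SimulationError(f"no candidate causal SNPs for the {comp} component")
        k = len(pool) if k is None else min(k, len(pool))
        idx = np.sort(rng.choice(pool, size=k, replace=False))
        W = center_scale(panel, idx).W
        s = rng.standard_normal(k)
        g = W @ s
        v = float(np.var(g, ddof=1))
        if v == 0.0:
            raise SimulationError(f"degenerate genomic component {comp}")
        scale = np.sqrt(frac / v)
        causal[comp] = idx
        effects[comp] = s * scale
        g_by[comp] = g * scale
    g_total = g_by["feature"] + g_by["remainder"]

    fixed = {
        "day": rng.normal(0.0, config.fixed_effect_sd, size=config.n_days),
        "block": rng.normal(0.0, config.fixed_effect_sd, size=config.n_blocks),
        "plate": rng.normal(0.0, config.fixed_effect_sd, size=config.n_plates),
    }
    n_rec = n * config.replicates_per_line
    day = rng.integers(0, config.n_days, size=n_rec)
    block = rng.integers(0, config.n_blocks, size=n_rec)
    plate = rng.integers(0, config.n_plates, size=n_rec)
    line_idx = np.repeat(np.arange(n), config.replicates_per_line)
    resid = rng.normal(0.0, np.sqrt(arch.sigma2_e), size=n_rec) if arch.sigma2_e > 0 else np.zeros(n_rec)
    value = (g_total[line_idx] + fixed["day"][day] + fixed["block"][block]
             + fixed["plate"][plate] + resid)
    pheno = pd.DataFrame({
        "line_id": np.asarray(panel.line_ids)[line_idx],
        "replicate": np.tile(np.arange(1, config.replicates_per_line + 1), n),
        "day": [f"d{v+1}" for v in day],
        "block": [f"b{v+1}" for v in block],
        "plate": [f"p{v+1}" for v in plate],
        "value": value,
    })
    tot = float(np.var(g_total, ddof=1)) + arch.sigma2_e
    truth = SimulationTruth(
        causal_snps=causal, effects=effects, g_by_component=g_by,
        g_total=g_total,
        realized_fractions={
            "feature": float(np.var(g_by["feature"], ddof=1)) / tot,
            "remainder": float(np.var(g_by["remainder"], ddof=1)) / tot,
            "residual": arch.sigma2_e / tot,
        },
        fixed_effects=fixed, feature_go=feature_go,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig):
    """Panel, feature map, phenotypes, and truth in one call."""
    panel = simulate_genotype_panel(config)
    fmap = simulate_annotation(panel, config)
    pheno, truth = simulate_phenotypes(panel, fmap, config)
    return panel, fmap, pheno, truth


def write_dataset(outdir: str | Path, panel: GenotypePanel, fmap: FeatureMap,
                  pheno: pd.DataFrame, truth: SimulationTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(panel, outdir / "genotypes.tsv")
    write_vcf(panel, outdir / "genotypes.vcf")
    write_bed(fmap.gene_intervals, outdir / "genes.bed")
    pairs = [(g, go) for go, genes in fmap.go_to_genes.items() for g in genes]
    write_go_table(pd.DataFrame(pairs, columns=["gene_id", "go_id"]), outdir / "go_map.tsv")
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    if truth is not None:
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
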