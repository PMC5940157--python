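"""End-to-end orchestration: simulate/load -> filter -> annotate -> fit ->
GO-term cross-validation scan -> gene-level CVAT -> marginal scan.

Every stage writes a self-describing TSV/CSV into the output directory and
the run manifest records seeds, versions, and row counts, so a rerun with the
same configuration reproduces every table bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import FeatureMap, aggregate_genes_to_go, map_snps_to_genes, read_bed, read_gff3, read_go_table
from .cvat import circular_permutation_test
from .grm import center_scale, compute_grm
from .gwas import genomewide_threshold, marginal_scan
from .panel import GenotypePanel, SNPFilterSpec, filter_snps, read_genotypes
from .prediction import CVScheme, go_term_scan
from .simulate import Architecture, SimulationConfig, simulate_annotation, simulate_genotype_panel, simulate_phenotypes, write_dataset
from .varcomp import adjust_phenotypes, fit_genomic_model, fit_line_model, heritability_report, write_fit_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config drives the whole pipeline: either a simulation block or a
    set of input paths, plus filter/CV/CVAT settings."""

    outdir: Path
    simulation: SimulationConfig | None = None
    inputs: dict | None = None  # genotypes, format, genes, go_map, phenotypes
    filter_spec: SNPFilterSpec = field(default_factory=SNPFilterSpec)
    cv: CVScheme = field(default_factory=CVScheme)
    cvat_n_perm: int = 10_000
    cvat_seed: int = 0
    cvat_all_passing: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be supplied")
        self.outdir = Path(self.outdir)


def config_from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulation" in raw:
        sim_raw = dict(raw["simulation"])
        arch = sim_raw.pop("architecture", None)
        if arch is not None:
            sim_raw["architecture"] = Architecture(**arch)
        for key in ("maf_spectrum", "genes_per_go"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "chrom_layout" in sim_raw and sim_raw["chrom_layout"] is not None:
            sim_raw["chrom_layout"] = tuple((c, int(n)) for c, n in sim_raw["chrom_layout"])
        sim = SimulationConfig(**sim_raw)
    return RunConfig(
        outdir=raw.get("outdir", "gfmcvat_run"),
        simulation=sim,
        inputs=raw.get("inputs"),
        filter_spec=SNPFilterSpec(**raw.get("filter", {})),
        cv=CVScheme(**raw.get("cv", {})),
        cvat_n_perm=raw.get("cvat", {}).get("n_perm", 10_000),
        cvat_seed=raw.get("cvat", {}).get("seed", 0),
        cvat_all_passing=raw.get("cvat", {}).get("all_passing", False),
        alpha=raw.get("alpha", 0.05),
    )


def _load_inputs(inputs: dict):
    panel = read_genotypes(inputs["genotypes"], inputs.get("format", "vcf"))
    genes_path = Path(inputs["genes"])
    if genes_path.suffix.lower() in (".gff", ".gff3"):
        gene_intervals = read_gff3(genes_path)
    else:
        gene_intervals = read_bed(genes_path)
    go_table = read_go_table(inputs["go_map"])
    pheno = pd.read_csv(inputs["phenotypes"])
    return panel, gene_intervals, go_table, pheno


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing outputs under ``config.outdir``.

    Returns the manifest dict.  Any stage failure propagates with the stage
    name attached.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}}
    stage = "setup"
    try:
        # --- data --------------------------------------------------------
        stage = "data"
        if config.simulation is not None:
            sim = config.simulation
            panel = simulate_genotype_panel(sim)
            sim_fmap = simulate_annotation(panel, sim)
            pheno, truth = simulate_phenotypes(panel, sim_fmap, sim)
            write_dataset(out / "simulated", panel, sim_fmap, pheno, truth)
            gene_intervals = sim_fmap.gene_intervals
            go_pairs = [(g, go) for go, genes in sim_fmap.go_to_genes.items()
                        for g in genes]
            go_table = pd.DataFrame(go_pairs, columns=["gene_id", "go_id"])
            manifest["seed"] = sim.seed
        else:
            panel, gene_intervals, go_table, pheno = _load_inputs(config.inputs)
        manifest["stages"]["data"] = {"n_lines": panel.n_lines, "n_snps": panel.n_snps,
                                      "n_records": len(pheno)}

        # --- filter ------------------------------------------------------
        stage = "filter"
        panel_f, filt_report = filter_snps(panel, config.filter_spec)
        manifest["stages"]["filter"] = filt_report
        panel_f.snps.to_csv(out / "snps_filtered.tsv", sep="\t", index=False)

        # --- annotate (on the filtered panel) ---------------------------
        stage = "annotate"
        fmap = aggregate_genes_to_go(map_snps_to_genes(panel_f, gene_intervals), go_table)
        n_genic = sum(len(v) > 0 for v in fmap.gene_to_snps.values())
        manifest["stages"]["annotate"] = {"n_genes": len(fmap.gene_to_snps),
                                          "n_genes_with_snps": n_genic,
                                          "n_go_terms": len(fmap.go_to_genes)}
        pd.DataFrame(
            [(go, g) for go, genes in fmap.go_to_genes.items() for g in genes],
            columns=["go_id", "gene_id"],
        ).to_csv(out / "feature_map.tsv", sep="\t", index=False)

        # --- variance components and heritability -----------------------
        stage = "fit"
        Wm = center_scale(panel_f)
        g_total = compute_grm(Wm)
        n_bar = pheno.groupby("line_id").size().mean()
        line_fit = fit_line_model(pheno)
        model1 = fit_genomic_model(
            pheno, [g_total],
            factors=tuple(f for f in ("day", "block", "plate") if f in pheno.columns),
        )
        write_fit_summary(line_fit, out / "heritability_line_model.tsv", n_bar)
        write_fit_summary(model1, out / "heritability_gblup.tsv", n_bar)
        manifest["stages"]["fit"] = {
            "n_bar": float(n_bar),
            "H2_individual": heritability_report(line_fit).H2_individual,
            "h2_gblup": heritability_report(model1).h2_gblup,
        }
        ytilde = adjust_phenotypes(model1, pheno)
        ytilde.to_csv(out / "adjusted_phenotypes.csv", index=False)

        # --- GO-term cross-validation scan -------------------------------
        stage = "cv"
        scan = go_term_scan(ytilde, Wm, fmap, config.cv)
        table = scan.table.sort_values("mean_PA", ascending=False).reset_index(drop=True)
        table.to_csv(out / "go_comparison.tsv", sep="\t", index=False,
                     float_format="%.6g")
        manifest["stages"]["cv"] = {
            "null_mean_PA": scan.null_cv.mean_pa, "null_SE": scan.null_cv.se_pa,
            "n_terms": len(table),
            "n_fdr_passing": int((table["FDR_p"] < config.alpha).sum()),
        }

        # --- CVAT on the predictive term(s) ------------------------------
        stage = "cvat"
        passing = table[table["FDR_p"] < config.alpha]
        targets = (passing["go_id"].tolist() if config.cvat_all_passing
                   else passing["go_id"].tolist()[:1])
        cvat_rows = []
        for go_id in targets:
            snps = fmap.go_to_snps(go_id)
            W_go = center_scale(panel_f, snps)
            from .grm import partition_grm
            gf, gr = partition_grm(Wm, snps)
            fit3 = fit_genomic_model(ytilde, [gf, gr], check_psd=False)
            g_go = fit3.g_by_component["feature"]
            res = circular_permutation_test(W_go, g_go, fmap, go_id,
                                            n_perm=config.cvat_n_perm,
                                            seed=config.cvat_seed)
            tab = res.table.copy()
            tab.insert(0, "go_id", go_id)
            cvat_rows.append(tab)
        cvat_table = (pd.concat(cvat_rows, ignore_index=True) if cvat_rows
                      else pd.DataFrame(columns=["go_id", "gene_id", "n_snps",
                                                 "T_obs", "p", "rank",
                                                 "minus_log10_p"]))
        if not cvat_rows:
            logger.info("no GO term passed FDR < %g — CVAT stage skipped", config.alpha)
        cvat_table.to_csv(out / "cvat_ranking.tsv", sep="\t", index=False,
                          float_format="%.6g")
        manifest["stages"]["cvat"] = {"n_terms": len(targets),
                                      "n_genes": len(cvat_table)}

        # --- marginal scan ------------------------------------------------
        stage = "gwas"
        scan2 = marginal_scan(model1.g_total, panel_f)
        gwas_alpha = config.alpha if 0.0 < config.alpha < 1.0 else 0.05
        thr = genomewide_threshold(scan2.n_tested, gwas_alpha)
        scan2.table.to_csv(out / "marginal_scan.tsv", sep="\t", index=False,
                           float_format="%.6g")
        manifest["stages"]["gwas"] = {
            "n_tested": scan2.n_tested,
            "bonferroni_threshold": thr,
            "n_significant": int((scan2.table["p"] < thr).sum()),
        }

        stage = "manifest"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return manifest
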