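"""Genomic prediction of held-out lines and the GO-term cross-validation scan.

Held-out (validation) line values are predicted from the training records as

    g^_v = K_{v,t} Z_t' V_t^{-1} (y~_t - mu^_t),

with K = G sigma_g^2 for GBLUP and K = G_f sigma_f^2 + G_r sigma_r^2 for
GFBLUP, and V_t = Z_t K_{t,t} Z_t' + I sigma_e^2 over the training records.
Predictive ability (PA) is the Pearson correlation between validation-line
means of the adjusted phenotypes and the predicted genomic values; feature
models are compared with the all-SNP null by a one-sided Welch t-test over
paired cross-validation splits, with Benjamini-Hochberg FDR control across
GO terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import FeatureMap
from .grm import GRM, ScaledGenotypes, compute_grm, partition_grm
from .varcomp import VarianceEstimate, fit_genomic_model, heritability_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVScheme:
    """Repeated random-subdivision cross-validation masking whole lines."""

    validation_fraction: float = 0.10
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats")

    def splits(self, line_ids: list[str]) -> list[list[str]]:
        """Validation line sets per repeat; depends only on the scheme and the
        line list, so every model compared under one scheme shares splits."""
        rng = np.random.default_rng(self.seed)
        n_val = math.ceil(self.validation_fraction * len(line_ids))
        return [
            sorted(rng.choice(line_ids, size=n_val, replace=False))
            for _ in range(self.n_repeats)
        ]


@dataclass
class CVResult:
    """Per-repeat predictive abilities for one model."""

    pa: np.ndarray
    model: str
    validation_sets: list[list[str]] = field(repr=False, default_factory=list)

    @property
    def mean_pa(self) -> float:
        return float(np.mean(self.pa))

    @property
    def se_pa(self) -> float:
        return float(np.std(self.pa, ddof=1) / np.sqrt(len(self.pa)))


def predict_validation(train_fit: VarianceEstimate, grms: list[GRM],
                       ytilde_train: pd.DataFrame, validation_lines: list[str],
                       ) -> pd.Series:
    """Predicted genomic values for validation lines from a training fit.

    Variance components and the GLS intercept mu^_t come from ``train_fit``
    (training data only); the cross-block rows K_{v,t} of the relationship
    matrices carry the information from training to validation lines.
    """
    train_lines = train_fit.line_ids
    all_ids = grms[0].line_ids
    overlap = set(validation_lines) & set(train_lines)
    if overlap:
        raise ValueError(f"validation lines present in training records: {sorted(overlap)[:5]}")
    t_sel = np.array([all_ids.index(l) for l in train_lines])
    v_sel = np.array([all_ids.index(l) for l in validation_lines])

    comp_names = [k for k in train_fit.components if k != "residual"]
    sig_e = train_fit.components["residual"]
    K_tt = np.zeros((len(t_sel), len(t_sel)))
    K_vt = np.zeros((len(v_sel), len(t_sel)))
    for name, grm in zip(comp_names, grms):
        sig = train_fit.components[name]
        K_tt += sig * grm.G[np.ix_(t_sel, t_sel)]
        K_vt += sig * grm.G[np.ix_(v_sel, t_sel)]

    rec_line = train_fit.record_lines
    y = ytilde_train["value"].to_numpy(dtype=float)
    mu_t = float(train_fit.beta.get("intercept", 0.0))
    resid = y - mu_t
    # V_t^-1 resid via Woodbury at the line level
    q = len(t_sel)
    D = np.bincount(rec_line, minlength=q).astype(float)
    A = sig_e * np.eye(q) + D[:, None] * K_tt
    B = K_tt @ np.linalg.inv(A)
    Zt_r = np.bincount(rec_line, weights=resid, minlength=q)
    vinv_r = (resid - (B @ Zt_r)[rec_line]) / sig_e
    g_v = K_vt @ np.bincount(rec_line, weights=vinv_r, minlength=q)
    return pd.Series(g_v, index=validation_lines, name="g_hat")


def cross_validate(ytilde: pd.DataFrame, grms: list[GRM], scheme: CVScheme,
                   model: str | None = None) -> CVResult:
    """Repeated 90/10 (by default) cross-validation of a genomic model.

    Each repeat masks a random set of whole lines, refits the variance
    components on the remaining records, predicts the masked lines, and
    scores the Pearson correlation between their adjusted-phenotype line
    means and the predictions.
    """
    line_ids = [l for l in grms[0].line_ids
                if l in set(ytilde["line_id"].astype(str))]
    if len(line_ids) < 20:
        raise ValueError("cross-validation needs at least 20 lines")
    if model is None:
        model = "gblup" if len(grms) == 1 else "gfblup"
    line_means = ytilde.groupby(ytilde["line_id"].astype(str))["value"].mean()

    pas = []
    val_sets = scheme.splits(line_ids)
    for val_lines in val_sets:
        if len(val_lines) < 3:
            logger.warning("validation set smaller than 3 lines — repeat skipped")
            continue
        mask = ytilde["line_id"].astype(str).isin(val_lines)
        train = ytilde[~mask]
        fit = fit_genomic_model(train, grms, check_psd=False)
        g_v = predict_validation(fit, grms, train, val_lines)
        obs = line_means.loc[val_lines].to_numpy()
        pa = float(np.corrcoef(obs, g_v.to_numpy())[0, 1])
        pas.append(pa)
    return CVResult(pa=np.array(pas), model=model, validation_sets=val_sets)


def compare_models(feature_cv: CVResult, null_cv: CVResult) -> float:
    """One-sided Welch t-test that the feature model's mean PA exceeds the
    null model's, with Welch-Satterthwaite degrees of freedom."""
    a, b = feature_cv.pa, null_cv.pa
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty cross-validation result")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: no sampling variability; decide on the means alone
        if np.mean(a) > np.mean(b):
            return 0.0
        return 1.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_percent_heritability(mean_pa: float, h2_line_means: float) -> float:
    """Percent of line-mean heritability the model accounts for: the maximum
    attainable line-mean heritability from a predictor with correlation PA is
    PA^2, so the share is PA^2 / H2 (in percent)."""
    if not (0.0 <= mean_pa <= 1.0 and 0.0 < h2_line_means <= 1.0):
        raise ValueError("inputs must be in [0, 1] with positive heritability")
    return 100.0 * mean_pa ** 2 / h2_line_means


@dataclass
class GOComparison:
    """Per-GO-term scan results shaped like a predictive-ability table."""

    table: pd.DataFrame  # go_id, n_genes, n_snps, mean_PA, SE, p, FDR_p, h2_f
    null_cv: CVResult
    feature_cvs: dict[str, CVResult] = field(repr=False, default_factory=dict)


def go_term_scan(ytilde: pd.DataFrame, Wm: ScaledGenotypes, fmap: FeatureMap,
                 scheme: CVScheme, go_terms: list[str] | None = None,
                 min_snps: int = 2) -> GOComparison:
    """Cross-validate a GFBLUP model for every GO term against the GBLUP null.

    Splits are shared across all terms and the null (common random numbers),
    so each Welch comparison is paired on the same subdivisions.  ``h2_f``
    per term comes from a single full-data GFBLUP fit.
    """
    if go_terms is None:
        go_terms = fmap.go_terms()
    g_total = compute_grm(Wm)
    null_cv = cross_validate(ytilde, [g_total], scheme, model="gblup")
    logger.info("GBLUP null: mean PA %.3f +/- %.3f", null_cv.mean_pa, null_cv.se_pa)

    rows, feature_cvs = [], {}
    for go_id in go_terms:
        snps = fmap.go_to_snps(go_id)
        usable = snps[np.isin(snps, Wm.snp_index)]
        if len(usable) < min_snps or len(usable) >= Wm.m:
            logger.warning("GO term %s has %d usable SNPs — skipped", go_id, len(usable))
            continue
        gf, gr = partition_grm(Wm, usable)
        cv = cross_validate(ytilde, [gf, gr], scheme, model=f"gfblup:{go_id}")
        full_fit = fit_genomic_model(ytilde, [gf, gr], check_psd=False)
        h2f = heritability_report(full_fit).h2_f
        rows.append({
            "go_id": go_id,
            "n_genes": len(fmap.genes_in_go(go_id)),
            "n_snps": len(usable),
            "mean_PA": cv.mean_pa,
            "SE": cv.se_pa,
            "p": compare_models(cv, null_cv),
        })
        rows[-1]["h2_f"] = h2f
        feature_cvs[go_id] = cv
    table = pd.DataFrame(rows, columns=["go_id", "n_genes", "n_snps", "mean_PA",
                                        "SE", "p", "h2_f"])
    if len(table):
        table["FDR_p"] = fdr_adjust(table["p"].to_numpy())
    else:
        table["FDR_p"] = pd.Series(dtype=float)
    table = table[["go_id", "n_genes", "n_snps", "mean_PA", "SE", "p", "FDR_p", "h2_f"]]
    return GOComparison(table=table, null_cv=null_cv, feature_cvs=feature_cvs)
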