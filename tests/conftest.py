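"""Shared fixtures and independent numerical oracles for the test suite.

The oracles here deliberately avoid the package's fast solvers: the REML
oracle builds the dense record-level covariance matrix and maximizes the
restricted likelihood numerically, and the prediction oracle solves the
dense GLS system directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import gfmcvat as gv


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def dense_restricted_loglik(theta, y, X, rec_line, Ks):
    """Constant-free restricted log-likelihood from the dense N x N V."""
    n = len(y)
    q = max(rec_line) + 1
    Z = np.zeros((n, q))
    Z[np.arange(n), rec_line] = 1.0
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * (Z @ K @ Z.T)
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    sign_c, logdet_C = np.linalg.slogdet(C)
    if sign_c <= 0:
        return -np.inf
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    Py = Vinv @ (y - X @ beta)
    return -0.5 * (logdet_V + logdet_C + float(y @ Py))


def brute_force_reml(y, X, rec_line, Ks, n_starts: int = 6, seed: int = 0):
    """Numerically maximize the dense restricted likelihood; returns
    (best components, best log-likelihood)."""
    rng = np.random.default_rng(seed)
    var_y = float(np.var(y, ddof=1))
    n_comp = len(Ks) + 1

    def neg(log_theta):
        return -dense_restricted_loglik(np.exp(log_theta), y, X, rec_line, Ks)

    best = (None, -np.inf)
    starts = [np.full(n_comp, var_y / n_comp)]
    starts += [var_y * rng.uniform(0.05, 1.0, size=n_comp) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = scipy.optimize.minimize(neg, np.log(x0), method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12,
                                               "maxiter": 5000})
        if -res.fun > best[1]:
            best = (np.exp(res.x), -res.fun)
    return best


def dense_gls_prediction(train_fit, grms, ytilde_train, validation_lines):
    """Validation-line genomic values from the dense mixed-model solve."""
    all_ids = grms[0].line_ids
    t_sel = np.array([all_ids.index(l) for l in train_fit.line_ids])
    v_sel = np.array([all_ids.index(l) for l in validation_lines])
    comp_names = [k for k in train_fit.components if k != "residual"]
    K_tt = sum(train_fit.components[c] * g.G[np.ix_(t_sel, t_sel)]
               for c, g in zip(comp_names, grms))
    K_vt = sum(train_fit.components[c] * g.G[np.ix_(v_sel, t_sel)]
               for c, g in zip(comp_names, grms))
    n = len(ytilde_train)
    Z = np.zeros((n, len(t_sel)))
    Z[np.arange(n), train_fit.record_lines] = 1.0
    V = Z @ K_tt @ Z.T + train_fit.components["residual"] * np.eye(n)
    resid = ytilde_train["value"].to_numpy() - float(train_fit.beta.get("intercept", 0.0))
    return K_vt @ Z.T @ np.linalg.solve(V, resid)


def refilter(panel, fmap):
    """Filter a panel and rebuild its feature map on the filtered indices."""
    panel_f, report = gv.filter_snps(panel)
    go_pairs = pd.DataFrame(
        [(g, go) for go, genes in fmap.go_to_genes.items() for g in genes],
        columns=["gene_id", "go_id"],
    )
    fmap_f = gv.aggregate_genes_to_go(
        gv.map_snps_to_genes(panel_f, fmap.gene_intervals), go_pairs)
    return panel_f, fmap_f, report


def toy_panel(mafs, quals=None, call_rates=None, n_lines: int = 10):
    """Hand-built panel whose metadata carries the given per-SNP values."""
    m = len(mafs)
    rng = np.random.default_rng(42)
    a = 2.0 * (rng.random((n_lines, m)) < 0.5)
    snps = pd.DataFrame({
        "snp_id": [f"s{j+1}" for j in range(m)],
        "chrom": "chr1",
        "pos": np.arange(1, m + 1) * 100,
        "maf": mafs,
        "qual": quals if quals is not None else [600.0] * m,
        "call_rate": call_rates if call_rates is not None else [1.0] * m,
    })
    return gv.GenotypePanel(
        line_ids=[f"L{i+1}" for i in range(n_lines)], snps=snps, allele_counts=a)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_sim():
    """One moderate simulated dataset reused across read-only tests."""
    cfg = gv.SimulationConfig(n_lines=60, n_snps=600, replicates_per_line=5,
                              n_genes=60, n_go_terms=4, seed=7)
    panel, fmap, pheno, truth = gv.simulate_dataset(cfg)
    panel_f, fmap_f, report = refilter(panel, fmap)
    Wm = gv.center_scale(panel_f)
    G = gv.compute_grm(Wm)
    return {
        "config": cfg, "panel": panel, "fmap": fmap, "pheno": pheno,
        "truth": truth, "panel_f": panel_f, "fmap_f": fmap_f,
        "filter_report": report, "Wm": Wm, "G": G,
    }


@pytest.fixture(scope="session")
def tiny_pheno():
    """Small unbalanced repeated-records table for exact-oracle REML tests."""
    rng = np.random.default_rng(11)
    rows = []
    for i, reps in enumerate([2, 3, 2, 3, 2]):
        for j in range(reps):
            rows.append({
                "line_id": f"L{i+1}", "replicate": j + 1,
                "day": f"d{(i + j) % 2 + 1}", "block": f"b{j % 2 + 1}",
                "plate": f"p{(i + 2 * j) % 2 + 1}",
                "value": float(rng.normal(loc=i * 0.5, scale=1.0)),
            })
    return pd.DataFrame(rows)
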