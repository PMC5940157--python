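"""Held-out prediction, cross-validation, Welch comparison, FDR, ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gfmcvat as gv

from conftest import dense_gls_prediction, refilter


def _one_rep_pheno(line_ids, values):
    return pd.DataFrame({"line_id": line_ids, "value": values})


def _toy_grm(n, seed=0, label="total"):
    rng = np.random.default_rng(seed)
    L = rng.normal(size=(n, 2 * n))
    G = L @ L.T / (2 * n)
    return gv.GRM(G=G, m=2 * n, line_ids=[f"L{i}" for i in range(n)], label=label)


class TestPredictValidation:
    def test_matches_dense_mme_solve(self):
        grm = _toy_grm(6, seed=1)
        rng = np.random.default_rng(2)
        train_lines = grm.line_ids[:4]
        ytrain = _one_rep_pheno(train_lines, rng.normal(size=4))
        fit = gv.fit_genomic_model(ytrain, [grm])
        pred = gv.predict_validation(fit, [grm], ytrain, grm.line_ids[4:])
        oracle = dense_gls_prediction(fit, [grm], ytrain, grm.line_ids[4:])
        np.testing.assert_allclose(pred.to_numpy(), oracle, atol=1e-8)

    def test_two_component_matches_dense_solve(self):
        gf, gr = _toy_grm(8, seed=3, label="feature"), _toy_grm(8, seed=4, label="remainder")
        gr.line_ids = gf.line_ids
        rng = np.random.default_rng(5)
        train = _one_rep_pheno(gf.line_ids[:6], rng.normal(size=6))
        # repeated records exercise the Z expansion
        train = pd.concat([train, train.assign(value=train["value"] + rng.normal(size=6))],
                          ignore_index=True)
        fit = gv.fit_genomic_model(train, [gf, gr])
        pred = gv.predict_validation(fit, [gf, gr], train, gf.line_ids[6:])
        oracle = dense_gls_prediction(fit, [gf, gr], train, gf.line_ids[6:])
        np.testing.assert_allclose(pred.to_numpy(), oracle, atol=1e-8)

    def test_zero_genomic_variance_predicts_zero(self):
        grm = _toy_grm(5, seed=6)
        fit = gv.VarianceEstimate(
            components={"genomic": 0.0, "residual": 1.0},
            beta=pd.Series({"intercept": 0.3}),
            g_by_component={}, g_total=np.zeros(3), e_hat=np.zeros(3),
            fitted_fixed=np.zeros(3), line_ids=grm.line_ids[:3],
            record_lines=np.array([0, 1, 2]), loglik=0.0, n_iter=1, converged=True)
        ytrain = _one_rep_pheno(grm.line_ids[:3], [1.0, 2.0, 3.0])
        pred = gv.predict_validation(fit, [grm], ytrain, grm.line_ids[3:])
        np.testing.assert_allclose(pred.to_numpy(), 0.0, atol=1e-12)

    def test_validation_overlap_rejected(self):
        grm = _toy_grm(5, seed=7)
        ytrain = _one_rep_pheno(grm.line_ids[:4], [0.1, 0.2, 0.3, 0.4])
        fit = gv.fit_genomic_model(ytrain, [grm])
        with pytest.raises(ValueError, match="validation"):
            gv.predict_validation(fit, [grm], ytrain, grm.line_ids[3:])


class TestCrossValidate:
    def test_determinism_and_paired_splits(self, small_sim):
        pheno, G = small_sim["pheno"], small_sim["G"]
        est = gv.fit_genomic_model(pheno, [G], factors=("day", "block", "plate"))
        yt = gv.adjust_phenotypes(est, pheno)
        scheme = gv.CVScheme(n_repeats=2, seed=13)
        a = gv.cross_validate(yt, [G], scheme)
        b = gv.cross_validate(yt, [G], scheme)
        np.testing.assert_array_equal(a.pa, b.pa)
        assert a.validation_sets == b.validation_sets
        # a different model under the same scheme shares the splits
        snps = small_sim["fmap_f"].go_to_snps(small_sim["truth"].feature_go)
        gf, gr = gv.partition_grm(small_sim["Wm"], snps)
        c = gv.cross_validate(yt, [gf, gr], scheme)
        assert c.validation_sets == a.validation_sets

    def test_no_signal_gives_null_pa(self):
        arch = gv.Architecture(sigma2_f=0.0, sigma2_r=0.0, sigma2_e=1.0)
        cfg = gv.SimulationConfig(n_lines=60, n_snps=400, replicates_per_line=4,
                                  n_genes=30, n_go_terms=2, seed=21,
                                  fixed_effect_sd=0.0, architecture=arch)
        panel, fmap, pheno, _ = gv.simulate_dataset(cfg)
        panel_f, _ = gv.filter_snps(panel)
        G = gv.compute_grm(gv.center_scale(panel_f))
        est = gv.fit_genomic_model(pheno, [G])
        yt = gv.adjust_phenotypes(est, pheno)
        cv = gv.cross_validate(yt, [G], gv.CVScheme(n_repeats=10, seed=3))
        assert abs(cv.mean_pa) < 3 * max(cv.se_pa, 0.05)

    def test_true_feature_beats_random_feature_on_average(self):
        """Concentrating the model on the truly enriched SNP set predicts
        better than an equal-size random set, averaged over seeds."""
        diffs = []
        for seed in range(8):
            cfg = gv.SimulationConfig(n_lines=100, n_snps=1200,
                                      replicates_per_line=6, n_genes=80,
                                      n_go_terms=4, seed=seed)
            panel, fmap, pheno, truth = gv.simulate_dataset(cfg)
            panel_f, fmap_f, _ = refilter(panel, fmap)
            Wm = gv.center_scale(panel_f)
            G = gv.compute_grm(Wm)
            est = gv.fit_genomic_model(pheno, [G], factors=("day", "block", "plate"))
            yt = gv.adjust_phenotypes(est, pheno)
            true_snps = fmap_f.go_to_snps(truth.feature_go)
            rng = np.random.default_rng(seed)
            rand_snps = np.sort(rng.choice(Wm.snp_index, size=len(true_snps),
                                           replace=False))
            scheme = gv.CVScheme(n_repeats=6, seed=seed)
            cv_true = gv.cross_validate(yt, list(gv.partition_grm(Wm, true_snps)), scheme)
            cv_rand = gv.cross_validate(yt, list(gv.partition_grm(Wm, rand_snps)), scheme)
            diffs.append(cv_true.mean_pa - cv_rand.mean_pa)
        diffs = np.array(diffs)
        assert diffs.mean() > 0


class TestWelchAndFDR:
    def test_welch_matches_textbook_formula(self):
        a = np.array([0.3, 0.4, 0.35, 0.32])
        b = np.array([0.1, 0.12, 0.09, 0.11])
        pa = gv.CVResult(pa=a, model="f")
        pb = gv.CVResult(pa=b, model="n")
        p = gv.compare_models(pa, pb)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        import scipy.stats
        assert p == pytest.approx(float(scipy.stats.t.sf(t, df)), abs=1e-10)

    def test_identical_samples_give_half(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        p = gv.compare_models(gv.CVResult(pa=x, model="a"),
                              gv.CVResult(pa=x.copy(), model="b"))
        assert p == pytest.approx(0.5)

    def test_wrong_direction_exceeds_half(self):
        lo = gv.CVResult(pa=np.array([0.0, 0.05, 0.02]), model="f")
        hi = gv.CVResult(pa=np.array([0.3, 0.35, 0.32]), model="n")
        assert gv.compare_models(lo, hi) > 0.5

    def test_degenerate_zero_variance_convention(self):
        a = gv.CVResult(pa=np.array([0.2, 0.2]), model="a")
        b = gv.CVResult(pa=np.array([0.1, 0.1]), model="b")
        assert gv.compare_models(a, b) == 0.0
        assert gv.compare_models(b, a) == 1.0

    def test_bh_adjustment(self):
        assert gv.fdr_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(gv.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        adj = gv.fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_bh_rejects_invalid(self):
        with pytest.raises(ValueError):
            gv.fdr_adjust([0.5, 1.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bh_invariants_hold_for_any_input(self, pvals):
        p = np.asarray(pvals)
        adj = gv.fdr_adjust(p)
        assert adj.shape == p.shape
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # monotone in the input ordering by p
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestHeritabilityShare:
    @pytest.mark.parametrize("pa,h2,expect,nd", [
        (0.12, 0.94, 1.5, 1),
        (0.35, 0.94, 13.0, 0),
        (0.0, 0.94, 0.0, 1),
    ])
    def test_percent_of_line_mean_heritability(self, pa, h2, expect, nd):
        assert round(gv.summarize_percent_heritability(pa, h2), nd) == expect


def test_go_term_scan_table_shape(small_sim):
    pheno, G, Wm = small_sim["pheno"], small_sim["G"], small_sim["Wm"]
    est = gv.fit_genomic_model(pheno, [G], factors=("day", "block", "plate"))
    yt = gv.adjust_phenotypes(est, pheno)
    scan = gv.go_term_scan(yt, Wm, small_sim["fmap_f"],
                           gv.CVScheme(n_repeats=4, seed=2))
    tab = scan.table
    assert list(tab.columns) == ["go_id", "n_genes", "n_snps", "mean_PA", "SE",
                                 "p", "FDR_p", "h2_f"]
    assert len(tab) == len(small_sim["fmap_f"].go_terms())
    assert (tab["FDR_p"] >= tab["p"] - 1e-12).all()
    assert tab["h2_f"].between(0, 1).all()
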