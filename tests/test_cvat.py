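"""Gene-level covariance association test and its circular-permutation null."""

import numpy as np
import pandas as pd
import pytest

import gfmcvat as gv
from gfmcvat.cvat import CVATError


def _scaled(W, line_prefix="L"):
    W = np.asarray(W, dtype=float)
    return gv.ScaledGenotypes(W=W, snp_index=np.arange(W.shape[1]),
                              line_ids=[f"{line_prefix}{i}" for i in range(W.shape[0])])


def _fmap(gene_to_snps, go_to_genes):
    intervals = pd.DataFrame({
        "gene_id": list(gene_to_snps), "chrom": "chr1",
        "start": np.arange(len(gene_to_snps)) * 100 + 1,
        "end": np.arange(len(gene_to_snps)) * 100 + 50,
    })
    return gv.FeatureMap(
        gene_intervals=intervals,
        gene_to_snps={g: np.asarray(v, dtype=int) for g, v in gene_to_snps.items()},
        go_to_genes=go_to_genes)


class TestBacksolve:
    def test_scalar_least_squares(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(6, 1))
        g = rng.normal(size=6)
        s = gv.backsolve_snp_effects(_scaled(w), g)
        assert s.effects[0] == pytest.approx(float(w[:, 0] @ g) / float(w[:, 0] @ w[:, 0]))

    def test_zero_input_zero_effects(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(5, 3))
        s = gv.backsolve_snp_effects(_scaled(W), np.zeros(5))
        np.testing.assert_allclose(s.effects, 0.0, atol=1e-12)

    def test_fitted_values_match_lstsq(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(5, 8))  # more SNPs than lines: pseudo-inverse path
        g = rng.normal(size=5)
        s = gv.backsolve_snp_effects(_scaled(W), g)
        fitted = W @ s.effects
        oracle = W @ np.linalg.lstsq(W, g, rcond=None)[0]
        np.testing.assert_allclose(fitted, oracle, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(CVATError):
            gv.backsolve_snp_effects(_scaled(np.ones((4, 2))), np.zeros(3))


class TestGeneValues:
    def test_full_and_empty_subsets(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(6, 4))
        Wm = _scaled(W)
        g = rng.normal(size=6)
        s = gv.backsolve_snp_effects(Wm, g)
        fmap = _fmap({"all": [0, 1, 2, 3], "none": []}, {"GO:X": ["all", "none"]})
        np.testing.assert_allclose(gv.gene_genomic_values(Wm, s, fmap, "all"),
                                   W @ s.effects, atol=1e-12)
        np.testing.assert_allclose(gv.gene_genomic_values(Wm, s, fmap, "none"),
                                   0.0, atol=1e-12)

    def test_disjoint_cover_additivity(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(7, 6))
        Wm = _scaled(W)
        g = rng.normal(size=7)
        s = gv.backsolve_snp_effects(Wm, g)
        fmap = _fmap({"gA": [0, 1, 2], "gB": [3, 4, 5]}, {"GO:X": ["gA", "gB"]})
        total = (gv.gene_genomic_values(Wm, s, fmap, "gA")
                 + gv.gene_genomic_values(Wm, s, fmap, "gB"))
        np.testing.assert_allclose(total, W @ s.effects, atol=1e-10)
        # statistic additivity: sum of per-gene T equals |g_fitted|^2 here
        t_sum = (gv.cvat_statistic(W @ s.effects, gv.gene_genomic_values(Wm, s, fmap, "gA"))
                 + gv.cvat_statistic(W @ s.effects, gv.gene_genomic_values(Wm, s, fmap, "gB")))
        assert t_sum == pytest.approx(float((W @ s.effects) @ (W @ s.effects)), abs=1e-8)


class TestStatistic:
    def test_orthogonal_and_self(self):
        assert gv.cvat_statistic([1.0, 0.0], [0.0, 5.0]) == 0.0
        v = np.array([1.0, -2.0, 0.5])
        assert gv.cvat_statistic(v, v) == pytest.approx(float(v @ v))

    def test_hand_inner_product(self):
        assert gv.cvat_statistic([1.0, -1.0, 2.0], [0.5, 0.5, 1.0]) == pytest.approx(2.0)


class TestCircularPermutation:
    def test_identical_columns_give_p_one(self):
        """With every SNP column identical the per-SNP contributions are
        constant, so every rotation reproduces T_obs and p = 1."""
        rng = np.random.default_rng(5)
        w = rng.normal(size=6)
        W = np.tile(w[:, None], (1, 4))
        fmap = _fmap({"gA": [0, 1], "gB": [2, 3]}, {"GO:X": ["gA", "gB"]})
        res = gv.circular_permutation_test(_scaled(W), rng.normal(size=6),
                                           fmap, "GO:X", n_perm=50, seed=0)
        assert (res.table["p"] == 1.0).all()

    def test_matches_exhaustive_enumeration_oracle(self):
        """Sampled rotations with n_perm >= m-1 switch to exhaustive mode and
        reproduce an independent enumeration of all distinct rotations."""
        rng = np.random.default_rng(6)
        W = rng.normal(size=(8, 6))
        g = rng.normal(size=8)
        fmap = _fmap({"gA": [0, 1], "gB": [2, 3, 4], "gC": [5]},
                     {"GO:X": ["gA", "gB", "gC"]})
        res = gv.circular_permutation_test(_scaled(W), g, fmap, "GO:X",
                                           n_perm=999, seed=1)
        assert res.exhaustive and res.n_permutations == 5
        # independent oracle: explicit loops over offsets and gene members
        s = np.linalg.pinv(W) @ g
        t = (g @ W) * s
        m = 6
        genes = {"gA": [0, 1], "gB": [2, 3, 4], "gC": [5]}
        for gene, members in genes.items():
            t_obs = sum(t[i] for i in members)
            n_ge = sum(
                1 for k in range(1, m)
                if sum(t[(i + k) % m] for i in members) >= t_obs - 1e-12
            )
            expected_p = (1 + n_ge) / (1 + (m - 1))
            row = res.table[res.table["gene_id"] == gene].iloc[0]
            assert row["p"] == pytest.approx(expected_p, abs=1e-12)
            assert row["T_obs"] == pytest.approx(t_obs, abs=1e-10)

    def test_line_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        W = rng.normal(size=(10, 8))
        g = rng.normal(size=10)
        fmap = _fmap({"gA": [0, 1, 2], "gB": [4, 5, 6, 7]}, {"GO:X": ["gA", "gB"]})
        res1 = gv.circular_permutation_test(_scaled(W), g, fmap, "GO:X",
                                            n_perm=99, seed=3)
        perm = rng.permutation(10)
        res2 = gv.circular_permutation_test(_scaled(W[perm]), g[perm], fmap,
                                            "GO:X", n_perm=99, seed=3)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(8)
        fmap1 = _fmap({"gA": [0]}, {"GO:X": ["gA"]})
        with pytest.raises(CVATError, match="2 genes"):
            gv.circular_permutation_test(_scaled(rng.normal(size=(4, 3))),
                                         rng.normal(size=4), fmap1, "GO:X")
        fmap2 = _fmap({"gA": [0], "gB": [0]}, {"GO:X": ["gA", "gB"]})
        with pytest.raises(CVATError, match="2 SNPs"):
            gv.circular_permutation_test(_scaled(rng.normal(size=(4, 1))),
                                         rng.normal(size=4), fmap2, "GO:X")


class TestRanking:
    def _result(self, rows):
        return gv.CVATResult(table=pd.DataFrame(rows), go_id="GO:X",
                             n_permutations=99)

    def test_sorts_by_p(self):
        res = gv.rank_genes(self._result([
            {"gene_id": "a", "n_snps": 1, "T_obs": 1.0, "p": 0.20},
            {"gene_id": "b", "n_snps": 1, "T_obs": 0.5, "p": 0.01},
        ]))
        assert list(res.table["gene_id"]) == ["b", "a"]
        assert list(res.table["rank"]) == [1, 2]

    def test_ties_broken_by_statistic(self):
        res = gv.rank_genes(self._result([
            {"gene_id": "a", "n_snps": 1, "T_obs": 2.0, "p": 0.05},
            {"gene_id": "b", "n_snps": 1, "T_obs": 3.1, "p": 0.05},
        ]))
        assert list(res.table["gene_id"]) == ["b", "a"]

    def test_singleton(self):
        res = gv.rank_genes(self._result(
            [{"gene_id": "solo", "n_snps": 2, "T_obs": 0.1, "p": 0.5}]))
        assert list(res.table["rank"]) == [1]

    def test_empty_rejected(self):
        with pytest.raises(CVATError):
            gv.rank_genes(self._result([]))
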