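# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the design decisions behind `gfmcvat`, at the level of
detail a user would need to interpret (or distrust) its output.

## Mixed models and REML

All variance-component models share one covariance structure over the record
vector `y` (one record per line per replicate):

    V = Σ_k Z K_k Z' σ²_k + I σ²_e

where `Z` is the record→line incidence matrix and `K_k` is a line × line
covariance kernel — the identity for the line model (i.i.d. line effects), a
genomic relationship matrix `G = WW'/m` for GBLUP, and the pair
`(G_f, G_r)` for the two-component feature model. Fixed effects use an
explicit intercept plus reference-level (first level dropped) indicator
coding of the day/block/plate factors; a rank-deficient design is rejected
with the aliased columns named.

Estimation is average-information REML. Implementation details, since they
determine behavior on hard data sets:

* **Likelihood evaluation.** `V⁻¹` is never formed at record level. With
  `K = Σ_k σ²_k K_k` and `D = diag(records per line)`, the Woodbury identity
  gives `V⁻¹ = (I − Z B Z')/σ²_e` with `B = K(σ²_e I + DK)⁻¹`, and
  `log|V| = (N−q) log σ²_e + log|σ²_e I + DK|`, so every solve is q × q
  (q = number of lines). The restricted log-likelihood is the constant-free
  `−½(log|V| + log|X'V⁻¹X| + y'Py)`. The test suite checks this fast form
  against a dense N × N evaluation pointwise and against a dense numerical
  maximization at the optimum.
* **Initialization** at (phenotypic variance)/(number of components) for
  every component.
* **Updates.** The AI step `θ ← θ + AI⁻¹·score` is accepted only if it does
  not decrease the restricted likelihood; otherwise it is halved up to 10
  times, then a fixed-point update `σ²_k ← σ²_k · (y'P dV_k P y)/tr(P dV_k)`
  (which shares the REML fixed point and preserves positivity) is tried. If
  the likelihood is flat to tolerance in every direction tried, the fit is
  declared converged at the current point.
* **Convergence** when both |Δ restricted log-likelihood| < 1e-6 and the
  maximum relative parameter change < 1e-6; at most 200 iterations; a
  non-converged fit is returned flagged and downstream use warns.
* **Bounds.** Components are clamped at 1e-8 × phenotypic variance, so `V`
  stays positive definite and a component "estimated to zero" sits at the
  floor rather than going negative. No bending or diagonal loading is applied
  to `G` itself.
* **BLUPs** at the converged components: `û_k = σ²_k K_k Z'Py`,
  `ê = σ²_e Py`, giving the exact record-level decomposition
  `y = Xb̂ + Zĝ + ê`. The adjusted phenotypes are `ỹ = y − Xb̂`, identical to
  `ĝ_i + ê_ij` by this decomposition; the fixed-effect adjustment is done
  once on the full data before cross-validation resampling (so the folds
  share one `b̂` — a deliberate, mild leakage that keeps the replicate
  structure of the records intact, and is how such analyses are run in
  practice).

### The variance-component scale for homozygous 0/2 coding

With fully homozygous lines coded 0/2 and `w_i = (a_i − 2p_i)/√(2p_i(1−p_i))`,
the genotype variance at a locus is `4p(1−p)` — twice the Hardy–Weinberg
value the scale assumes — so `trace(G)/n = 2` exactly (at the empirical
frequencies). A model-scale component `σ²_k` therefore contributes
`σ²_k · mean(diag(K_k)) ≈ 2σ²_k` to the phenotypic variance. The package
reports heritability ratios in the conventional untransformed form
(`σ̂²_g/(σ̂²_g+σ̂²_e)` etc.), which consequently understates the among-line
fraction for such panels — the same behavior the field's standard pipelines
show on inbred panels; `GRM.mean_diagonal()` exposes the conversion factor,
and the recovery tests compare estimates to simulation truth on the
phenotypic scale.

## Prediction and the GO-term scan

Held-out prediction follows the cross-block form
`ĝ_v = K_{v,t} Z_t' V_t⁻¹(ỹ_t − μ̂_t)`, with `μ̂_t` the GLS intercept of the
training fit and repeated training records expanded through `Z_t`. The
cross-validation scheme masks whole lines (10% by default, 50 repeats by
default), refits the variance components on each training portion, and scores
PA as the Pearson correlation between validation-line means of `ỹ` and
`ĝ_v`. Splits are a function of the scheme's seed and the line list only, so
every model scored under one scheme is compared on identical splits (common
random numbers); the feature-vs-null comparison is a one-sided Welch t-test
over the paired per-repeat PA values, Benjamini–Hochberg-adjusted across
terms. The per-term `h²_f = σ̂²_f/(σ̂²_f+σ̂²_r)` in the scan table comes from
one full-data GFBLUP fit, not from the folds.

## CVAT and the circular permutation

Within a predictive GO term with SNP matrix `W_GO` (genome order), SNP
effects are backsolved as `ŝ = W_GO'(W_GO W_GO')⁺ ĝ_GO` using an
eigendecomposition pseudo-inverse with a relative eigenvalue cutoff of 1e-10;
`ĝ_GO` is the feature component of the full-data two-component fit. Each
gene's statistic is `T = ĝ_GO · ĝ_gene = Σ_{i∈gene} t_i` with per-SNP
contributions `t_i = (ĝ_GO·w_i) ŝ_i`.

The null distribution rotates the genome-ordered contribution vector `t` by a
uniform offset `k ∈ {1, …, m−1}`, keeping positions and gene memberships
fixed — equivalently, each permutation hands every gene a random same-size
*contiguous* set of SNP contributions, which preserves the serial correlation
of effects along the genome while destroying their association with gene
membership. This is the operative definition of the test: "does the gene
capture more of the term's genomic variance than a random SNP set of the same
size?". Rotating the raw effect vector `ŝ` alone (with `ĝ_GO` held fixed)
was considered and rejected: the observed statistic sums aligned products
`(ĝ_GO·w_i)ŝ_i`, which are square-like and positive, while misaligned
cross-products are near zero, so that variant rejects essentially every gene
and cannot be calibrated. With the contribution rotation the per-gene
rejection rate on exchangeable-null simulations is at the nominal level
(checked in the acceptance suite).

Details: p-values use add-one smoothing, `p = (1+#{T* ≥ T_obs})/(1+n_perm)`,
so p is never exactly 0, and ties count against significance; when
`n_perm ≥ m−1` all distinct rotations are enumerated exhaustively and the
sampled and exhaustive modes agree by construction. Genes are ranked by
ascending p, ties broken by descending `T_obs`, then gene id. Overlapping
genes each score their own `T` from the shared contributions; no
double-count correction is applied, matching the defining sum.

## The marginal scan

The single-marker baseline regresses the full-data GBLUP `ĝ` on each SNP's
allele counts and tests the slope (`t = r√(n−2)/√(1−r²)`, n−2 df). The
genome-wide threshold is Bonferroni `α/m` (recorded in the output so users
can re-threshold); no mixed-model correction is applied per test since the
response itself is already the kinship-informed `ĝ`.

## The synthetic-data generator

The generator emulates the study design the models assume, not any particular
organism's genome:

* **Genotypes.** `n_lines = 200` fully homozygous lines, `n_snps = 5000`
  biallelic SNPs spread over six chromosome arms (2L, 2R, 3L, 3R, 4, X), MAF
  drawn uniform on [0.05, 0.5] (the real panel's spectrum is not public
  knowledge; uniform is a neutral default), genotypes sampled independently
  per SNP and re-oriented so the stored empirical MAF ≤ 0.5. Per-SNP Phred
  quality and call rate are clean by default (everything passes the filters);
  `frac_low_quality` and `missing_rate` exercise the filter paths. An
  optional founder-block mode (`ld_block_size > 1`) copies haplotype blocks
  among lines to create within-block LD for permutation-stress experiments.
* **Annotation.** `n_genes = 300` non-overlapping gene intervals tiled over
  the chromosomes with ~25% of SNPs left intergenic; genes dealt into
  `n_go_terms = 10` GO terms (~30 genes each, overlaps allowed, every gene in
  at least one term).
* **Phenotypes.** One record per line per replicate (`23` replicates, the
  study design's mean), `value = g_f + g_r + day + block + plate + e`. The
  genetic architecture is *infinitesimal within components* by default: every
  SNP in the feature term (and every non-feature SNP) carries a Gaussian
  effect, matching the GBLUP/GFBLUP covariance assumption so that
  parameter-recovery checks are meaningful. Effects are rescaled so the
  realized in-sample variances of `g_f` and `g_r` equal the configured
  fractions exactly (removing Monte-Carlo slack); the residual is drawn at
  `σ²_e`. Defaults `σ²_f = 0.3, σ²_r = 0.2, σ²_e = 0.5` sum to one, so
  phenotypes are on a unit-variance scale. Day/block/plate effects are drawn
  once per level from N(0, 0.5²) (6 days, 8 blocks, 12 plates) and assigned
  to records at random. Sparse architectures (`n_causal_f/r`) and a
  gene-concentrated mode (`causal_gene`) support power and contrast
  experiments. With `σ²_f = 0` the causal pool is the whole genome — the
  exchangeable, no-enrichment null.
* **Determinism.** Each stage derives its generator from `(seed, stage)`, so
  identical configs are bit-reproducible stage by stage.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: linkage disequilibrium and population structure (by
default lines are unrelated, which makes all-SNP genomic prediction weak,
PA ≈ √(Nh²/(Nh²+m)); real panels have LD and relatedness), non-Gaussian and
non-additive effects, genotype–environment correlation, selection, and any
realistic gene-length or GO-size distribution.

## Problem sizes in the test suite

Simulation-backed tests run at reduced scale, chosen as the smallest sizes at
which the Monte-Carlo criteria are meaningful: parameter recovery at the full
200 lines × 23 replicates but 3000 SNPs over 20 seeds; power (true-term
GFBLUP vs GBLUP) at 150 lines, 2000 SNPs, 8 CV repeats, 20 seeds; calibration
at 120 lines over 10 seeds with 999 permutations; the weak-effect contrast
(no genome-wide-significant SNP, causal gene still ranked first) at 120
lines with the feature fraction lowered to 0.15 concentrated in one gene —
the regime where single markers are individually undetectable but jointly
detectable, which is the regime the set test exists for.

## Known limitations

* Standard errors of variance components and heritabilities are not computed.
* At most two genomic components; no dominance, epistasis or LD-weighted
  kinships.
* The GO-restricted rotation domain means genes covering a large fraction of
  a small term have little room to look atypical; terms need at least two
  genes and two SNPs.
* Mean imputation of missing genotypes (after filtering, before algebra)
  slightly shrinks relationships for low-call-rate SNPs.
* `h²_f` from a full-data fit can reach 1.0 when the feature and remainder
  kernels are nearly collinear — an overestimate, as two similar relationship
  matrices let one component absorb the other's variance.
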