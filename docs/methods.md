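# Methods

Statistical models, estimators and numerical conventions used in
`adiponet`, module by module. Defaults quoted here are the code defaults;
all are overridable.

## Network discovery (`adiponet.network`)

Expression is filtered (genes expressed, i.e. > 0, in at least 90% of
samples) and rank-based inverse-normal transformed per gene (Blom-style
offsets, average ranks for ties). The signed-magnitude adjacency is
`a_ij = |cor(x_i, x_j)|^beta`. The soft-threshold power is the first on the
candidate grid whose scale-free topology fit `R^2` — the squared
correlation of `log10 p(k)` on `log10 k` over connectivity-histogram bins —
reaches the cut (default 0.8); the default operating power is 6 for the
simulated data sizes, and `pick_power` reports the whole grid (R², slope,
mean/median/max connectivity) so the choice is auditable.

Topological overlap is

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with `k_i = sum_{u != i} a_iu`, TOM_ii = 1. Modules come from
average-linkage hierarchical clustering of `1 - TOM` with a static tree cut
at height 0.99 and a minimum module size of 20; smaller clusters are
labelled `unassigned`. The module eigengene is the first principal
component of the module's standardized expression, sign-oriented so that
the mean module kME (correlation of gene expression with the eigengene) is
non-negative. Module–trait association is the Pearson correlation of
eigengene and trait with a Bonferroni threshold of 0.05 divided by
(number of modules × number of traits).

## Module preservation (`adiponet.preservation`)

For each reference module, `Z_summary = (Z_density + Z_connectivity) / 2`.
The density statistic is the mean within-module adjacency in the test
data; the connectivity statistic is the correlation between reference and
test intramodular connectivity (kIM) over module genes. The null replaces
the module with random gene sets of the same size drawn from the test
data's genes outside the module, recomputing both statistics per
permutation (default 200); `Z = (obs - mean_null) / sd_null`. Sampling the
gene set (rather than permuting sample labels) keeps the null spread
positive even when reference and test data coincide. Interpretation bands:
`Z_summary < 2` no evidence, 2–10 weak-to-moderate, `> 10` strong
preservation.

## Gene-set enrichment and motifs (`adiponet.enrich`)

Over-representation uses the hypergeometric upper tail
(`fisher_enrichment`, equivalent to Fisher's exact test on the 2×2 table)
with a Haldane–Anscombe 0.5 continuity correction applied only to the
reported odds ratio when a cell is zero. Promoters are taken strand-aware
(default 2 kb upstream, 1 kb downstream of the TSS) and clipped at
position 0. PWMs are built from position frequency matrices
(JASPAR/MEME-minimal parsed via Biopython) with pseudocount 0.5 and
background 0.25; scanning scores both strands at a fraction-of-maximum
log-odds threshold and skips windows containing non-ACGT bases. Motif
enrichment compares the hit rate in target promoters against background
promoters with a one-sided binomial test; multiple motifs are controlled
with Benjamini–Hochberg (step-up with a running minimum, capped at 1).

## Partitioned heritability (`adiponet.ldsc`)

LD scores use the adjusted squared correlation
`r2_adj = r2 - (1 - r2)/(n - 2)` (unbiased, so individual terms can be
negative) summed over variants within a window (default ±1 Mb).
Per-category scores multiply `r2_adj` by the annotation indicator of the
tagged variant; annotations may overlap and always include the base
category. The regression is weighted least squares of GWAS chi-square on
`N * ell_c` for all categories with a free intercept and weights
`1 / max(ell_base, 1)`. Category heritability under overlap is
`h2_c = sum_j a_jc * tau-contribution_j`; enrichment is the category's
h² share divided by its variant share. Standard errors come from a
20-block delete-a-block jackknife over variants, applied directly to the
enrichment ratio. Note the intercept is only weakly identified when LD
scores barely vary across variants (e.g. unlinked SNPs); calibration
checks therefore examine the fitted mean chi-square rather than the raw
intercept.

## Polygenic scores (`adiponet.prs`)

- **Infinitesimal:** per LD block,
  `w = ((M/(N h2)) I + D)^{-1} beta_hat` with `D` the in-sample LD of the
  reference panel and `M` the genome-wide variant count. With identity LD
  this reduces to shrinkage by `1/(1 + M/(N h2))`.
- **Point-normal Gibbs:** spike-and-slab prior with inclusion probability
  `p` from a grid (1.0, 0.3, 0.1, 0.03, 0.01); posterior mean effect is the
  average of `p_j * E[beta_j | incl]` over post-burn-in sweeps (default
  100 burn-in, 200 kept), seeded and deterministic.
- **Clumping + thresholding:** greedy p-value-ordered clumping at
  `r^2 < 0.2` within blocks, then p-value cuts
  (0.5, 0.1, 0.05, 1e-5, 5e-8) giving nested variant sets.

Scoring aligns alleles between weights and panel (flipping the dosage sign
on ref/alt swaps, dropping mismatches). Evaluation reports score-quantile
odds ratios against the middle quantile with Woolf (log-OR) confidence
intervals, sex-stratified odds ratios compared by the Cochran–Mantel–
Haenszel test (statsmodels `StratifiedTable.test_null_odds`, no continuity
correction; for a single stratum this equals the score statistic
`(a - E)^2 / V` with `V = r1 r2 c1 c2 / (n^2 (n-1))`), and extreme-decile
disease prediction via logistic regression with a rank fallback when the
classes separate perfectly.

## TWAS (`adiponet.twas`)

The cis window is the closed interval gene start − 500 kb to gene end +
500 kb on the gene's chromosome. Genes pass to weight training only if
Haseman–Elston regression (off-diagonal GRM entries vs phenotype
cross-products) estimates cis h² with one-sided p < 0.01; the HE standard
error uses a 30-block delete-a-block jackknife over individuals (blocked,
not delete-one, purely for cost). Weights are the best of marginal top1
and ridge (optionally elastic net) by k-fold cross-validated R² on
standardized data. The association statistic is

    z_twas = w' z_gwas / sqrt(w' V w)

with `V` the cis LD matrix, two-sided normal p-value, and strict Bonferroni
significance `p < alpha / n_tests`.

## Fine-mapping (`adiponet.focus`)

Given TWAS z-scores at a locus and the predicted-expression correlation
matrix `Sigma`, each causal configuration `c` has marginal likelihood
`z | c ~ N(0, Sigma D_c Sigma + Sigma)` with
`D_c = diag(sigma2_alpha * c)` and independent Bernoulli(theta) priors
(default `theta = 1/m`). All `2^m` configurations are enumerated (guarded
at m ≤ 16, with an optional `k_max` cap on configuration size); gene PIPs
are sums of normalized posteriors over configurations containing the gene,
and the credible set is the smallest PIP-ordered set whose configurations
reach cumulative posterior ρ (default 0.9). `sigma2_alpha` defaults to the
plug-in `max(mean chi2 - 1, 1e-3)`; `Sigma` gets a 1e-8 ridge before
Cholesky. The prior log-probability is computed with explicit guards so
the theta ∈ {0, 1} boundaries do not produce `0 * (-inf)`.

## eQTL and differential expression (`adiponet.eqtl_de`)

Cis-eQTL scans use a ±1 Mb window, MAF ≥ 0.05 and a Hardy–Weinberg exact
filter; betas/SEs/p-values are vectorized OLS identical to per-pair
regression (verified against statsmodels). Trans-eQTL tests regress a
module eigengene on a distal variant. Differential expression uses the
limma moderated t: the inverse-gamma variance prior `(d0, s0^2)` is fitted
by method of moments on `log s^2` (Fisher digamma/trigamma moments); when
the excess dispersion is non-positive the convention is `d0 = Inf` with
`s0^2` equal to the *arithmetic* mean of the sample variances, matching
`limma::squeezeVar` exactly (an R limma comparison runs in the test
suite). Posterior variances are
`(d0 s0^2 + d s^2) / (d0 + d)` with `d0 + d` degrees of freedom, BH FDR
across genes, and an intersection helper for network-membership overlap.

## Simulator (`adiponet.simdata`)

Genotypes are thresholded blockwise-AR(1) Gaussians (default block size
10, rho 0.7) dichotomized per haplotype at MAF-matched thresholds and
summed to dosages — exact Hardy–Weinberg by construction. Genes sit on a
regular grid (100 kb spacing, 10 kb length); the module genes are a
contiguous cluster so their cis-window union covers roughly 17% of the
simulated genome. Expression follows a one-factor model: a hub gene driven
by its nearest cis variant, module genes loading on the hub factor,
background genes independent. Quantitative traits put a configurable
multiple (default 5×) of per-variant heritability inside the module cis
union; binary traits use a liability threshold at the target prevalence;
sex-specific effect scales (0.6, 1.0) create sex-dimorphic genetic
effects. Summary statistics come either from explicit per-variant
regressions on the cohort or from the analytic mode
`z ~ N(sqrt(N) R beta_std, R)` per LD block, which makes GWAS sample sizes
of 20,000+ usable in calibration studies without materializing N×M
genotype matrices. All generators take a single integer seed and are fully
deterministic.

### Generator scope and limitations

The simulator is designed to exercise the estimators, not to mimic real
cohorts: LD is blocked AR(1) rather than empirically estimated, there is a
single expression factor (no batch structure, so principal-component
covariate correction is available but not required), allele frequencies
are drawn uniformly above a floor, and the binary trait shares the
quantitative trait's genetic architecture. Problem sizes in the
calibration studies (thousands of individuals, hundreds-to-thousands of
variants, tens of seeds) are the package's own choices sized for a single
CPU within a few minutes.

## Numerical conventions

- Correlations and standardization use population (ddof 0) scaling unless
  an estimator's definition requires otherwise.
- All randomized procedures take explicit integer seeds and use
  `numpy.random.default_rng`; repeated runs are bit-identical.
- Jackknife SEs are delete-a-block throughout (20 blocks for LDSC over
  variants, 30 for Haseman–Elston over individuals).
- Matrix solves prefer `numpy.linalg.solve`/Cholesky with small explicit
  ridges (1e-8) only where a correlation matrix can be numerically
  singular.
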