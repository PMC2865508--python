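# Methods

This note documents the models implemented in `esnpnet`, the defaults and
why they were chosen, what the synthetic-data generator emulates, and the
numerical conventions that matter for reproducing results.

## eSNP mapping

Association between a SNP (allele counts 0/1/2) and an expression trait is
tested with the Kruskal–Wallis statistic on midranks with tie correction;
the p-value comes from the χ² distribution with (genotype classes − 1)
degrees of freedom. Rank tests make the scan invariant to monotone
transforms of expression, which suits log-ratio intensity data with heavy
tails. Missing genotypes are dropped pairwise; a SNP with a single
remaining genotype class is untestable and raises. The matrix engine in
`eqtl.kw_matrix` evaluates all SNP × gene pairs from genotype one-hot
matrices and per-gene midranks; its agreement with per-pair
`scipy.stats.kruskal` is asserted in the test suite, including under ties.

**Cis/trans.** A pair is *cis* when the SNP lies on the gene's chromosome
within 1 Mb of the gene body, boundary inclusive ("within 1 Mb" is read as
≤), and *trans* otherwise. Coordinates are 1-based inclusive everywhere,
including the BED-like gene table this project reads and writes.

**Empirical FDR.** The null is built by shuffling the expression matrix's
sample labels as a whole (preserving gene–gene correlation) `n_perm` times
(default 10) and re-running the same tests — cis permutations are
restricted to the same cis windows. The threshold is the largest observed
p-value t with plug-in FDR(t) = (mean permutation count ≤ t)/(observed
count ≤ t) below the target (default 10%). The FDR is estimated globally
within each family (cis, trans), not per gene. Because the threshold search
targets the boundary and alternatives are a small fraction of pairs, the
realized pair-level FDR fluctuates *around* the target rather than sitting
below it; the calibration suite asserts it at the target within a
Monte-Carlo margin. Reported associations are LD-pruned per gene: among
SNPs correlated at |r| > 0.89 (single linkage) only the smallest-p SNP is
kept, ties broken by lexicographically smallest SNP id.

## LD conventions

"Correlation > 0.89" always means the absolute Pearson correlation of
genotype codes — not r² — computed over shared non-missing samples;
composite genotype correlation requires no phasing. LD groups are
single-linkage connected components of the thresholded correlation graph
restricted to pairs within a 1 Mb positional window (blocks are not
otherwise defined; single linkage is deterministic and order-independent).
Set expansion is one hop: the expansion of a core set adds every panel SNP
exceeding the threshold with at least one core member, and is not iterated
to a fixed point — it models proxy lookup of tag SNPs on another panel.
MAF bins are right-closed: (5,10], (10,20], (20,30], (30,40], (40,50]%,
with MAF ≤ 5% ineligible throughout.

## Matched-resampling enrichment

Each null draw reproduces the focal set's composition exactly: per
(MAF bin × cis/trans) stratum counts; focal LD groups of size k ≥ 2 drawn
as k SNPs from a single pool LD group with the same per-stratum
composition; cis slots filled from near-gene pool SNPs while trans slots
may use any SNP in the bin; all sampling within a draw without
replacement. In expanded mode each accepted draw's one-hop expansion must
fall within ±10% of the expanded focal size (rejection sampling, capped at
1,000 attempts per accepted draw — a cap breach raises with diagnostics
rather than biasing the null).

Estimators reported:

* `p_empirical` = (1 + #{null ≥ observed}) / (n_iter + 1) — the add-one
  permutation estimator with ties counted as exceeding; conservative and
  never zero.
* `p_plain` = #{null > observed} / n_iter — the plain strict-exceedance
  proportion.
* `p_mid` — the mid-p (ties counted half). On a discrete statistic the
  tie-inclusive estimator is conservative by construction, so uniformity
  checks in the calibration suites use `p_mid`; significance decisions use
  `p_empirical`.
* `p_approx` — the upper normal tail at Z = (obs − mean)/SD of the null,
  reported for resolution beyond 1/n_iter. The 95% CI is mean ± 1.96 SD
  (the resampled null proportion is close to normal at these set sizes).

`n_iter` defaults to 100,000; the calibration suites run at 1,000–10,000
iterations, which is where the Monte-Carlo error of the rates being
asserted, not the estimator itself, dominates. Draws consume randomness in
a fixed order (multi-groups in ascending focal group id, then strata in
ascending key order) over pools sorted by SNP id, so results are invariant
to input row order at a fixed seed. The nested set-vs-set comparison
(`compare_sets`) applies the same machinery with the background as pool and
a one-sided alternative that the focal subset is more enriched; a
non-nested focal set is pooled with the background (with a warning) so the
procedure stays defined.

## Co-expression network

Genes are ranked by expression variance (the natural spread measure on the
log-ratio scale) and the top 25% enter the network. Adjacency is unsigned,
a_ij = |cor(i,j)|^β with β = 6 (a signed variant and a scale-free-fit β
chooser are available); topological overlap is
ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with zero-diagonal
adjacency and unit TOM diagonal. Modules are branches of the
average-linkage dendrogram of 1 − ω under a static height cut (default
0.99, exposed); clusters below 30 genes are unassigned (label 0). A static
cut was chosen over dynamic tree cutting for determinism and zero extra
dependencies; the cut height default separates factor modules with
gene–factor correlation ≥ ~0.7 from noise at n = 200 while leaving pure
noise unclustered. Labels are assigned in decreasing module size with
gene-id tie-breaks, so they are input-order invariant. The eigengene is
PC1 of the per-gene z-scored module matrix (unit-norm scores,
`var_explained` = leading eigenvalue share), oriented to correlate
positively with the module's mean profile.

## Cross genetics and causal inference

F2 genotypes are simulated gamete-by-gamete as a Markov chain along each
chromosome with recombination fractions from Haldane's map function,
giving 1:2:1 genotype ratios and the correct decay of marker–marker
correlation. QTL scans regress a trait on additive (a = g − 1) and
dominance (d = [g = 1]) codes per marker, with
LOD = (n/2) log₁₀(RSS₀/RSS₁); marker-level regression suffices because the
simulated maps are dense, so no interval-mixture (pseudomarker) machinery
is used. Forward stepwise selection adds the marker with the best
conditional LOD while it exceeds the threshold (default 3.0). The
pleiotropy test is a bivariate Gaussian LRT of marker effects on a trait
pair, n log(det S₀/det S₁) against χ²₄.

Causal classification compares three linear-Gaussian factorizations for
(L, G, T) — causal P(G|L)P(T|G), reactive P(T|L)P(G|T), independent
P(G|L)P(T|L) — by AIC (the shared P(L) cancels). AIC was chosen over a
bespoke likelihood cascade because the comparison is between
non-nested factorizations of equal or near-equal complexity; the
classifier is validated by parameter recovery (≥90% correct for causal and
reactive chains at b = 0.7, n = 500; ≥80% for independent) rather than
claimed to replicate any particular prior implementation. "Supported as
causal" additionally requires an AIC margin ≥ 2 over the runner-up.

**Candidate filter.** A module gene is a candidate when (1) it lies inside
the configured linkage interval and has a cis eQTL with LOD ≥ 3, (2) it is
supported as causal for at least one clinical trait, and (3) its human
ortholog has a cis eSNP whose GWAS p is below 0.05. Results are ordered by
ascending best human GWAS p; module genes without an ortholog are logged
and skipped.

## Gene-set statistics

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k), accumulated in log space (logsumexp over the log-pmf) so
p-values of order 10⁻⁷⁰ are exact; fold = k/(nK/N). The universe size N is
a required explicit argument — published analyses use different universes
for different annotation sources, and a silent default would hide that.
Signatures use the equal-variance two-sample t per gene with Storey
q-values; π0 is the single-λ estimator at λ = 0.5 (deterministic, adequate
at these scales; the spline smoother adds tuning without benefit here).
Genes with zero variance in both groups get p = 1 with a flag.
Sex-adjusted phenotype comparisons report per-sex percent change
100 (mean_ko − mean_wt)/mean_wt and the t-test of the genotype coefficient
in trait ~ genotype + sex.

## Synthetic-data generator

The generator defines the study conditions under which every calibration
and recovery result is computed.

* **Genotypes.** SNPs in LD blocks laid on chromosomes (5 kb spacing,
  50 kb gaps); genes tile the chromosomes. Within a block, alleles come
  from a latent Gaussian haplotype copula: each haplotype's indicators
  share a block factor, thresholded at the MAF quantile, and the latent
  correlation is calibrated by root-finding so the *genotype* correlation
  has expectation equal to `within_block_r` (default 0.6). All SNPs in a
  block share one MAF drawn uniformly inside `maf_range` (default
  (0.05, 0.5)): with unequal frequencies a thresholded-Gaussian pair
  cannot reach high allelic correlation (the φ-coefficient bound), so
  block-constant MAF is what makes strong LD attainable — and is also how
  real haplotype blocks behave to first order.
* **Expression.** Designated cis pairs add `cis_effect` (default 1.0 per
  allele) to unit-variance noise. Module genes are
  s·(ℓ·factor + √(1−ℓ²)·noise): the loading ℓ (default 0.7) is the
  gene–factor correlation, and the scale s (default 1.3) keeps module
  genes among the most variable, so the top-25% selection retains them.
  Each module's factor is driven by a SNP placed in cis range of the
  module's first gene (locus effect 0.7 on the unit-variance factor) —
  this plants a complete gene: cis-regulated, module-central, and
  disease-causal.
* **GWAS.** An independent cohort (default 4,000 samples) is simulated on
  the same panel; liability = Σ effects·factors + N(0,1) with the module
  factors reconstructed from their driver SNPs (effect 0.3 per factor);
  cases are the top 20% of liability (liability-threshold model, a
  standard prevalence for a common metabolic disease). The association
  test is the genotype-by-status contingency χ² (a 1-df trend variant is
  configurable); which statistic the original consortia used internally is
  not modeled — only that null SNPs give uniform p.
* **Cross.** Default 554 F2 animals (the historical cross size), 2
  chromosomes × 21 markers at 5 cM. The chain L→G→T uses b = 0.7 per edge
  with unit noise; reactive and independent variants re-wire the same
  effects. Clinical traits are insulin (carrying the chain signal),
  glucose (sign-flipped, r ≈ −0.6) and islet count (r ≈ 0.5), mirroring
  the reported trait-correlation signs.

What the generator does **not** emulate: coalescent LD decay and allele
frequency spectra, phased haplotypes, population structure and
relatedness, imputation uncertainty, sex chromosomes, array-specific error
models, and polygenic disease architecture beyond the planted module.
Passing calibration on this generator therefore shows the statistics are
internally correct and well calibrated under idealized LD and effect
structures, not that effect sizes transfer to any real cohort.

## Numerical and reproducibility choices

* Every source of randomness derives from one top-level seed through named
  CRC32-keyed substreams; no code touches the global NumPy state, and
  adding a stage does not disturb another stage's stream.
* Monte-Carlo suite sizes (200 replicates × 1,000 iterations for type-I
  calibration, 10,000 matching draws, 200 recovery replicates per chain,
  20 FDR seeds) were sized so the binomial error of the asserted rate is
  small against the asserted band.
* Degenerate cases are errors, not silent values: monomorphic SNPs in
  correlation, constant genes in the network, constant traits in scans,
  identical traits in the pleiotropy LRT, infeasible matching strata
  (named in the message).
* The staged pipeline caches each stage's outputs on disk and skips
  completed stages on re-run; identical config + seed reproduces
  byte-identical outputs.

## Known limitations

* The trans scan is O(SNPs × genes); the cap subsamples pairs
  deterministically rather than prioritizing, so capped runs trade power
  uniformly.
* The expanded-mode null loops draw-by-draw (rejection sampling defeats
  vectorization); at 100,000 iterations on large panels this is the slow
  path.
* The plug-in FDR uses π0 = 1 implicitly; with a large alternative
  fraction it would be conservative, with a tiny one it is boundary-tight
  (see above).
* Orientation of eigengenes via the mean profile can flip for modules with
  balanced anti-correlated halves; the unsigned network makes such modules
  possible in principle.
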