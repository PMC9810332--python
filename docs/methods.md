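# Methods

## The model

`regherit` connects two layers of modelling: a regulatory layer that decides
*which parts of the genome* are the distinctive regulatory territory of each
cellular context, and a statistical-genetics layer that measures *how much of
a phenotype's SNP-heritability* concentrates in that territory.

### Regulatory scoring

For one context with paired expression and chromatin accessibility, every
TF–target-gene pair receives a trans-regulatory score

    TRS_ij = ( Σ_k B_ik · O_k · I_kj ) · 2^{R_ij} · sqrt(TF_i · TG_j)

where `B_ik` is the motif binding strength of TF i on regulatory element (RE)
k, `O_k` the RE's accessibility, `I_kj` a prior RE–gene interaction strength
learned externally and consumed here as input, `R_ij` a prior TF–gene
expression correlation in [−1, 1], and `TF_i`, `TG_j` the two expression
levels. The exponent/square-root placement follows the published scoring
model this layer reimplements; it matters only as a monotone
reparameterization of `R` and expression, but absolute score values depend on
it, so it is fixed and tested against a dense triple-loop oracle.

Every RE–gene pair with positive prior receives a cis-regulatory score

    CRS_kj = ( Σ_i B_ik · TRS_ij ) · I_kj · O_k .

Trans edges are kept against an empirical null built by re-pairing a
candidate TF with a uniformly drawn different target (its prior column,
prior correlation and expression), at FDR 0.001: the threshold is the
smallest observed score `t` at which the null-to-observed tail ratio drops to
the target FDR, which makes the selection monotone in the FDR parameter.
Cis edges are kept when `log2(1 + CRS)` lies in the upper `alpha = 0.05` tail
of a Normal fit over the candidate universe. A consequence worth knowing:
the re-pairing null can only certify edges whose height comes from genuine
TF–target coordination; signals that a random re-pairing can reproduce (e.g.
a promiscuous prior column) are — correctly — not selected.

### Context specificity and genome categories

Contexts are grouped by average-linkage hierarchical clustering of their TRS
vectors (correlation distance, tree cut to a requested group count). An RE
of context i is *context-specific* when no RE of any other context overlaps
it beyond a base-ratio threshold, with the candidate RE's own length as
denominator: strictly more than 50% against contexts of other groups,
strictly more than 60% against contexts of the same group. The relaxed
within-group bar keeps lineage-shared REs (several brain tissues would
otherwise annihilate each other's specific sets). The specific REs of a
context, merged into disjoint regions, form its genome category. Four
alternative category constructions (all network REs; all accessible peaks;
specificity-filtered peaks; ±100 kb windows around the top 10% specifically
expressed genes by the leave-one-context-out t-statistic
`(x_i − mean(others)) / sd(others)`) are provided for ablation, plus pooled
group-level categories using the strict cross-group rule only.

### Stratified heritability and relevance

Per-SNP χ² statistics from a GWAS of N samples follow, in expectation,

    E[χ²_j] = N · Σ_i τ_i · l_{j,i} + N·a + 1 ,

with `l_{j,i} = Σ_{k∈C_i} r²_{jk}` the LD score of SNP j in category C_i
(window 1 Mb by default) and `a` a confounding term. The fit is a
single-step weighted least squares of χ² on `{N·l_i}` with a free intercept
and weights `1/max(l_base, 1)`; the iterative two-step LDSC weighting is a
deliberate simplification left out. Standard errors come from a delete-one
block jackknife over 200 contiguous equal-count genomic blocks. Enrichment
of category i is

    E_i = (Σ_{j∈C_i} h_j / Σ_j h_j) / (|C_i| / M) ,   h_j = Σ_i τ_i·1{j∈C_i},

with jackknife SE and a one-sided p for `E_i > 1` (depletion is never
rewarded). The default per-context design is base category + one focal
category + intercept; a joint all-context fit is available by passing a
multi-column LD score table.

The relevance of a phenotype to a context is `R = E · (−log10 p)`, so a
context scores high only when its category is both strongly and confidently
enriched. R's own significance comes from a delete-one-fold jackknife: the
category's regions are split into 100 random (seeded) folds, R is recomputed
with each fold removed, `Z = R / SD_jackknife` is treated as one-sided
standard normal, and q-values are Benjamini–Hochberg across the contexts of
one phenotype. Relevant tissues are those with `R ≥ 100` and `q ≤ 0.01`.
The fold partition is random rather than genome-ordered so folds are not
confounded with chromosomes. Log base 10 is used in every `−log p`
(configurable in `relevance_score`).

### Downstream analyses

Relevance correlation between two phenotypes is the Spearman correlation of
their R-score vectors, computed as Pearson on average ranks (R vectors can
tie at 0). Agreement with gold-standard phenotypic correlations is scored
by Pearson correlation, mean squared error, and the Kraskov
k-nearest-neighbour mutual information estimator (algorithm 1: max-norm
k-th-neighbour radius, strict marginal counts, digamma formula, nats;
ties broken by seeded jitter of 1e-10·sd).

SNP-associated subnetworks score every RE by `A = C·S` with `C` the RE's
maximal CRS and `S` the mean over SNPs within 50 kb of
`w_l · (−log10 p_l) · exp(−d_lk / 5000)`, where `w_l` is the reciprocal of
the (floored) total LD score and `d_lk` the distance in bp (0 inside the
RE, else to the nearest boundary base; the window is strict). A scores over
the whole scored universe (zero-score REs included — they shape the null)
are fit by a Normal; upper-tail p-values pass Benjamini–Hochberg at FDR
0.05, and selected REs are closed one hop: bound TFs with a retained trans
edge to one of the RE's targets, cis targets, nearby SNPs. Overlap of two
phenotypes' subnetworks is tested per node level with a hypergeometric
upper tail against that level's count in the context network.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed) and serializes its ground
truth.

* **LD.** Block-diagonal AR(1): within a block `r = ρ_b^{|i−j|}`, zero
  across blocks. Per-block decay rates are drawn around `block_r = 0.5`
  with a ±70% multiplicative spread — real genomes have very unequal local
  LD, and that variation in total LD scores is also what identifies the
  base-category coefficient next to the free intercept. 50,000 SNPs at 1 kb
  spacing in 100 blocks by default.
* **Atlas.** 6 contexts in 3 groups, 240 REs each (1.5–2 kb wide), placed
  in reserved genomic slots interleaved across the genome: half are unique
  to their context (specific by construction), a quarter copied verbatim
  within the group, a quarter copied to all contexts. Omics tables are
  log-normal/sparse-uniform draws around group templates, so TRS vectors
  correlate within groups. Atlas networks keep all scored edges so the
  planted specific-RE ground truth is exact.
* **GWAS.** The marginal-z shortcut: `z_j ~ N(0, sqrt(N Σ τ_i l_{j,i} +
  N·a + 1))`, `χ² = z²`. This matches the regression model's expectation
  exactly (verified by a moment-check test) and keeps runs at desk scale; z
  values are independent across SNPs, so the block jackknife is exactly
  honest under the generator, which is what the calibration tests certify.
  Defaults: N = 50,000, background `τ_base = 1e-6` genome-wide, and
  `τ = 5e-5` extra per SNP inside the causal context's specific category —
  chosen so the planted context's R score lands in the several-hundred
  range typical of genuinely relevant tissues, decisively above the R ≥ 100
  selection threshold.

What passing these tests shows: the estimators invert their own generative
model, uncertainties are honest, nulls are calibrated, and planted structure
is recovered end to end. What they do not show: robustness to real-genome
features the generator omits — MAF-dependent architectures, long-range LD,
population stratification (the `a` term is modelled but defaults to 0),
sample overlap between phenotype pairs, and real atlases two orders of
magnitude larger.

## Numerical choices

* Jackknife blocks are contiguous and equal-SNP-count in (chrom, pos) order;
  delete-one refits use per-block sufficient statistics, so a full fit plus
  200 leave-one-out solves costs one pass over the data.
* p-values are floored at 1e-300; `−log10` of the floor caps R
  contributions.
* A category SE of exactly 0 (e.g. the all-SNP category, whose enrichment is
  identically 1) maps to p = 1 when the point estimate is ≤ 1.
* `select_crs_edges` and `select_associated_res` return empty selections
  with a warning when the fitted Normal has zero variance; `fit_stratified`
  raises a singularity error naming duplicated categories.
* Strict inequalities throughout the overlap rule and the 50 kb SNP window;
  interval queries go through an interval tree whose results are
  contract-tested against exhaustive pairwise comparison.
* Fold and block jackknives use the standard delete-one-group variance
  `(g−1)/g · Σ(θ_b − θ̄)²`.

## Problem sizes used by the test suite and acceptance script

Recovery, jackknife-honesty, and end-to-end relevance experiments run at the
default 50k-SNP scale (20, 100, and 20 replicates respectively); the
500-replicate null-calibration experiment uses a broad quarter-genome test
category (12,500 member SNPs) so the jackknife z statistic is in its
asymptotic regime; sign-recovery uses 20 phenotype pairs per condition. The
whole suite completes in a few minutes on one CPU.

## Known limitations

* The one-sided enrichment test is conservative for very small categories
  (a few hundred member SNPs): the jackknife z statistic inherits the
  finite-sample left skew of t-type statistics under χ² noise, so rejection
  at nominal 5% drops to ~2–3%. It is never anticonservative in our
  experiments.
* Single-step WLS weights (reciprocal total LD score) rather than the
  iterative variance-based weighting; τ point estimates are unbiased either
  way, but efficiency is slightly lower.
* The TRS FDR null re-pairs TF rows with other targets' prior columns; in
  tiny dense matrices the re-paired null can reproduce genuine pairs, which
  inflates the estimated FDR and makes selection conservative (see the
  network-module tests for the planted design that avoids this).
* Genetic-correlation estimation, eQTL validation, chromatin-loop lookup,
  and admixed-population corrections are out of scope.
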