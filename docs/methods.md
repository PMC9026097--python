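# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `modscape`, and what the test suite does and does not
establish about real data.

## Differential expression

Each contrast is a two-group comparison on log2-scale expression (the input
matrices are assumed RMA-like, i.e. already normalized and log2). The
per-gene effect is the difference of group means; with n_a = n_b = 3 this is
the OLS coefficient of the two-group design, so "generalized least squares"
reduces to ordinary least squares (the design is balanced and no correlation
structure is modeled).

Empirical-Bayes moderation places a scaled inverse-χ² prior on the residual
variances. Hyperparameters (d₀, s₀²) are estimated on the log scale: with
e_g = log s²_g − ψ(d/2) + log(d/2), the mean of e identifies s₀² and its
excess variance over ψ′(d/2) identifies d₀ through trigamma inversion
(Newton's method, tolerance 1e−8). When the excess variance is nonpositive
the prior df is capped at 1e6 (treated as infinite; p-values switch to the
normal) and s₀² is the arithmetic mean of the variances. The implementation
reproduces R limma's `lmFit`/`eBayes` to ~1e-14 on shared fixtures (limma is
used in the tests as an independent oracle only). Setting d₀ = 0 recovers
the ordinary equal-variance t-test exactly; both limits are tested.

DEG thresholds are strict inequalities as published: lenient p < 0.05 with
linear FC > 1.25 or < 0.80; stringent FDR < 0.10 with the same FC gates. FC
is 2^log2fc from the model coefficient (identical to the ratio of group
means here). |FC|max ranks genes by max |log2FC| across the three contrasts
so up- and down-regulation are comparable in magnitude.

## Gene filters and sample QC

Detection: a gene is detectable on an array when its value strictly exceeds
that array's own 20th-percentile quantile (type-7 linear interpolation, used
for every quantile in the package), in at least 2 of the comparison's 6
samples. Variability: genes are kept when their across-sample SD (n−1
denominator) is ≥ the 5th percentile of all gene SDs, so an all-equal-SD
matrix keeps everything. Single-sample outlier exclusion requires BOTH
|z| > 2.50 for the designated sample AND that sample being the strict
min/max — a tied extremum is kept. The per-array detection quantile is
computed after probe collapse (the alternative ordering is not
distinguishable from the published description; this choice is recorded
here). Probe collapse keeps the probe with the highest mean across all
samples, ties broken toward the lexicographically smaller probe ID and
logged.

Sample screening: PCA on the gene-standardized matrix (samples as
observations) followed by a two-sided Grubbs (maximum normalized residual)
test on PC1 scores, using the closed form
t² = n(n−2)G²/((n−1)² − nG²), p = min(1, 2n·P(T_{n−2} > t)). The closed form
agrees with a 100,000-draw Monte-Carlo null to within ±0.01 at n = 12
(tested). Note the popular 4-point example {−1, 0, 1, 10} sits almost
exactly at the n = 4 critical value: with the sample-SD (ddof = 1) statistic
G = 1.4804 the two-sided p is 0.052, not below 0.05 — claims to the contrary
implicitly use a population-SD normalization.

## Co-expression modules

Reference profiles are standardized per gene (mean 0, SD 1 across the 24
reference samples; constant genes flagged and excluded), then clustered with
average linkage on Euclidean distance. Pruning is a variable-height
("dynamic") rule re-implemented in a height-profile form with one knob:

* walking the dendrogram top-down, a node is **tight** when its merge height
  is ≤ (1 − `prune_depth`) times the height at which it joins its parent;
* a tight node with ≥ `min_module_size` (default 25) leaves becomes one
  module, unless both of its children are themselves tight and large enough,
  in which case the split is taken instead (nested structure wins);
* all other leaves stay unassigned (module 0).

`prune_depth` defaults to 0.08. The choice comes from the behaviour of the
height-ratio statistic on factor-model simulations: subtrees of ≥ 25 leaves
in pure-noise dendrograms bottom out at node/parent ratios ≈ 0.91–0.94,
while planted-module clades (within-module r ≈ 0.7) drop to ≈ 0.92 or far
below, so 0.08 keeps noise almost entirely unassigned (≥ 97.8% across seeds)
while recovering planted modules of 25–196 genes at ARI ≥ 0.97. Occasional
small false modules on noise are expected and tolerated (a few percent of
genes). Module assignment is invariant to gene input order (tested via ARI
= 1 between permuted runs; distances on continuous data are tie-free).

Labels are `GENE-size` with the member carrying the most annotation terms
(lexicographic tie-break; duplicate labels disambiguated with a numeric
suffix). The medoid is the member minimizing summed Euclidean distance to
the other members. The module network connects modules whose medoid profiles
have signed Spearman r_s ≥ 0.80 (a 1e−12 numerical tolerance admits the
exact boundary); anti-correlated medoids are not connected.

The DEM test compares member log2FCs against all other detectable genes with
a two-sided Wilcoxon rank-sum: exact enumeration when a module has ≤ 10
detectable members, otherwise the tie-corrected, continuity-corrected normal
approximation computed from a single shared ranking (so testing hundreds of
modules costs one sort). BH adjustment runs across modules; DEM calls use
FDR < 0.05. The shift statistic is the difference of medians.

## Set statistics

`direction_fisher` builds the 2×2 table {signature, background} ×
{log2fc > 0, log2fc < 0} over detectable genes; genes with exactly zero
log2fc are dropped from the table but counted in the result. Because the
published description names the test but not the table, an exact binomial
test of the member up-fraction against 0.5 is always reported alongside.
The cumulative-overlap area ranks all detectable genes by log2FC descending
(gene-ID tie-break), accumulates C(k) = hits(k)/m − k/N, and averages over
k; the statistic is antisymmetric under rank reversal by construction and
lives in [−0.5, 0.5]. Its p-value is the rank-sum test of member vs
non-member fold changes.

Annotation enrichment is a plain one-sided hypergeometric per term with BH
across terms (the GO-graph-conditional variant is out of scope; no GO
topology ships with the package). Disease sources aggregate into a
gene × source boolean table with tier = number of sources; resampling
nulls (`random_set_fc_null`, `mean_distance_null`) use the add-one
estimator p = (1 + #{null ≥ obs})/(n_trials + 1), so p ∈ (0, 1] always, and
are deterministic given their seed. Trials are drawn without replacement by
arg-partitioning random keys in memory-bounded chunks.

## GWAS proximity

Distance is gene-body to locus: 0 when the locus position falls inside the
half-open gene interval, otherwise distance to the nearer interval edge;
genes with no same-chromosome locus get ∞ and are excluded from means but
counted. The window scan tests, per distance window, a one-sided Fisher
table of (top DEG vs rest) × (near vs not); overlap counts are monotone in
window size by construction. The mean-distance null is lower-tailed
(closeness is the hypothesis); p < 0.10 is flagged "marginal".

## Motif enrichment

PWMs carry a 0.01 pseudocount and uniform background by default; N scores as
background (log-odds 0). Scanning covers both strands; the hit threshold
defaults to 80% of the maximal achievable log-odds score, and reverse-strand
hits are reported at their forward-strand leftmost coordinate. The
enrichment model is logistic, logit P(DEG) = β·motif + s(GC) [+ s(length)
when length varies], with s(·) an unpenalized cubic B-spline whose 4
interior knots sit at covariate quintiles — a fixed-basis stand-in for a
penalized smoother that keeps the model fully reproducible. Significance is
the χ²₁ likelihood-ratio test of β = 0, BH-adjusted across PWMs. Separation
(non-finite deviance or |β| > 15) triggers a ridge-penalized IRLS refit
(penalty 1e−4) with the LRT taken on unpenalized log-likelihoods at the
penalized estimates, and the result is flagged. The motif feature defaults
to the hit count; max-score mode is available. The IRF profile runs the
model per IRF-family PWM per DEG set and bins hit positions at 250 bp for
PWMs passing FDR < 0.05; PWMs with constant hit counts across the universe
are skipped with a warning.

## Small-sample statistics

`exact_wilcoxon` enumerates all C(N, n) rank assignments when N ≤ 12 and the
data are tie-free; the two-sided exact p is 2·min(lower tail, upper tail)
capped at 1 — under this convention the 3-vs-6 configuration with the small
group at ranks {1, 2, 4} gives p = 4/84 ≈ 0.048, the published
reporter-assay value. Larger or tied samples use the tie- and
continuity-corrected normal approximation. Exhaustive comparison at N = 12
shows exact and approximate p agree within 0.02 whenever both groups have
≥ 4 members; the discrete support makes the gap necessarily larger for
extreme splits (worst case 0.115 at 1-vs-11), which the tests pin at their
measured values rather than pretending a uniform bound.

ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt subtracts the
calibrator-group mean ΔCt, relative expression is 2^(−ΔΔCt); the calibrator
group's geometric mean is exactly 1. Fisher's LSD is unprotected (no omnibus
F gate), uses the pooled one-way-ANOVA MSE and residual df for all pairwise
t tests, and assigns letters by insert-and-absorb over the significance
graph, columns ordered by descending group mean; the letter display is
asserted consistent with the pairwise p matrix in the tests.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the study's *design*, not its biology:

* **Treatment matrix**: 4 groups × 3 replicates; planted genes get a
  constant signed shift of `effect_size_log2` (default 1.0) on a
  N(7, 1.5²) per-gene baseline with i.i.d. N(0, 0.25²) residuals. Default
  perturbed fractions (MMF 3%, DRF 2.5%, IDMF 10%) mirror the relative DEG
  burden of the three compounds.
* **Reference matrix**: 24 samples; module genes load on a shared latent
  factor (gene = a·z_m + ε). Factors are standardized across samples so the
  within-module correlation a²/(a² + σ²) holds realization by realization,
  not just in expectation — without this, the χ²₂₄-distributed realized
  factor variance makes roughly one planted module in five far more diffuse
  than nominal. Background genes get variance-matched pure noise, so modules
  are separable only through correlation.
* **Genome**: genes of 2–20 kb with 5–50 kb gaps laid on synthetic ~500-gene
  chromosomes; a chosen fraction of a designated list receives a locus
  within 100 kb; remaining loci are placed uniformly (length-weighted by
  chromosome).
* **Promoters**: i.i.d. backgrounds with configurable GC; planted genes get
  one exact consensus instance at a recorded position.
* **Signatures / disease sources**: directional sets with a known planted
  concordant fraction; source membership with truncated-geometric tiers.

None of this models probe-level physics, heteroskedastic or correlated
noise, LD structure, or real motif redundancy. Passing recovery tests
therefore demonstrates that the statistics are implemented correctly and are
calibrated under their own assumptions — not that they are robust to the
failure modes of real microarray data.

All randomness flows through explicitly seeded `numpy.random.Generator`
streams (one stream per operation, derived from the seed), so identical
parameters give byte-identical outputs; resampling stages record their seeds
in the pipeline manifest and are exactly replayable.

## Problem sizes in tests and the acceptance script

Simulated checks run at 5,000 genes for DE calibration/recall, 1,200–1,500
genes for module recovery and noise behaviour, 200 repetitions × 1,000
trials for null-uniformity checks, and 10,000 trials for the random-set
null — sizes at which the asserted properties are statistically stable while
the full suite completes in about a minute.

## Known limitations

* The pruning rule is a deliberately simple variant of dynamic tree cut; it
  has one knob and no outlier re-assignment (PAM-like) stage, so weakly
  correlated module members that chain into the noise tail stay unassigned.
* The spline-logistic motif model fixes its basis; it does not select
  smoothness from data.
* `direction_fisher`'s published counterpart is ambiguous about the exact
  2×2 table; both implemented variants (background table, binomial vs 50%)
  are reported so downstream users can compare.
* Empirical-Bayes moderation assumes exchangeable variances; with planted
  homogeneous noise the prior df estimate correctly diverges (capped at
  1e6), which maximizes shrinkage.
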