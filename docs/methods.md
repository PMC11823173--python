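# Methods

This note records the models, numerical choices and known limitations behind
colxnet, in the spirit of the methods documentation of mature statistical
packages.

## Scope and data model

The pipeline consumes a gene × sample expression matrix (TSV) with a unit
tag — `rsem` (normalized RNA-Seq), `counts` (raw), `log_intensity`
(microarray) or `log2` — together with an optional clinical table (TSV),
gene-set collections (GMT) and a cell-type signature (TSV). Gene identity is
a case-sensitive symbol string with no alias resolution; all cross-matrix
operations intersect on symbols. Clinical stage is binarized by major stage
number (1–2 vs 3–4; substage letters are ignored — the upstream sources do
not state a substage rule, so the major number is the only defensible
choice). Missing clinical values are handled by complete-case analysis per
model: a sample missing one outcome is still used for the other.

## Preprocessing

Three low-expression filters, each implemented with exactly the stated
inequality semantics:

| rule | removes a gene iff | boundary |
|---|---|---|
| RSEM | value < 1 in ≥ 50% of samples **and** mean < 50 | inclusive ≥ (a gene at exactly 50% qualifies) |
| counts | count < 5 in ≥ 90% of samples | inclusive ≥ |
| log intensity | below threshold in > 80% of samples | strict > |

The RSEM rule is conjunctive: a gene mostly silent but very high in a few
samples (mean ≥ 50) is kept. The microarray intensity threshold is dataset-
specific and therefore a required parameter with no default. Probe
consolidation keeps, per gene, the probe with maximal mean intensity
(max-mean rule, the documented default of the standard consolidation
utility); unmapped and multi-mapping probes are dropped and reported. Count
normalization is median-of-ratios with a zero-free-gene reference (the
DESeq size-factor construction); log transform is `log2(x + 1)`.

## Network construction and module detection

Signed adjacency `((1+r)/2)^β` preserves the correlation sign (negative
correlation → adjacency near 0), Pearson by default. β is selected as the
smallest candidate whose signed scale-free fit R² (log-log regression of the
binned connectivity distribution, 10 equal-width bins) reaches the target
(default 0.85) with a negative slope; if none reaches it, the β maximizing
R² is used, with a logged note. Candidate powers whose network is nearly
empty (mean connectivity < 1) are excluded from selection in both branches:
degenerate degree distributions produce spuriously good fits. On
latent-factor data — and on many real cohorts — the target is often not
reached and the fallback is the normal path, which the fit table makes
transparent; the run manifest records β, the target and whether it was
reached.

Module detection clusters `1 − TOM` by average linkage and applies a single
static cut. The cut height is chosen by a gap scan: candidate heights are
the midpoints of the widest gaps between consecutive merge heights (natural
separations between tight clusters and the diffuse upper tree); the
candidate maximizing the number of clusters of at least `min_module_size`
genes wins; among ties the coarsest cut is used, stepped one or two tied
cuts finer for deep-split levels 3–4. This replaces the dynamic hybrid tree
cut of the reference implementation with a transparent, testable rule. On
the latent-factor generator the static cut recovers planted blocks with ARI
0.95–1.0 across seeds; on real data with nested or overlapping modules the
dynamic algorithm may split more finely, so module counts are not expected
to match it exactly — a deliberate simplification whose fidelity gates are
the recovery and preservation tests.

Eigengenes are computed by SVD of the row-standardized member submatrix,
rescaled to unit variance, and sign-oriented to correlate non-negatively
with the mean member profile so that downstream survival coefficients have
a stable direction. With duplicated member rows the eigengene is recomputed
on the duplicated matrix (no deduplication) — the direction is essentially
unchanged, which a property test asserts.

## Module preservation

Preservation of a module in a test cohort is a permutation Z panel of four
statistics: two density (mean off-diagonal intramodular correlation and mean
signed adjacency in the test cohort) and two connectivity (correlation
across member genes of reference-vs-test intramodular connectivity;
correlation of the vectorized intramodular correlation matrices). The null
draws `n_perm` (default 200, minimum 50) random same-size gene sets from the
shared universe excluding the module, in both cohorts simultaneously.
`Z_density` and `Z_connectivity` are medians of their groups' Z scores;
`Z_summary` is their mean, with > 10 read as strong preservation. This is a
reduced version of the published 7+-statistic panel: it keeps the "mean of
summarized density and connectivity" definition while keeping the
permutation oracle simple. Ranks among modules computed from the full panel
are not reproducible from the reduced one and are not attempted. A zero
permutation SD yields ±inf with a warning rather than an error.

## %G.A.M.E. and Jenks stratification

`game_s = |{g ∈ M : x_gs > median_g}| / |M|` with interpolated per-gene
medians over the full cohort and a strictly-above tie rule (ties at the
median do not count; a constant gene contributes 0 everywhere). The score is
invariant to any strictly increasing per-gene transformation, so the
expression scale (log or linear) is immaterial. For exchangeable genes with
distinct values and even n the cohort mean is exactly 0.5.

Jenks natural breaks are computed by exact dynamic programming over
contiguous partitions of the sorted values (O(k n²) with prefix sums),
minimizing the total within-class sum of squared deviations — verified
against exhaustive enumeration for n ≤ 25, k ≤ 4. Returned breaks are the
class maxima of the lower classes; assignment uses "value ≤ break → lower
class", so a value exactly at the first break is "low". The Kaplan–Meier
label merges medium and high into "high" (low vs all-other).

## Gene-set statistics

Overlap: one-sided upper-tail hypergeometric p (equivalent to Fisher's exact
test for enrichment), sample odds ratio `ad/bc` (+inf when `bc = 0` with
overlap), BH across the collection; significance requires the mode's p.adj
threshold (0.05 standard, 0.10 for TF-target candidate discovery) and odds
ratio > 1.

Differential activity between high and low strata: per-gene log2 mean
difference `d_g`; enrichment = set mean of `d` minus background mean. The
background is all genes retained after preprocessing (and it contains the
set, so enrichment = `(1 − m/N)`(set mean − non-set mean)). The test
statistic divides enrichment by a standard error that combines (i) the
VIF-inflated set-mean variance, `VIF = 1 + (m−1)ρ̄` with ρ̄ the mean pairwise
correlation of set genes across all samples floored at 0, built from
per-gene Welch variances, and (ii) the non-set mean's variance with genes
treated as independent, both scaled by `(1 − m/N)²`; degrees of freedom are
the mean per-gene Welch–Satterthwaite df. This replaces the reference
method's probability-density convolution with a closed-form approximation
carrying the same outputs (log-fold-change enrichment, BH p-values, the
25%-of-anchor-magnitude significance gate); a Monte-Carlo calibration
(2,000 null sets, ρ = 0.3) shows type-I error ≈ 0.05 where the uncorrected
statistic exceeds 0.15. Because activity is measured relative to the
background, sets disjoint from a strongly shifted module show a small
opposite-signed enrichment; the magnitude gate is what keeps such
compositional effects out of the significant calls. When the anchor
module's activity is exactly 0 the gate degenerates and the p.adj gate
alone applies, with a warning.

## Cell-type markers and deconvolution

Markers use the "tissue-enriched" four-fold rule: for every other type,
log2 fold change ≥ 2 (pseudocount 1 on normalized means, consistent with the
log pseudocount used elsewhere) and BH-adjusted p < 0.05, adjusted across
all genes × contrasts. The per-contrast test is a moderated pooled t on
log2(normalized + 1): per-gene variances are shrunk toward an across-gene
prior fitted by moment matching on log variances (the empirical-Bayes
moderation that makes 2–3-replicate designs testable); an unmoderated
two-sample test at n = 3 per type cannot clear a collection-wide BH
correction no matter how large the fold change, which is exactly the regime
this moderation exists for. The signature matrix holds per-type mean
normalized expression of the markers, optionally capped per type by
descending minimum pairwise fold change (most specific first). Deconvolution
is per-sample non-negative least squares of the bulk marker-gene vector on
the signature columns — absolute scores plus relative fractions (absolute /
row sum; undefined for all-zero rows). This NNLS stand-in preserves the
absolute/relative contract of the hosted ν-SVR tool it replaces but has no
feature selection or batch adjustment of its own; the published tool's
signature gene count is therefore not a reproduction target. Fraction ↔
%G.A.M.E. association uses Spearman correlation with Bonferroni correction
across cell types, run separately for absolute and relative fractions.

## Survival

Cox models are fit by lifelines (partial likelihood, Efron tie handling,
Newton convergence) on age, gender, binarized stage and one signal variable
standardized to unit SD; hazards are reported as `(e^β − 1)·100` percent per
unit. Degenerate covariates (a cohort entirely in one stage group, or a
single-gender subcohort) are dropped from the model with a logged note
rather than failing. Models require ≥ 10 events (overridable for small
diagnostic fits). BH adjustment is applied across the signal-variable
models within one outcome family; covariates within one model are not
cross-adjusted. The proportional-hazards check correlates scaled Schoenfeld
residuals with event-time rank. Kaplan–Meier comparison requires two groups
with at least one event each; medians are the smallest time with S(t) ≤ 0.5
(NaN when never reached); the log-rank test is the standard
observed-minus-expected χ²₁.

## Synthetic cohorts: what they emulate, and what they do not

Expression: one latent factor per module, `x_gs = λ_g z_{m,s} + ε_gs`, with
loadings λ uniform on (0.6, 0.9) by default, standard-normal factors (the
anchor-module factor optionally a two-Gaussian mixture with separation Δ = 4
and weight 0.5, the structural premise behind bimodal %G.A.M.E.), unit-SD
Gaussian noise and pure-noise background genes. Defaults: 1,200 genes,
300 samples, module sizes (60, 50, 40); the anchor gene is a member of the
first module. Setting `sample_seed` redraws patients while keeping the
gene-level structure (loadings) fixed, which is how a replicate cohort for
preservation analysis is generated — real validation cohorts share biology
but not patients.

Clinical: age ~ N(60, 10) truncated to [18, 90]; gender Bernoulli(0.5) (set
`male_fraction=0.01` for a breast-cancer-like cohort); stage 3–4 with
probability 0.3. Survival: exponential times with hazard
`0.02·exp(ln(2)·z_anchor + 0.03·(age−60) + 1.0·stage34)` — hazard ratio 2
per SD of module activity, ~3%/year of age — independently censored at
uniform times up to 120, giving roughly one third censoring.

Cell types: 4 types × 3 replicates, negative-binomial counts
(dispersion 0.05, moderate for sorted bulk replicates), 40 planted 16-fold
markers per type over a 1,200-gene universe with log-uniform baselines
(20–200); the anchor gene is planted as a marker of the last (BMSC-like)
type. Mixtures are noisy convex combinations of the per-type mean profiles.

Not emulated: probe-level microarray structure, batch effects, gene-length/
GC biases, overlapping or nested modules, non-proportional hazards,
competing risks, and platform shift between signature and bulk. Passing
tests therefore demonstrate correctness of the statistics and recovery
under the stated generative model, not robustness to these real-data
complications.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes (e.g. 1,000 null Cox fits
at n = 300, 2,000 null activity sets, 10–20 seeds per recovery check,
200-permutation preservation nulls) were chosen as the smallest sizes at
which the binomial/Monte-Carlo error of each estimate is well inside its
acceptance band. Correlations are clipped to [−1, 1] before powering;
adjacency/TOM computations are dense (a configurable `max_genes` guard
errors above 20,000 genes — desk-scale post-filter counts do not need
block-wise processing). Permutation seeds, simulation seeds and the CLI
seed all flow from explicit integer seeds; identical config + seed yields
bitwise-identical outputs and manifest checksums.

## Known limitations

- The static cut is a deliberate simplification of dynamic tree cutting;
  module boundaries on real data will differ in detail.
- The preservation panel is reduced (4 statistics); cross-study module
  *ranks* from the full published panel are out of reach.
- The VIF-corrected activity test is an approximation to a full
  convolution-based posterior; its calibration is demonstrated by
  simulation, not proved.
- NNLS deconvolution assumes the bulk platform matches the signature's
  normalized-count scale.
- The scale-free fit target is often unattainable on strongly modular
  synthetic data; the fallback rule is then the operative selector.
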