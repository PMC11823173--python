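# colxnet

Anchor-gene co-expression module analysis for bulk transcriptomics: discover
the weighted co-expression module containing a chosen anchor gene (by default
*COL10A1*, collagen type X alpha-1), validate it across cohorts, score and
stratify patients by module expression, and characterize the strata with
gene-set statistics, cell-type deconvolution and survival models.

## Who this is for

Computational biologists studying a single gene of interest in tumor (or
other bulk) expression cohorts who want the full "gene → module → patient
strata → phenotype" chain as a reproducible, testable library rather than a
collection of R sessions. Every stage is importable from Python; a thin
`colxnet` command-line wrapper covers file-based runs; a synthetic-cohort
generator with known ground truth makes every stage testable without any
data download.

## The methods

- **Signed weighted network & modules.** Adjacency
  `a_ij = ((1 + cor(x_i, x_j))/2)^β` with the soft-thresholding power β
  chosen for approximate scale-free topology; gene-gene similarity smoothed
  by the topological overlap measure
  `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; modules from
  average-linkage clustering of `1 − TOM` with a static cut and a minimum
  module size (default 30), numbered 1..K by descending size (0 =
  unassigned). The **anchor module** is the module containing the anchor
  gene; each module is summarized by its **eigengene** (first principal
  component of the standardized member rows, sign-oriented).
- **Preservation.** Permutation `Z_summary` = mean of summarized density and
  connectivity preservation Z statistics of a module evaluated in a second
  cohort; `Z_summary > 10` indicates strong preservation.
- **%G.A.M.E.** (percentage of Genes Above-Median Expression): per sample,
  the fraction of module genes expressed strictly above their cohort-wide
  medians — a `[0,1]`-bounded, rank-faithful proxy of module activity whose
  distribution becomes bimodal when module expression is bimodal. Samples
  are split into low/medium/high at the Jenks natural breaks (optimal 1-D
  classification) and binarized as low vs all-other for survival comparison.
- **Gene-set statistics.** One-sided Fisher overlap tests with BH adjustment
  (significant iff `p.adj < 0.05` and odds ratio > 1; `p.adj < 0.10` in
  TF-target discovery mode), and a correlation-aware differential activity
  test between strata: mean log2 fold change of the set relative to the
  background, variance inflated by `VIF = 1 + (m−1)·ρ̄`, significant iff
  `p.adj < 0.05` **and** |enrichment| ≥ 25% of the anchor module's own
  activity.
- **Cell types.** Four-fold marker rule (`log2FC ≥ 2` and `p.adj < 0.05`
  against *every* other type, moderated t on log2 normalized counts),
  mean-expression signature matrix, and non-negative-least-squares
  deconvolution of bulk samples into absolute scores and relative fractions,
  correlated with %G.A.M.E. (Spearman, Bonferroni across cell types).
- **Survival.** Multivariate Cox proportional hazards (age, gender, stage
  1–2 vs 3–4, plus one standardized signal variable; Efron ties), hazards
  reported as `(e^β − 1)·100` percent per SD, scaled-Schoenfeld PH
  diagnostics, and Kaplan–Meier/log-rank comparison of the %G.A.M.E. strata.

## Worked example

```bash
python examples/01_simulate_and_discover_module.py
```

prints (seed 1):

```
cohort: 1200 genes x 300 samples
soft-thresholding power beta = 9 (scale-free R^2 = 0.69)
anchor module: id 1 (assigned), 60 genes
recall of the planted anchor block: 1.00 (fraction of planted genes recovered)
eigengene vs true latent factor R^2: 0.97 (how faithfully the module eigengene tracks the planted factor)
```

The simulated cohort plants three latent-factor modules; the discovered
anchor module recovers the planted block exactly, and its eigengene tracks
the generating factor almost perfectly. The other examples walk through
preservation (`02`), %G.A.M.E. stratification (`03`), set enrichment and
activity (`04`), markers and deconvolution (`05`), and survival (`06`).
`examples/06_survival_analysis.py` for instance reports, for a planted
hazard ratio of 2 per SD of module activity, `module ME: hazard=+111%/unit`
and a low-vs-high log-rank p of ~5e-22 at n = 500.

For file-based runs, `colxnet run --config config.yaml` executes the whole
chain (filter → network → anchor module → preservation → %G.A.M.E. →
enrichment/activity → deconvolution → survival) and writes TSV tables plus a
checksummed JSON manifest; `colxnet simulate` writes a synthetic cohort to
disk; the remaining subcommands run individual stages.

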