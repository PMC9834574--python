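# Methods

## Data model and identification filtering

The pipeline consumes a MaxQuant-style `proteinGroups` table: one row per
protein group, "+"-flag columns for reverse database hits, potential
contaminants and proteins only identified by site, semicolon-separated
accession lists, and one linear-scale `LFQ intensity <sample>` column per
biological sample with 0 meaning "not quantified". Rows matching any of
the four identification filters (reverse → contaminant → only-by-site →
"Fragment" in the lead FASTA entry, case-sensitive substring) are removed;
a row matching several rules is counted once under the first rule so the
filter report partitions the input exactly. Gene symbols can be remapped
from the first majority accession; symbols shared by several protein
groups are disambiguated by appending the accession in brackets.

Intensities are log2-transformed; zeros become missing cells. A protein is
retained when at least one *condition* group (AS, MR, CON) has ≥ 50 %
valid values — retained at exactly 50 %, excluded only strictly below.
The comparison unit is the condition group rather than the six
condition × sex cells because the filter is applied once to the full
sample set before any contrast is formed; the six-cell variant is
available via `filter_valid_values(..., by="group")`.

## Imputation

Missing LFQ values are treated as left-censored (missing-not-at-random):
for each sample column `j` with observed mean `μ_j` and sample standard
deviation `σ_j` (n−1 denominator, computed on observed values only), each
missing cell draws independently from
`Normal(μ_j − shift·σ_j, (width·σ_j)²)` with defaults `shift = 1.8`,
`width = 0.3` — the downshifted-Gaussian convention of the Perseus
ecosystem. Observed cells are never touched (bit-identical). Each column
uses its own generator seeded from `(seed, column index)`, so subsetting
samples reproduces draws; the imputed-cell mask is returned alongside the
completed matrix.

## Moderated linear model

Per-protein ordinary least squares on a cell-means design over the six
condition × sex groups gives coefficients (group means), residual variance
`s_g²` with `d_g = n − 6` degrees of freedom, and average log2 intensity
`A_g`. Contrasts: three condition contrasts averaging the two sexes with
equal cell weights (sample-size weights available via
`build_design(..., sex_weighting="size")`; equal weights were chosen so the
larger sex cell does not dominate the condition effect), and the four
sex-stratified cell differences.

The empirical-Bayes prior is a scaled inverse-chi-square on the residual
variances, fitted in closed form by matching moments of
`z_g = log s_g²` using the digamma/trigamma identities: with
`e_g = z_g − ψ(d_g/2) + log(d_g/2)`,

```
ψ'(d0/2) = var(e) − ψ'(d_g/2)          (ψ' inverted by Newton iteration)
s0²      = exp(mean(e) + ψ(d0/2) − log(d0/2))
```

With the mean–variance trend enabled (default), a robust lowess curve of
`z_g` on `A_g` (window fraction 0.4, 4 robustness iterations) is removed
first and the moments are fitted to the trend residuals, making
`s0²(A) = exp(trend(A))·s0²` a smooth function of average intensity; this
captures the variance inflation that downshift imputation concentrates on
low-abundance proteins. `d0` is clamped to `[0.1, 1e7]`; numerically
identical variances yield `d0 = +∞` with a warning (normal reference
distribution, `s̃² = s0²`). The `d0 = 0` limit reproduces per-protein
ordinary t-tests exactly and is pinned by an oracle test; the finite-`d0`
path agrees with R/limma's `eBayes(trend=FALSE)` to 1e-9 in a cross-check
test (limma is never used by the implementation).

Moderated statistics: `s̃_g² = (d0·s0²(A_g) + d_g·s_g²)/(d0 + d_g)`,
`t = β̂_c / (sd_c·s̃_g)` against `t(d0 + d_g)`; two-sided p-values are
Benjamini–Hochberg-adjusted **within each contrast** (the analysis reports
per-comparison significant counts, so pooling across contrasts would mix
different null fractions).

## Effect classification

Strict thresholding at adjusted p < 0.05 (`adj_p == α` is not
significant; a zero log fold change carries no direction). Condition
level: *shared* and *divergent* require both versus-control contrasts
significant (same or opposite signs); *AS-specific* requires significance
versus control **and** versus MR with the sign conserved in the AS-vs-MR
contrast and a quiet MR-vs-CON (symmetrically for *MR-specific*, where
the AS-vs-MR sign must oppose the MR direction); proteins significant in
neither versus-control contrast are *ns*; every remaining pattern (e.g.
significant versus control but not versus the other condition) is *other*.
The specific/shared/divergent taxonomy alone is not exhaustive, hence the
explicit residual bucket; the six labels partition the protein set. Sex
level, within a condition: *female-only* / *male-only* / *both* from the
two sex-matched contrasts.

## Enrichment

Unordered over-representation by the hypergeometric upper tail
`P(X ≥ overlap)` with population = background (all detected proteins),
successes = in-background set members, draws = query (all up- or all
down-regulated proteins, kept in order of decreasing |log2 FC|). Sets
with in-background size < 3 are never tested. BH adjustment runs within
each query direction. Significant terms are then demoted when the overlap
is < 5 % of the set's in-background size or ≤ 1 gene — the published
intersection-filter sentence is ambiguous ("<5 % … or less than one
gene"); this reading removes trivially supported terms and both
thresholds are configurable. Terms with identical matched gene lists
within the same branch (and direction) collapse to the lowest-raw-p term,
ties broken lexicographically; the reduction is idempotent. Category
proportions are computed over the merged up+down significant sets, each
distinct set counted once, with uniform weights unless representative
weights are supplied; unmapped sets fall into "other terms". An ordered
(rank-threshold) query mode exists as an option: it scans all prefixes of
the ranked list and Bonferroni-corrects each set's best prefix p by the
number of prefixes — a deliberately simple variant, off by default.

## Down-sampling robustness

Each repetition draws `n_subset` (default 17) samples from the larger
group without replacement, refits the two-group moderated model against
all control samples — the variance prior re-estimated within the
repetition, since each repetition stands for an independent analysis —
and counts adjusted p < 0.05. Imputation is performed once, upstream, not
per draw (the workflow imputes a single time before modeling). The count
vector is compared with a reference count by a two-sided one-sample
t-test; a zero-variance count vector reports p = 1 with a warning instead
of failing.

## Clinical statistics

* Two-sample Wilcoxon rank test: exact for combined n ≤ 50 without ties,
  otherwise normal approximation with tie and continuity correction;
  all-identical inputs return p = 1. One-sample signed-rank: zeros
  dropped, exact for n ≤ 25 without tied magnitudes. Exact p-values are
  pinned against full enumeration oracles for combined n ≤ 8.
* 2×2 chi-squared with Yates correction on by default:
  `Σ (|O−E| − min(0.5, |O−E|))²/E` with 1 df, so the statistic is never
  negative and fully vanishes when every |O−E| < 0.5. The uncorrected
  statistic equals the classical Pearson closed form (property-tested).
  This corrected form reproduces the published cohort table's printed
  categorical p-values (0.22, 0.709, 0.149, 0.321, 1) from the printed
  counts, where the uncorrected statistic does not. A 2×k table with an
  all-zero column (e.g. a "severe" grade nobody has) is analyzed as 2×2
  after dropping that column, since a zero column makes expected counts
  zero. Several other categorical rows of that table are not reproducible
  from the printed counts under any standard chi-squared variant — the
  underlying denominators likely differ due to missing data — and are
  excluded from validation.
* ECV = (1 − hematocrit)·ΔR1_myo/ΔR1_blood with ΔR1 = 1/T1_post −
  1/T1_pre, invariant to common rescaling of all four T1 times; equal
  ΔR1 ratios collapse to 1 − hematocrit. A zero blood ΔR1 is an error.
  aECV = (LV mass / 1.05 g ml⁻¹)·ECV.
* Annotation-median summaries: per-sample median log2 intensity over a
  member set, compared between condition groups by the two-sample
  Wilcoxon test; the MYH6/MYH7 ratio is the per-sample linear-scale ratio
  `2^(log2 MYH6 − log2 MYH7)`.

## Synthetic cohort generator

The generator defines the validation conditions. No generative model is
published for this design, so the simplest model under which the
moderated linear model is well-specified was chosen: protein baselines
uniform on log2 22–34 (matching LFQ magnitudes), additive group effects,
i.i.d. Gaussian residuals (default SD 0.5 on the log2 scale, a typical
between-subject spread for tissue LFQ). Default design: 21/20 (AS f/m),
5/12 (MR), 8/9 (CON); 3,000 proteins, 15 % carrying effects with mixture
AS-specific 0.35, MR-specific 0.10, shared 0.30, divergent 0.05,
sex-only-female 0.10, sex-only-male 0.10 — loosely mirroring the observed
preponderance of AS over MR regulation. Divergent effects are
equal-magnitude, opposite-sign in AS and MR; sex-only effects are planted
in the AS female (resp. male) cell, the condition with the largest sex
cells. Dropout is logistic in intensity
(`P(missing) = logistic(−steepness·(x − midpoint))`, defaults midpoint 23,
steepness 0.8), the standard left-censoring surrogate consistent with
downshift imputation; it concentrates missingness on low-abundance
proteins without erasing the mid-range. All randomness flows from one
seed through named sub-stream generators (baselines, effects, noise,
dropout, gene sets, clinical), so partial reruns reproduce.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide sharing, correlated protein modules, batch effects,
heavy-tailed residuals, and abundance-dependent noise beyond what
imputation induces. Passing recovery tests therefore shows the statistics
are implemented correctly and well-calibrated under the assumed model,
not that real cohorts meet those assumptions.

**Detection-limit attenuation.** With MNAR censoring, a strongly
down-regulated arm of a low-baseline protein loses most of its
observations; downshift imputation replaces them with values near the
sample's detection floor, flattening the planted effect. In simulations
this costs the divergent class 10–20 % of its calls (the censored arm's
versus-control contrast loses significance and the protein is read as
single-condition-specific). This is a property of left-censored LFQ data,
not of the estimator: on complete matrices the planted
AS-specific/shared/divergent classes are recovered essentially perfectly
at |log2 FC| = 4·noise SD. Validation therefore measures recovery on the
complete generated matrix and checks calibration (false discovery
control, p-value uniformity) through the full censor–filter–impute path.

## Problem sizes and numerical choices

Validation runs use 2,000-protein cohorts (null calibration over 20
seeds, recovery over 3, down-sampling at 25 repetitions), sizes at which
every Monte-Carlo margin is comfortable. Tolerances: BH monotonicity at
1e-12, oracle equivalence at 1e-10, limma agreement at 1e-9; the
trigamma inverse iterates Newton steps to relative 1e-10. Degenerate
inputs are first-class: empty filtered tables, samples with < 2 observed
values, rank-deficient designs, zero contingency margins and zero blood
ΔR1 all raise informative errors rather than propagating NaNs.
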