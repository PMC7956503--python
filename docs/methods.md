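# Methods

`uvep` implements a label-free spectral-count proteomics workflow for
small clinical cohorts: from per-run protein identification lists to a
proteome-based stratification of subjects, a compact marker panel, and a
statistical link to a measured phenotype (respiratory impedance). This
note records the model behind each stage, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions.

## Quantification model

The quantity carried through the pipeline is the spectral count (SpC,
also called PSM count): the number of MS/MS spectra assigned to a
protein in one LC-MS/MS run. SpC is a semiquantitative proxy for
relative protein abundance; it is integer-valued, long-tailed across
proteins, and overdispersed across technical replicates.

**Alignment.** Per-run protein lists are aligned into a proteins x runs
matrix over the union of accessions. A protein absent from a run's list
is a structural zero — it was not identified, which for count data is
evidence of low abundance, not a value missing at random — so no
imputation is performed.

**Normalization.** Each run column is scaled so its total count equals
the grand mean of the original column totals (total-count scaling). This
corrects injection and acquisition-depth differences while preserving
within-run protein ratios and ranks; it is idempotent and leaves a
provenance record on the matrix. More elaborate schemes (e.g. NSAF-type
length normalization) need protein lengths, which the run tables do not
carry, and are out of scope.

**Detection-frequency filter.** A protein is kept if it was detected
(raw count > 0, judged before normalization) in strictly more than
`min_frac` of runs (default 0.25; with 42 runs this means at least 11).
Filtering on raw detection makes the filter outcome independent of
whether normalization ran first.

**Replicate QC and averaging.** Each subject contributes two technical
replicates. QC computes, over proteins detected in either replicate, the
Pearson correlation and the least-squares slope of replicate 2 on
replicate 1; the defaults flag correlation < 0.8 or slope outside
[0.8, 1.25]. QC is flag-only — subjects are never dropped automatically,
because exclusion is a study-level decision. Replicates are then
averaged to per-subject aSpC; with two replicates everywhere, total
matrix mass exactly halves.

## Stratification

Subjects are clustered by Ward's minimum-variance criterion on Euclidean
distances between their protein profiles, and the dendrogram is cut at
`k` clusters (default 3). Labels A, B, C, ... are assigned canonically —
clusters ordered by decreasing size, ties by smallest member id — so the
output is independent of input order.

The user-facing default clusters the matrix as prepared (no transform).
A `log2p1` option applies log2(x + 1) first: Euclidean distance on raw
counts is dominated by the few most abundant proteins, whose replicate
noise scales with abundance, and the log transform stabilizes the
variance. The end-to-end recovery harness and the worked examples use
`log2p1` for exactly this reason; on simulated cohorts raw-count
clustering recovers planted structure unreliably while log-scale
clustering recovers it essentially always.

## Differential expression: DAve and DCI

For two conditions with group-mean aSpC values X and Y per protein:

- DAve = 2(X − Y)/(X + Y), the difference scaled by the mean, bounded in
  [−2, 2] with ±2 attained exactly when the protein is absent on one
  side; DAve(0, 0) is defined as 0 (no signal either way).
- DCI = (X + Y)(X − Y)/2, the difference weighted by total abundance,
  which separates confident changes of abundant proteins from
  noise-level flips of rare ones.

A protein is a DEP for one pairwise comparison when |DAve| > 0.2 and
|DCI| > 5 (both strict); the pooled DEP set is the union over all
pairwise group comparisons. Cluster-of-differentiation markers are
reported at the stricter |DCI| > 10. Both indices are antisymmetric;
DAve is scale-invariant while DCI scales quadratically, which is why the
two thresholds act as a relative and an absolute gate respectively.

## Discriminant screen and LDA

Each protein is screened by a one-way ANOVA F-ratio across the
stratified groups on aSpC, with the p-value from the F distribution
(df = G − 1, N − G); defaults F ≥ 5 and p ≤ 0.01 (non-strict). A protein
constant everywhere has an undefined F and is never selected. With two
groups the F statistic is exactly the square of the pooled-variance
two-sample t statistic, which the tests exploit as an oracle.

The multivariate LDA is fitted on the surviving proteins with one pooled
within-group covariance common to all groups, and subjects are assigned
to the group centroid with minimal Mahalanobis distance. Because the
protein count typically exceeds the subject count, the pooled covariance
is singular; it is regularized by shrinkage toward its own diagonal,
S = (1 − λ) S_pooled + λ diag(S_pooled) with λ = 0.5 by default
(configurable), plus a tiny ridge (1e-8 of the mean diagonal) so
duplicated or zero-variance proteins cannot break the inversion. λ = 0.5
is the neutral midpoint between the empirical covariance and its
diagonal; with ~20 subjects and dozens of proteins the off-diagonal
estimates are noisy enough that equal weighting is a reasonable prior,
and the assignment is not sensitive to λ in the separable regimes the
screen produces. Canonical discriminant axes (eigenvectors of
S⁻¹ B, at most min(G − 1, p)) are exposed for score plots. Exact
distance ties are broken by canonical label order and logged.

## Marker panel and alpha-value typing

Discriminants are intersected with the DEP set; the panel nomination
ranks the intersection by each protein's largest |DAve| over all
pairwise comparisons and draws proteins round-robin across their
*characteristic group* (the group with the highest mean aSpC) until the
panel size (default 6) is reached. The balancing step matters: a panel
whose proteins all characterize one group carries no information for
separating the remaining groups, and plain top-k ranking does produce
such panels on some simulated cohorts (alpha-typing accuracy dropped to
~0.6 when it happened). With balancing, typing accuracy on simulated
cohorts at fold change 4 is 1.0 across all tested seeds.

The alpha-value of panel protein p in subject i is the within-subject
panel-relative abundance, α_i(p) = aSpC_i(p) / Σ_q aSpC_i(q), a
composition on the simplex that is invariant to any global rescaling of
the subject's counts. Subjects with zero panel total are flagged
degenerate and given the uniform profile. Typing assigns each subject to
the nearest group reference centroid (per-group mean alpha profile,
renormalized) in Euclidean distance, recording the margin to the
runner-up; the nearest-centroid rule generalizes qualitative
"protein X high in group Y" descriptions. The alpha formula is isolated
behind one function so an alternative weighting can be swapped in.

## Phenotype linkage

Respiratory impedance enters as per-subject Z-scores of Rrs6/8/10,
Xrs6/8/10 and AX (computed upstream from reference equations; this
package consumes them as given). Per variable, groups are compared with
the tie-corrected Kruskal–Wallis H (p from chi-squared, df = G − 1),
followed by Dunn's pairwise z tests on the pooled ranks with Holm
adjustment over the G(G − 1)/2 pairs of that variable. Dunn/Holm is the
standard follow-up when the global test is rank-based; the method enum
leaves room for alternatives. Holm is implemented in-package (step-down
with a monotonicity-enforcing running maximum) and cross-checked against
statsmodels in the tests.

Categorical cohort characteristics are compared with the 2x2 chi-squared
test with Yates continuity correction truncated at zero:
χ² = Σ max(|O − E| − 0.5, 0)² / E, p from chi-squared with 1 df. The
truncation means deviations smaller than the half-count correction give
exactly χ² = 0, p = 1. This variant (the R `chisq.test` default)
reproduces the published cohort-table p-values from their printed counts
to three decimals, which the uncorrected statistic does not. A zero
row or column margin leaves the expected count undefined and is an
error. Cohort tables use per-row pairwise-complete denominators so a
missing answer in one covariate does not shrink the others.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at the study's scale:

| parameter | default | meaning |
|---|---|---|
| subjects_per_group | [9, 6, 6] | three latent groups, 21 subjects |
| replicates | 2 | technical replicates per subject (42 runs) |
| n_proteins | 1200 | catalog size, ~1100 surviving the 25% filter |
| baseline_log_mean / sd | 1.0 / 1.5 | log-normal baseline means (long tail) |
| dispersion | 0.05 | NB overdispersion φ in Var = μ + φμ² |
| marker_frac_per_group | 0.01 | 12 planted markers per group, disjoint |
| fold_change | 4 | marker mean multiplier in its own group |
| marker_min_baseline | 2.0 | markers drawn from quantifiable proteins |
| run_size_factor_sd | 0.1 | log-normal per-run depth factor |
| fot_group_shift | ±1.5 pattern | planted impedance shifts per group |
| fot_noise_sd | 1.0 | Z-score noise around the shift |

Counts are negative-binomial because spectral counts are overdispersed
relative to Poisson; φ = 0.05 gives technical-replicate correlation
≈ 0.94 and regression slope ≈ 0.96 across seeds, matching the
replicates-near-identity structure real runs show, while still far from
Poisson for abundant proteins. Markers are up-regulated one-vs-rest in
their own group only, and are drawn only from proteins with baseline
mean ≥ 2 — a marker is by definition a measurable protein, and planting
markers below the detection floor would test the assay floor rather than
the method. Replicate pairs share a subject's expected means but draw
independent size factors and counts. The default impedance shifts give
the first group higher resistance / lower reactance / higher AX and the
last group the opposite, with the middle group at zero. All randomness
flows from the single config seed.

What the generator does **not** emulate: peptide-level identification
and protein inference, shared-peptide ambiguity, correlated protein
modules (proteins are independent given group), batch or acquisition
drift across runs, heavy zero-inflation beyond what the NB produces, and
any real biological covariance between the proteome and impedance —
the FOT link is planted directly on the group labels. Passing recovery
tests therefore shows the pipeline recovers the structure it assumes;
it does not certify performance on real cohorts where those assumptions
are violated.

## Problem sizes and numerical conventions

The recovery analyses run at the study scale (21 subjects, 42 runs,
1200 proteins), which completes in under a second per replicate; the
null calibration of the Kruskal–Wallis test uses 2000 replicates of
7 + 7 + 7 normal observations. Normalization equalizes column totals to
relative tolerance 1e-9 and is asserted idempotent at the same
tolerance. Ward merge heights are checked non-decreasing on every
dendrogram. All exact distance ties (LDA and alpha typing) break by
canonical label order and are logged, never silent. Frequency and
DAve/DCI thresholds are strict inequalities; the F-screen thresholds are
non-strict (F ≥ 5, p ≤ 0.01). Pipeline outputs are deterministic:
identical config and inputs produce byte-identical files.

## Known limitations

- Total-count normalization is a stated stand-in where the upstream
  normalization of the original protocol is not fully specified.
- The covariance shrinkage weight is a pragmatic default, not estimated
  from data (no Ledoit–Wolf style optimization).
- No cross-validated error estimate for the LDA (training-set
  assignment only), and no cluster-number selection — k is a config
  choice.
- The alpha-typing reference centroids are derived from the same
  subjects they then type in the round-trip check; honest external
  validity needs a held-out cohort.
- Count moderation (shrinkage variance models as in modern count-based
  differential tools) is deliberately out of scope; DAve/DCI are
  threshold rules, not calibrated tests.
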