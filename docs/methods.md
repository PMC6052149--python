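# Methods

## Problem and scope

Untargeted GC-TOF-MS profiling of urine headspace yields a peaks × samples
intensity table with substantial missingness and arbitrary per-sample scale.
The question is which volatile metabolites differ between a case group
(e.g. interstitial-cystitis patients) and controls, with an honest false
discovery rate at small n (typically 10 per group). vocdiff implements the
tabular pipeline: detection filtering, total-metabolome normalization, an
integrative three-test permutation procedure with Stouffer combination and
Storey FDR, compound/pathway annotation, and a microarray DEG + GO
companion for follow-up expression experiments. Instrument-side steps (peak
detection, deconvolution, spectral identification) are out of scope; the
package consumes a quantified peak table.

## Preprocessing

* **Detection filter.** A peak is retained when it is quantified in strictly
  more than half of the samples of *each* group (with n = 10 per group:
  ≥ 6 observed in both). Strict inequality is the literal reading of "more
  than half"; the filter is idempotent and does not alter values.
* **mTIC normalization.** Each sample's observed intensities are divided by
  that sample's sum of observed intensities (the "total identified volatile
  metabolome"). Missing cells are excluded from the sum — a censored value
  is unknown, not zero, and zero-filling would bias small samples — and stay
  missing. The transform is invariant to per-sample scale factors.
* **Quantile normalization** (QC only). Classic rank-mean normalization:
  the k-th smallest value in each sample is replaced by the mean of the k-th
  smallest values across samples; ties receive the mean of the reference
  values at the tied ranks (fractional ranks interpolate). It refuses tables
  with missing values rather than imputing silently. It is not part of the
  default testing path: the analysis normalization is mTIC, and quantile
  normalization is kept as the quality-assessment transform, switchable in
  the CLI.

Pipeline order is detection filter → mTIC → testing. Filtering first means
the mTIC denominator is the sum over retained identified peaks.

## The integrative differential test

Per peak, on observed values only (missing cells are omitted pairwise and
permutations shuffle the observed-value labels):

* **Component statistics.** Welch t (unequal variances — the safer default,
  and second-order anyway under a permutation null); the log2-median-ratio
  LMR = log2(median_case / median_control), the literal reading of the
  test's name; and the Wilcoxon rank-sum statistic.
* **Permutation nulls.** Group labels are permuted B times (default
  10,000); when the number of distinct assignments C(n, n₁) is at most
  20,000 all assignments are enumerated and p-values are exact proportions
  #{|T_b| ≥ |T_obs|}/N (the identity assignment guarantees p > 0). Sampled
  p-values use the add-one rule (1 + #{|T_b| ≥ |T_obs|})/(B + 1), so they
  are never zero. A 10 + 10 design has C(20,10) = 184,756 assignments and
  therefore uses sampling; designs up to 6 + 6 are exhaustive. The reported
  Wilcoxon p-value comes from the standard rank-sum test (exact enumeration
  for untied data within the threshold, otherwise the normal approximation
  with tie and continuity corrections).
* **Stouffer combination.** Each two-tailed p becomes a signed z,
  z_i = sign_i · Φ⁻¹(1 − p_i/2), where the sign is the component's own
  effect direction (t: sign of the statistic; LMR: its own sign; Wilcoxon:
  the rank-sum direction). Concordant tests reinforce, discordant tests
  cancel. Equal weights, divisor √3.
* **Calibration of the combined statistic.** The three component tests are
  computed on the *same* data, so their z-scores are strongly positively
  correlated and the naive normal-theory combined p, 2(1 − Φ(|z|)), is
  badly anti-conservative: its measured type-I error at α = 0.05 is ≈ 0.24
  under the global null in this package's simulations. The default therefore
  referees the combined z against its own permutation null — for every label
  permutation the three statistics are converted to empirical p-values and
  signs within the same permutation set, combined identically, and the
  adjusted p-value is the two-tailed empirical p of the observed combined z.
  Because the same permutations drive all three components, the dependence
  between the tests is carried into the null and the combined test is
  calibrated (measured size ≈ 0.05). The normal-theory combination remains
  available (`combined_null="normal"`) for comparison, and the closed-form
  `stouffer_combine` op implements it directly.
* **Storey q-values.** π̂₀ = #{p > λ}/((1 − λ)m) at a fixed λ = 0.5, capped
  at 1 and floored at 1/m (so q-values never reach 0 and the m = 1 case
  degenerates to q = p). The single-λ estimator is preferred over the
  λ-grid spline for reproducibility and small-m robustness; with π₀ = 1 the
  q-values coincide exactly with Benjamini–Hochberg adjusted p-values.
* **Reported effect sizes.** FC = log2(mean_case / mean_control) computed on
  the normalized values, and SD = pooled standard deviation of the log2
  intensities across both groups. The "SD" convention in such result tables
  is ambiguous (per-group, pooled, of the FC); pooled log2 SD is used here
  and documented as such.
* **Untestable peaks** (fewer than 2 observed values in a group, or
  non-positive medians/means) are reported with a reason code and excluded
  from the q-value computation, never silently dropped. A table with zero
  testable peaks is an error.

## Annotation

CAS registry numbers are validated by syntax (`N{2,7}-NN-N`) and checksum
(digits weighted 1, 2, 3, … from the right, sum mod 10). Validation is
advisory: vendor quantification tables occasionally carry registry numbers
that fail the checksum, so invalid entries are flagged but retained and may
still be mapped. CAS → KEGG and KEGG → pathway mapping are local joins
against user-supplied or bundled tables (no web services, so runs are
reproducible; the funnel counts are mapping-table-dependent by
construction). The funnel n_total ≥ n_with_CAS ≥ n_KEGG ≥ n_pathway is
monotone and order-independent.

## Transcriptomics companion

On a normalized log2 expression matrix: probes with mean log2 signal above
the grand probe mean pass the abundance prefilter (the conventional guard
against unreliable low-intensity probes, and the default enrichment
background); per-contrast Welch t-tests (Satterthwaite df) with linear fold
change 2^|Δmean| give DEGs at p < 0.05 and FC ≥ 1.5 (inclusive, with a
1e-12 numerical tolerance on the boundary because the threshold arrives
through a log2/exp2 round trip). GO-BP over-representation uses the exact
hypergeometric tail P(overlap ≥ k), identical to Fisher's one-sided exact
test; terms are selected at raw p < 0.05 with ≥ 3 DEGs (a BH-adjusted
column is emitted for information only, since the selection rule is defined
on the raw p).

## Synthetic-data generators

The VOC generator draws per-peak log2 intensities Normal(μ_j, σ) with μ_j
uniform on [10, 18] log2 units (peaks span ~2.5 orders of magnitude, as in
GC-MS practice), shifts a chosen fraction of peaks by a signed log2 effect
in the case group only (negative = suppressed in cases), multiplies each
sample by a private scale factor log-uniform in [1/(1+jitter), 1+jitter]
(so mTIC normalization is non-trivial), then censors cells below each
peak's `lod_quantile` intensity quantile and drops cells independently at
`missing_rate`. Defaults (10 vs 10 samples, 113 peaks, 10% differential at
log2 effect −1.467 with σ = 1.381, lod_quantile 0.2, missing_rate 0.05,
jitter 0.25) emulate the target study design; the missingness rates are
conventional placeholders, since studies rarely report them. A single seed
drives one generator; all outputs are bitwise reproducible. The expression
generator draws probe baselines uniform on log2 [4, 12] and shifts
differential probes by the given effect in every non-reference condition.

What the simulations do *not* emulate: retention-time drift, batch effects,
heteroscedastic per-peak variances, correlated metabolite families, and
intensity-dependent missingness beyond simple left censoring. Passing the
simulation-based checks therefore establishes the statistical machinery
(calibration, FDR control, power) under the assumed generative model, not
performance on any particular real cohort.

## Measured operating characteristics and a known attenuation effect

At the target design (100 peaks, 10 vs 10, 10 planted effects of log2
−1.467, σ = 1.381, complete data), measured over 100 seeded replicates with
B = 1000:

* each component test and the calibrated combined test hold their size
  (type-I error ≈ 0.042–0.057 at α = 0.05);
* the mean false-discovery proportion among q < 0.1 calls is ≈ 0.13;
* the combined test's per-feature power at α = 0.05 is ≈ 0.52, against a
  closed-form two-sample t reference of ≈ 0.61 for d = 1.467/1.381.

The gap has a specific, instructive cause: all planted effects share one
sign, so the case group's total metabolome is systematically smaller and
mTIC normalization reabsorbs part of the signal — the mean recovered log2
fold change is ≈ −1.35 rather than −1.467 (≈ 8% attenuation, worth ~0.06
of power), with the remainder attributable to the median-ratio component's
lower efficiency at n = 10 and the sample-level noise the normalization
shares across peaks. This is the familiar compositional bias of
total-signal normalization: it is a property of the design (a minority of
same-signed effects), not a defect of the test, and it would affect the
real pipeline identically.

## Problem sizes used in the checks

The test suite and acceptance script run simulations at desk scale chosen
for tight Monte Carlo error: 100 replicates of 100-feature 10 vs 10 studies
(B = 1000) for calibration/FDR/power, 200 replicates of 500-probe n = 3
expression studies for the DEG operating characteristics, 200 features for
the sampled-vs-exhaustive permutation agreement (B = 5000 against the 252
enumerable assignments at 5 + 5), and 500 random instances for the
rank-sum brute-force scan. Default analysis settings are larger
(B = 10,000) than the simulation settings.
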