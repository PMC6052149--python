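# vocdiff

Differential analysis of urinary volatile-organic-compound (VOC) peak tables
from untargeted GC-TOF-MS profiling, built for two-group case/control designs
such as interstitial-cystitis (IC) patients versus healthy controls. The
package covers the full tabular workflow downstream of peak detection:

1. **Preprocessing** — detection filtering (keep peaks quantified in more
   than half of the samples of each group), normalization of each sample to
   its total identified volatile metabolome (mTIC), and rank-mean quantile
   normalization as a QC transform.
2. **Integrative differential testing** — for each peak, three component
   tests (Welch *t*, log2-median-ratio, Wilcoxon rank-sum); the *t* and
   median-ratio statistics are referred to empirical nulls from random
   permutations of the group labels; the three two-tailed p-values are
   combined with Stouffer's method, *z* = (z_t + z_lmr + z_w)/√3 with each
   z_i = sign_i · Φ⁻¹(1 − p_i/2); the combined statistic is calibrated
   against its own permutation null; false discovery rates are Storey
   q-values with the single-λ estimator (λ = 0.5),
   π̂₀ = #{p > λ} / ((1−λ)m) and q_(i) = min_{j≥i} π̂₀ · m · p_(j)/j.
3. **Annotation** — CAS registry-number validation (checksum), CAS → KEGG
   compound mapping and compound → pathway joins against local tables
   (bundled desk-scale fixtures included).
4. **Transcriptomics companion** — Welch-test differential expression on a
   normalized log2 microarray matrix (DEG rule: p < 0.05 and linear fold
   change ≥ 1.5, with an above-average-abundance prefilter) and one-sided
   hypergeometric GO-biological-process over-representation (selected at
   p < 0.05 with ≥ 3 DEGs per term).
5. **Synthetic data** — generators that emulate the statistical structure of
   such studies (log-normal peak intensities, per-sample scale factors,
   left-censored and random missingness, planted log2 effects) with full
   ground truth, so every stage is verifiable at desk scale.

## Worked example

Simulate a 113-peak, 10 vs 10 study with ~10% of peaks suppressed in cases
(log2 FC −2.5), preprocess it and fit the integrative model:

```python
from vocdiff import (VocSimParams, generate_voc_study, detection_filter,
                     mtic_normalize, PermutationConfig, VolatileDifferentialModel)

params = VocSimParams(effect_log2=-2.5, seed=7)
table, truth = generate_voc_study(params)
prepared = mtic_normalize(detection_filter(table))
model = VolatileDifferentialModel(
    prepared, PermutationConfig(n_permutations=10_000, seed=7)
)
results = model.fit(fdr_threshold=0.1)
print(results.summary())
```

```
Integrative differential test (permutation t + log2-median-ratio + Wilcoxon, Stouffer combination, Storey FDR)
peaks tested: 105 of 105 | permutations: 10000 (exhaustive <= 20000 assignments) | seed: 7 | combined null: permutation
significant at FDR < 0.1: 2

               p_t   p_lmr  p_wilcoxon  z_combined  p_adjusted  q_value  fc_log2      sd
feature_id
peak_062    0.0005  0.0044      0.0002     -5.7698      0.0004   0.0352  -4.0544  1.4551
peak_096    0.0016  0.0030      0.0048     -5.1642      0.0016   0.0751  -2.7373  1.2178
```

Reading the output: 8 of the 113 simulated peaks failed the detection filter
(too many missing values), leaving 105 tested. Two peaks clear FDR < 0.1;
both are genuinely planted (`truth` confirms), both suppressed in cases
(negative log2 fold change), with the three component p-values, the signed
combined z, the permutation-calibrated combined p (`p_adjusted`) and the
Storey q-value shown per peak. `results.frame` holds the full per-peak
table, including untestable peaks with a reason code.

The same pipeline is available from the shell:

```bash
vocdiff simulate-voc --seed 7 values.tsv groups.tsv truth.tsv
vocdiff run-all --seed 7 --permutations 10000 values.tsv groups.tsv out
# -> out.results.tsv, out.report.json (funnel counts, thresholds, seed)
```

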