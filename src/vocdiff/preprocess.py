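"""Peak-table preprocessing: detection filtering and normalization.

The default analysis path is ``detection_filter`` -> ``mtic_normalize`` ->
differential testing. Quantile normalization is provided as a separate QC
transform (it is how quality assessment of the quantification is usually
done) and is deliberately not part of the default testing path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import PeakTable

__all__ = ["detection_filter", "mtic_normalize", "quantile_normalize"]


def detection_filter(table: PeakTable) -> PeakTable:
    """Keep peaks quantified in more than half of the samples of each group.

    "More than half" is a strict inequality: with 10 samples per group a peak
    needs >= 6 observed values in *both* groups to survive. Peak order is
    preserved; the result may be empty.
    """
    observed = table.observed_mask()
    keep = pd.Series(True, index=table.feature_ids)
    for samples in (table.case_samples, table.control_samples):
        counts = observed[samples].sum(axis=1)
        keep &= counts > len(samples) / 2.0
    return PeakTable(table.intensities.loc[keep], table.groups.copy())


def mtic_normalize(table: PeakTable) -> PeakTable:
    """Normalize each sample to its total identified volatile metabolome.

    The per-sample sum of observed peak intensities (mTIC) is the
    denominator; missing cells are excluded from the sum and stay missing.
    After normalization each sample's observed intensities sum to 1.
    """
    sums = table.intensities.sum(axis=0, skipna=True)
    empty = [s for s in table.sample_ids if not np.isfinite(sums[s]) or sums[s] <= 0]
    all_missing = [s for s in table.sample_ids if table.intensities[s].isna().all()]
    if all_missing:
        raise ValueError(f"samples with no observed intensities: {all_missing}")
    if empty:  # defensive; positive-intensity invariant should prevent this
        raise ValueError(f"samples with non-positive mTIC: {empty}")
    return PeakTable(table.intensities.div(sums, axis=1), table.groups.copy())


def quantile_normalize(table: PeakTable) -> PeakTable:
    """Classic rank-mean quantile normalization across samples.

    Each sample's k-th smallest value is replaced by the mean of the k-th
    smallest values over all samples, so afterwards every sample shares an
    identical sorted value vector. Tied values receive the mean of the
    reference values at their tied ranks. Missing values are refused:
    filter (or impute) first.
    """
    values = table.intensities.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "quantile_normalize requires a complete table; "
            "apply detection_filter / imputation before normalizing"
        )
    n_peaks, _ = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(axis=0, method="average").to_numpy()
    # fractional (tied) ranks interpolate between neighbouring reference values
    normalized = np.interp(ranks, np.arange(1, n_peaks + 1), reference)
    out = pd.DataFrame(normalized, index=table.feature_ids, columns=table.sample_ids)
    return PeakTable(out, table.groups.copy())
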