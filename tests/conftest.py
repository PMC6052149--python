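import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vocdiff import PeakTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_peak_table(values, n_case=None, missing=None):
    """Build a small PeakTable from a 2-D list; case samples come first."""
    values = np.asarray(values, dtype=float)
    n_peaks, n_samples = values.shape
    n_case = n_samples // 2 if n_case is None else n_case
    if missing is not None:
        values = values.copy()
        for (i, j) in missing:
            values[i, j] = np.nan
    samples = [f"c{i}" for i in range(n_case)] + [
        f"k{i}" for i in range(n_samples - n_case)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    frame = pd.DataFrame(values, index=[f"p{i}" for i in range(n_peaks)], columns=samples)
    return PeakTable(frame, groups)


@pytest.fixture
def tiny_table():
    return make_peak_table(
        [
            [2.0, 3.0, 5.0, 1.0, 1.0, 2.0],
            [4.0, 4.0, 4.0, 8.0, 8.0, 8.0],
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        ],
        n_case=3,
    )
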