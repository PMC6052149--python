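"""Core in-memory containers and their TSV dialect.

Two tabular containers cover the whole pipeline:

* :class:`PeakTable` — a GC-MS peak quantification table (peaks x samples)
  with explicit missingness (NaN) and a two-group design (case / control).
* :class:`ExpressionMatrix` — a normalized log2 microarray matrix
  (probes x samples) with an arbitrary condition label per sample.

Both serialize to plain TSV: a values file whose first column is the feature
identifier and whose remaining columns are samples, plus a two-column sidecar
mapping sample id to group/condition. Missing cells are written as ``NA`` and
read back from either ``NA`` or the empty string. Lines starting with ``#``
are comments (the CLI writes a provenance header there).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

_NA_VALUES = ["NA", ""]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
    )


def _write_tsv(frame: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", na_rep="NA")


def _read_sidecar(path, value_name: str) -> pd.Series:
    frame = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False
    )
    if frame.shape[1] != 1:
        raise ValueError(
            f"sidecar {path} must have exactly two columns "
            f"(sample id, {value_name}); found {frame.shape[1] + 1}"
        )
    series = frame.iloc[:, 0]
    series.index.name = "sample_id"
    series.name = value_name
    return series


@dataclass
class PeakTable:
    """Peaks x samples intensity matrix with missingness and group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by peak/feature id with one column per sample.
        NaN marks a missing (unquantified) cell; observed values must be
        strictly positive (instrument units are arbitrary).
    groups
        Series mapping each sample id to ``"case"`` or ``"control"``.
    """

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        self.groups = self.groups.astype(str)
        if not self.intensities.index.is_unique:
            raise ValueError("duplicate feature ids in peak table")
        if not self.intensities.columns.is_unique:
            raise ValueError("duplicate sample ids in peak table")
        missing_labels = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing_labels:
            raise ValueError(f"samples without a group label: {missing_labels}")
        self.groups = self.groups.loc[list(self.intensities.columns)]
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control'; found {sorted(bad)}")
        for g in (CASE, CONTROL):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need at least 2 '{g}' samples")
        values = self.intensities.to_numpy()
        observed = ~np.isnan(values)
        if np.any(values[observed] <= 0):
            raise ValueError("observed peak intensities must be strictly positive")

    # -- basic accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def observed_mask(self) -> pd.DataFrame:
        return self.intensities.notna()

    def copy(self) -> "PeakTable":
        return PeakTable(self.intensities.copy(), self.groups.copy())

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, values_path, groups_path, header_comment: str | None = None) -> None:
        _write_tsv(self.intensities.rename_axis("feature_id"), values_path, header_comment)
        _write_tsv(self.groups.rename("group").to_frame(), groups_path, header_comment)

    @classmethod
    def from_tsv(cls, values_path, groups_path) -> "PeakTable":
        return cls(_read_tsv(values_path), _read_sidecar(groups_path, "group"))


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression matrix with condition labels."""

    log2_values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        self.log2_values = self.log2_values.astype(float)
        self.condition = self.condition.astype(str)
        if not self.log2_values.index.is_unique:
            raise ValueError("duplicate probe ids in expression matrix")
        missing_labels = [s for s in self.log2_values.columns if s not in self.condition.index]
        if missing_labels:
            raise ValueError(f"samples without a condition label: {missing_labels}")
        self.condition = self.condition.loc[list(self.log2_values.columns)]
        if not np.all(np.isfinite(self.log2_values.to_numpy())):
            raise ValueError("expression matrix must be finite (no NaN/inf)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.log2_values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.log2_values.columns

    def samples_in(self, condition: str) -> list[str]:
        sel = list(self.condition.index[self.condition == condition])
        if not sel:
            raise ValueError(f"no samples with condition {condition!r}")
        return sel

    def to_tsv(self, values_path, conditions_path, header_comment: str | None = None) -> None:
        _write_tsv(self.log2_values.rename_axis("probe_id"), values_path, header_comment)
        _write_tsv(self.condition.rename("condition").to_frame(), conditions_path, header_comment)

    @classmethod
    def from_tsv(cls, values_path, conditions_path) -> "ExpressionMatrix":
        return cls(_read_tsv(values_path), _read_sidecar(conditions_path, "condition"))
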