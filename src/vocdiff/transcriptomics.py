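"""Microarray differential expression and GO-BP over-representation.

Differentially expressed genes (DEGs) between two conditions are probes with
a two-tailed Welch t-test p-value < 0.05 and linear fold change >= 1.5
(computed from the difference of mean log2 signals). An optional
above-average-abundance prefilter keeps probes whose mean log2 signal
exceeds the grand mean over all probes — the conventional guard against
unreliable low-intensity probes.

Over-representation of Gene Ontology Biological Process terms in a DEG list
is scored with the one-sided hypergeometric tail (equivalently Fisher's
exact test); terms with p < 0.05 and at least 3 DEGs are selected.

``ExpressionContrastModel(matrix, ("C", "LPS")).fit()`` is the model-style
entry point; ``welch_deg`` / ``abundance_filter`` / ``gobp_enrichment`` are
the functional surface.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import ExpressionMatrix

__all__ = [
    "abundance_filter",
    "welch_deg",
    "gobp_enrichment",
    "ExpressionContrastModel",
    "DEGResults",
]

# tolerance for the inclusive fold-change boundary (2**log2(1.5) round-trip)
_FC_EPS = 1e-12


def abundance_filter(matrix: ExpressionMatrix) -> pd.Index:
    """Probes whose mean log2 signal strictly exceeds the grand probe mean."""
    probe_means = matrix.log2_values.mean(axis=1)
    return matrix.probe_ids[probe_means > probe_means.mean()]


def welch_deg(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    abundance_pass: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-probe Welch test and fold change for the contrast a vs b.

    ``fc_linear`` is ``2**|mean_a - mean_b|`` (always >= 1) with
    ``direction`` +1 when the probe is higher in ``condition_a``. ``is_deg``
    requires p < ``p_threshold``, fold change >= ``fc_threshold`` (inclusive)
    and, when ``abundance_pass`` is given, membership in that probe set;
    when it is None the abundance prefilter is simply not applied.
    """
    a_cols = matrix.samples_in(condition_a)
    b_cols = matrix.samples_in(condition_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for the Welch test")
    A = matrix.log2_values[a_cols].to_numpy()
    B = matrix.log2_values[b_cols].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    delta = A.mean(axis=1) - B.mean(axis=1)
    # identical constant groups: 0/0 -> NaN; no evidence of change
    p = np.where(np.isnan(p) & (delta == 0), 1.0, p)

    fc_linear = np.exp2(np.abs(delta))
    direction = np.sign(delta).astype(int)
    frame = pd.DataFrame(
        {
            "p_value": p,
            "fc_linear": fc_linear,
            "direction": direction,
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
        },
        index=matrix.probe_ids.rename("probe_id"),
    )
    if abundance_pass is None:
        frame["passes_abundance"] = True
    else:
        frame["passes_abundance"] = frame.index.isin(abundance_pass)
    frame["is_deg"] = (
        (frame["p_value"] < p_threshold)
        & (frame["fc_linear"] >= fc_threshold - _FC_EPS)
        & frame["passes_abundance"]
    )
    return frame


def gobp_enrichment(
    deg_ids,
    background_ids,
    term_table: pd.DataFrame,
    p_threshold: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    ``term_table`` needs columns ``term_id`` and ``gene_id`` (``term_name``
    optional). Gene sets are intersected with the background before testing.
    ``p_value`` is P(overlap >= observed); ``selected`` marks terms with
    p < ``p_threshold`` and overlap >= ``min_overlap``. A Benjamini-Hochberg
    column (``p_bh``) is included for information only — selection uses the
    raw p as stated. Results are sorted by p.
    """
    background = pd.Index(pd.unique(pd.Series(list(background_ids))))
    degs = pd.Index(pd.unique(pd.Series(list(deg_ids)))) if len(list(deg_ids)) else pd.Index([])
    if len(degs) == 0:
        warnings.warn("empty DEG list: enrichment result is empty", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "n_deg_in_term", "n_deg",
                "n_background_in_term", "n_background", "p_value", "p_bh", "selected",
            ]
        )
    if not degs.isin(background).all():
        raise ValueError("deg_ids must be a subset of background_ids")

    N, n = len(background), len(degs)
    has_names = "term_name" in term_table.columns
    rows = []
    for term_id, sub in term_table.groupby("term_id", sort=True):
        genes = pd.Index(pd.unique(sub["gene_id"]))
        in_bg = genes[genes.isin(background)]
        K = len(in_bg)
        if K == 0:
            continue
        k = int(in_bg.isin(degs).sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": sub["term_name"].iloc[0] if has_names else "",
                "n_deg_in_term": k,
                "n_deg": n,
                "n_background_in_term": K,
                "n_background": N,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        warnings.warn("no term overlaps the background", stacklevel=2)
        result["p_bh"] = pd.Series(dtype=float)
        result["selected"] = pd.Series(dtype=bool)
        return result
    result["p_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["selected"] = (result["p_value"] < p_threshold) & (
        result["n_deg_in_term"] >= min_overlap
    )
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)


def read_gmt(path) -> pd.DataFrame:
    """Read a GMT gene-set file into a (term_id, term_name, gene_id) frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term_id, term_name, genes = parts[0], parts[1], parts[2:]
            rows.extend((term_id, term_name, g) for g in genes if g)
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])


class DEGResults:
    """Results of one expression contrast: per-probe records + counts."""

    def __init__(self, frame: pd.DataFrame, contrast: tuple[str, str],
                 background: pd.Index, p_threshold: float, fc_threshold: float):
        self.frame = frame
        self.contrast = contrast
        self.background = background
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold

    @property
    def deg_ids(self) -> pd.Index:
        return self.frame.index[self.frame["is_deg"]]

    @property
    def n_up(self) -> int:
        return int((self.frame["is_deg"] & (self.frame["direction"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["is_deg"] & (self.frame["direction"] < 0)).sum())

    def enrich(self, term_table: pd.DataFrame, p_threshold: float = 0.05,
               min_overlap: int = 3) -> pd.DataFrame:
        return gobp_enrichment(
            self.deg_ids, self.background, term_table,
            p_threshold=p_threshold, min_overlap=min_overlap,
        )

    def summary(self) -> str:
        a, b = self.contrast
        return "\n".join(
            [
                f"Welch DEG analysis: {a} vs {b}",
                f"probes tested: {len(self.frame)} | background: {len(self.background)}",
                f"DEG rule: p < {self.p_threshold}, fold change >= {self.fc_threshold}",
                f"DEGs: {len(self.deg_ids)} (up in {a}: {self.n_up}, down: {self.n_down})",
            ]
        )


class ExpressionContrastModel:
    """Welch DEG model for one two-condition contrast of an expression matrix.

    With ``apply_abundance_filter=True`` (default) the probe universe — both
    the tested probes and the enrichment background — is restricted to probes
    whose mean log2 signal is above the grand probe mean.
    """

    def __init__(self, matrix: ExpressionMatrix, contrast: tuple[str, str],
                 apply_abundance_filter: bool = True):
        self.matrix = matrix
        self.contrast = tuple(contrast)
        self.apply_abundance_filter = apply_abundance_filter

    def fit(self, p_threshold: float = 0.05, fc_threshold: float = 1.5) -> DEGResults:
        a, b = self.contrast
        if self.apply_abundance_filter:
            background = abundance_filter(self.matrix)
        else:
            background = self.matrix.probe_ids
        frame = welch_deg(
            self.matrix, a, b,
            p_threshold=p_threshold, fc_threshold=fc_threshold,
            abundance_pass=background if self.apply_abundance_filter else None,
        )
        return DEGResults(frame, self.contrast, background, p_threshold, fc_threshold)
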