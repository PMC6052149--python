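"""Integrative differential testing for two-group peak tables.

The procedure applied to each peak:

1. Three component tests — a Welch t statistic, the log2 ratio of group
   medians (LMR), and the Wilcoxon rank-sum test. The t and LMR statistics
   are referred to an empirical null obtained by permuting group labels; the
   rank-sum test has its own exact/asymptotic null.
2. The three two-tailed p-values are converted to signed z-scores (sign =
   each test's own effect direction) and combined with Stouffer's method,
   z = (z_t + z_lmr + z_w) / sqrt(3).
3. The combined statistic is itself calibrated against its permutation null
   (the same label permutations, so the dependence between the three
   component tests is carried into the null), yielding the adjusted p-value.
   A normal-theory alternative (2*(1-Phi(|z|))) is switchable but is
   anti-conservative because the components are computed on the same data.
4. Storey q-values (single-lambda pi0 estimate at lambda = 0.5) convert
   adjusted p-values into false-discovery-rate estimates.

The model/results interface mirrors statsmodels:
``VolatileDifferentialModel(table, config).fit()`` returns a
:class:`VolatileDifferentialResults` with the per-peak table, funnel counts
and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PeakTable

__all__ = [
    "PermutationConfig",
    "t_statistic",
    "log2_median_ratio",
    "fold_change_sd",
    "wilcoxon_ranksum_p",
    "permutation_pvalue",
    "stouffer_combine",
    "storey_qvalues",
    "differential_analysis",
    "VolatileDifferentialModel",
    "VolatileDifferentialResults",
]

_SQRT3 = math.sqrt(3.0)
_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-null settings.

    ``n_permutations`` label shuffles are sampled unless the number of
    distinct case/control assignments is at most ``exhaustive_threshold``,
    in which case all assignments are enumerated and p-values are exact
    proportions. With 10 + 10 samples there are C(20,10) = 184,756
    assignments, so the default threshold leaves that design on the sampled
    path; designs up to roughly 6 + 6 are enumerated.
    """

    n_permutations: int = 10_000
    seed: int = 0
    exhaustive_threshold: int = 20_000

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.exhaustive_threshold < 1:
            raise ValueError("exhaustive_threshold must be positive")


class UntestableFeature(ValueError):
    """Raised when a single feature cannot be tested (too few observations)."""


# ---------------------------------------------------------------------------
# Component statistics
# ---------------------------------------------------------------------------

def _welch_rows(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Welch t for row-aligned 2-D blocks (rows = permutations)."""
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    # 0/0 (both groups constant and equal) is a null result, not an error
    t = np.where((se2 == 0) & (diff == 0), 0.0, t)
    return t


def _lmr_rows(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    med_c = np.median(case, axis=1)
    med_k = np.median(control, axis=1)
    if np.any(med_c <= 0) or np.any(med_k <= 0):
        raise UntestableFeature("log2-median-ratio requires positive group medians")
    return np.log2(med_c) - np.log2(med_k)


def t_statistic(case, control) -> float:
    """Two-sample Welch t statistic, positive when the case mean is larger."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise UntestableFeature("t statistic needs >= 2 observed values per group")
    return float(_welch_rows(case[None, :], control[None, :])[0])


def log2_median_ratio(case, control) -> float:
    """log2( median(case) / median(control) )."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 1 or control.size < 1:
        raise UntestableFeature("log2-median-ratio needs >= 1 observed value per group")
    return float(_lmr_rows(case[None, :], control[None, :])[0])


def fold_change_sd(case, control) -> tuple[float, float]:
    """log2 fold change of group means and pooled SD of log2 intensities."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise UntestableFeature("fold change needs >= 2 observed values per group")
    if case.mean() <= 0 or control.mean() <= 0:
        raise UntestableFeature("fold change requires positive group means")
    fc = float(np.log2(case.mean()) - np.log2(control.mean()))
    lc, lk = np.log2(case), np.log2(control)
    n1, n2 = case.size, control.size
    pooled_var = ((n1 - 1) * lc.var(ddof=1) + (n2 - 1) * lk.var(ddof=1)) / (n1 + n2 - 2)
    return fc, float(np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _perm_indices(
    n: int, n1: int, config: PermutationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Index matrix of label assignments: rows are permutations, the first
    ``n1`` columns index the permuted case group. Returns (idx, exhaustive).
    Exhaustive enumeration includes the identity assignment."""
    total = math.comb(n, n1)
    if total <= config.exhaustive_threshold:
        case_sets = np.array(list(combinations(range(n), n1)), dtype=np.intp)
        mask = np.zeros((total, n), dtype=bool)
        np.put_along_axis(mask, case_sets, True, axis=1)
        # stable argsort over ~mask puts case columns first, original order kept
        idx = np.argsort(~mask, axis=1, kind="stable")
        return idx, True
    base = np.tile(np.arange(n, dtype=np.intp), (config.n_permutations, 1))
    idx = rng.permuted(base, axis=1)
    return idx, False


def _empirical_p(abs_null: np.ndarray, abs_obs, exhaustive: bool) -> np.ndarray:
    """Two-tailed empirical p of |T_obs| against the permutation |T| values.

    Exhaustive: exact proportion #{|T_b| >= |T_obs|} / N (the identity
    assignment is enumerated, so p > 0). Sampled: add-one rule
    (1 + #{|T_b| >= |T_obs|}) / (B + 1).
    """
    abs_obs = np.atleast_1d(abs_obs)
    counts = (abs_null[None, :] >= abs_obs[:, None]).sum(axis=1)
    if exhaustive:
        p = counts / abs_null.size
    else:
        p = (1.0 + counts) / (abs_null.size + 1.0)
    return p


def _self_inclusive_p(abs_values: np.ndarray, exhaustive: bool) -> np.ndarray:
    """Empirical p of each permutation's own statistic within the null set."""
    ranks = stats.rankdata(abs_values, method="min")
    count_ge = abs_values.size - ranks + 1
    if exhaustive:
        return count_ge / abs_values.size
    return (1.0 + count_ge) / (abs_values.size + 1.0)


def permutation_pvalue(values, labels, statistic, config: PermutationConfig) -> float:
    """Two-tailed permutation p-value of a two-sample statistic.

    ``labels`` assigns each value to one of exactly two groups; the first
    label encountered is treated as the case group. ``statistic`` is either
    one of the built-in names ``"t"``, ``"lmr"``, ``"mean_diff"`` (vectorized)
    or a callable ``statistic(case_values, control_values) -> float``.
    All-constant data returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two groups")
    case_mask = labels == uniq[0]
    n, n1 = values.size, int(case_mask.sum())
    if np.all(values == values[0]):
        return 1.0

    # reorder so the first n1 positions are the observed case group
    order = np.concatenate([np.nonzero(case_mask)[0], np.nonzero(~case_mask)[0]])
    v = values[order]

    rng = np.random.default_rng(config.seed)
    idx, exhaustive = _perm_indices(n, n1, config, rng)
    vc, vk = v[idx[:, :n1]], v[idx[:, n1:]]
    v_obs_c, v_obs_k = v[None, :n1], v[None, n1:]

    if statistic == "t":
        null = _welch_rows(vc, vk)
        obs = _welch_rows(v_obs_c, v_obs_k)
    elif statistic == "lmr":
        null = _lmr_rows(vc, vk)
        obs = _lmr_rows(v_obs_c, v_obs_k)
    elif statistic == "mean_diff":
        null = vc.mean(axis=1) - vk.mean(axis=1)
        obs = v_obs_c.mean(axis=1) - v_obs_k.mean(axis=1)
    elif callable(statistic):
        null = np.array([statistic(row_c, row_k) for row_c, row_k in zip(vc, vk)])
        obs = np.array([statistic(v_obs_c[0], v_obs_k[0])])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return float(_empirical_p(np.abs(null), np.abs(obs), exhaustive)[0])


def wilcoxon_ranksum_p(case, control, exhaustive_threshold: int = 20_000) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the data are untied and the number of label
    assignments is at most ``exhaustive_threshold``; otherwise the normal
    approximation with tie and continuity corrections.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return 1.0
    untied = np.unique(pooled).size == pooled.size
    exact = untied and math.comb(pooled.size, case.size) <= exhaustive_threshold
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Combination and FDR
# ---------------------------------------------------------------------------

def stouffer_combine(p_t, p_lmr, p_wilcoxon, direction_sign) -> tuple[float, float]:
    """Stouffer combination of three two-tailed p-values into a signed z.

    Each p is mapped to z_i = sign_i * Phi^-1(1 - p_i/2); ``direction_sign``
    is a single sign applied to all three components or a sequence of three
    per-component signs (each test's own effect direction). The combined
    statistic is z = sum(z_i)/sqrt(3) and the normal-theory two-tailed
    p_adjusted = 2*(1 - Phi(|z|)), clamped to (0, 1].
    """
    ps = np.array([p_t, p_lmr, p_wilcoxon], dtype=float)
    signs = np.broadcast_to(np.asarray(direction_sign, dtype=float), (3,))
    if np.any(ps <= 0):
        warnings.warn(
            "p-value of 0 passed to stouffer_combine; clamped to the smallest "
            "positive float (permutation p-values cannot be 0 under the "
            "add-one rule)",
            RuntimeWarning,
            stacklevel=2,
        )
        ps = np.maximum(ps, _TINY)
    if np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = float((signs * stats.norm.isf(ps / 2.0)).sum() / _SQRT3)
    p_adj = float(np.clip(2.0 * stats.norm.sf(abs(z)), _TINY, 1.0))
    return z, p_adj


def _stouffer_z_rows(p_mat: np.ndarray, sign_mat: np.ndarray) -> np.ndarray:
    """Vectorized signed Stouffer z over rows of three-column p/sign arrays."""
    z = sign_mat * stats.norm.isf(np.clip(p_mat, _TINY, 1.0) / 2.0)
    return z.sum(axis=1) / _SQRT3


def storey_qvalues(p_values, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = #{p > lambda} / ((1 - lambda) m), capped at 1 and floored at 1/m.
    The q-value of the i-th smallest p is min_{j >= i} pi0 * m * p_(j) / j
    (so with pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values).
    Input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    pi0 = max(min(float(pi0), 1.0), 1.0 / m)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Per-feature integrative test
# ---------------------------------------------------------------------------

def _feature_result(
    case: np.ndarray,
    control: np.ndarray,
    config: PermutationConfig,
    rng: np.random.Generator,
    combined_null: str,
) -> dict:
    """Run the full integrative test on one feature's observed values."""
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise UntestableFeature("fewer than 2 observed values in a group")
    v = np.concatenate([case, control])
    n = v.size
    fc_log2, sd = fold_change_sd(case, control)

    if np.all(v == v[0]):
        return dict(
            p_t=1.0, p_lmr=1.0, p_wilcoxon=1.0, z_combined=0.0, p_adjusted=1.0,
            fc_log2=fc_log2, sd=sd, n_case_obs=n1, n_control_obs=n2,
        )

    idx, exhaustive = _perm_indices(n, n1, config, rng)
    vc, vk = v[idx[:, :n1]], v[idx[:, n1:]]

    t_null = _welch_rows(vc, vk)
    lmr_null = _lmr_rows(vc, vk)
    ranks = stats.rankdata(v)
    w_mu = n1 * (n + 1) / 2.0
    w_null = ranks[idx[:, :n1]].sum(axis=1) - w_mu

    t_obs = _welch_rows(v[None, :n1], v[None, n1:])[0]
    lmr_obs = _lmr_rows(v[None, :n1], v[None, n1:])[0]
    w_obs = ranks[:n1].sum() - w_mu

    p_t = float(_empirical_p(np.abs(t_null), abs(t_obs), exhaustive)[0])
    p_lmr = float(_empirical_p(np.abs(lmr_null), abs(lmr_obs), exhaustive)[0])
    p_w_reported = wilcoxon_ranksum_p(case, control, config.exhaustive_threshold)

    # Signed Stouffer z of the observed data, built from the same empirical
    # p recipe used for every permutation so the combined statistic and its
    # permutation null are exchangeable under H0.
    p_w_internal = float(_empirical_p(np.abs(w_null), abs(w_obs), exhaustive)[0])
    obs_p = np.array([[p_t, p_lmr, p_w_internal]])
    obs_sign = np.sign(np.array([[t_obs, lmr_obs, w_obs]]))
    z_obs = float(_stouffer_z_rows(obs_p, obs_sign)[0])

    if combined_null == "permutation":
        null_p = np.column_stack(
            [
                _self_inclusive_p(np.abs(t_null), exhaustive),
                _self_inclusive_p(np.abs(lmr_null), exhaustive),
                _self_inclusive_p(np.abs(w_null), exhaustive),
            ]
        )
        null_sign = np.sign(np.column_stack([t_null, lmr_null, w_null]))
        z_null = _stouffer_z_rows(null_p, null_sign)
        p_adjusted = float(_empirical_p(np.abs(z_null), abs(z_obs), exhaustive)[0])
    elif combined_null == "normal":
        p_adjusted = float(np.clip(2.0 * stats.norm.sf(abs(z_obs)), _TINY, 1.0))
    else:
        raise ValueError("combined_null must be 'permutation' or 'normal'")

    return dict(
        p_t=p_t, p_lmr=p_lmr, p_wilcoxon=p_w_reported, z_combined=z_obs,
        p_adjusted=p_adjusted, fc_log2=fc_log2, sd=sd,
        n_case_obs=n1, n_control_obs=n2,
    )


_RESULT_COLUMNS = [
    "p_t", "p_lmr", "p_wilcoxon", "z_combined", "p_adjusted", "q_value",
    "fc_log2", "sd", "n_case_obs", "n_control_obs", "testable", "reason",
]


class VolatileDifferentialResults:
    """Results of the integrative differential test.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per input peak with the component p-values, signed combined
        z, adjusted (combined) p, Storey q-value, log2 fold change, pooled
        log2 SD, per-group observation counts, and a testability flag with a
        reason code for untestable peaks. Sorted by q then adjusted p;
        untestable peaks sit at the bottom.
    """

    def __init__(self, frame: pd.DataFrame, config: PermutationConfig,
                 fdr_threshold: float, combined_null: str):
        self.frame = frame
        self.config = config
        self.fdr_threshold = fdr_threshold
        self.combined_null = combined_null

    @property
    def n_tested(self) -> int:
        return int(self.frame["testable"].sum())

    def n_significant(self, fdr_threshold: float | None = None) -> int:
        """Number of tested peaks with q-value below the FDR threshold."""
        th = self.fdr_threshold if fdr_threshold is None else fdr_threshold
        q = self.frame.loc[self.frame["testable"], "q_value"]
        return int((q < th).sum())

    def significant(self, fdr_threshold: float | None = None) -> pd.DataFrame:
        th = self.fdr_threshold if fdr_threshold is None else fdr_threshold
        sub = self.frame[self.frame["testable"]]
        return sub[sub["q_value"] < th]

    def summary(self) -> str:
        lines = [
            "Integrative differential test (permutation t + log2-median-ratio "
            "+ Wilcoxon, Stouffer combination, Storey FDR)",
            f"peaks tested: {self.n_tested} of {len(self.frame)}"
            f" | permutations: {self.config.n_permutations}"
            f" (exhaustive <= {self.config.exhaustive_threshold} assignments)"
            f" | seed: {self.config.seed}"
            f" | combined null: {self.combined_null}",
            f"significant at FDR < {self.fdr_threshold}: "
            f"{self.n_significant()}",
            "",
        ]
        show = self.significant()
        if show.empty:
            show = self.frame[self.frame["testable"]].head(10)
        cols = ["p_t", "p_lmr", "p_wilcoxon", "z_combined", "p_adjusted",
                "q_value", "fc_log2", "sd"]
        lines.append(show[cols].round(4).to_string())
        return "\n".join(lines)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        from .tables import _write_tsv

        _write_tsv(self.frame.rename_axis("feature_id"), path, header_comment)


class VolatileDifferentialModel:
    """Two-group integrative differential-abundance model for a peak table.

    The table is expected to be detection-filtered and mTIC-normalized
    (``vocdiff.preprocess``); the test itself only requires positive
    observed intensities and at least two observations per group per peak.
    Missing values are omitted pairwise: each peak is tested on its observed
    values only, and permutations shuffle the observed-value labels.
    """

    def __init__(self, table: PeakTable, config: PermutationConfig | None = None):
        self.table = table
        self.config = config or PermutationConfig()

    def fit(
        self,
        fdr_threshold: float = 0.1,
        combined_null: str = "permutation",
    ) -> VolatileDifferentialResults:
        table, config = self.table, self.config
        case_cols = table.case_samples
        ctrl_cols = table.control_samples
        values = table.intensities
        seed_seq = np.random.SeedSequence(config.seed)
        children = seed_seq.spawn(table.n_peaks)

        rows: dict[str, dict] = {}
        for i, fid in enumerate(table.feature_ids):
            case = values.loc[fid, case_cols].dropna().to_numpy(dtype=float)
            control = values.loc[fid, ctrl_cols].dropna().to_numpy(dtype=float)
            rng = np.random.default_rng(children[i])
            try:
                rows[fid] = _feature_result(case, control, config, rng, combined_null)
                rows[fid]["testable"] = True
                rows[fid]["reason"] = ""
            except UntestableFeature as exc:
                rows[fid] = dict(
                    testable=False, reason=str(exc),
                    n_case_obs=case.size, n_control_obs=control.size,
                )

        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "feature_id"
        testable = frame["testable"].fillna(False).astype(bool)
        if not testable.any():
            raise ValueError("no testable peaks (all flagged untestable)")
        frame.loc[testable, "q_value"] = storey_qvalues(
            frame.loc[testable, "p_adjusted"].to_numpy()
        )
        frame = frame.reindex(columns=_RESULT_COLUMNS)
        frame = frame.sort_values(
            by=["testable", "q_value", "p_adjusted"],
            ascending=[False, True, True],
            kind="stable",
        )
        return VolatileDifferentialResults(frame, config, fdr_threshold, combined_null)


def differential_analysis(
    table: PeakTable,
    config: PermutationConfig | None = None,
    fdr_threshold: float = 0.1,
    combined_null: str = "permutation",
) -> VolatileDifferentialResults:
    """Convenience wrapper: fit :class:`VolatileDifferentialModel` on a table."""
    return VolatileDifferentialModel(table, config).fit(
        fdr_threshold=fdr_threshold, combined_null=combined_null
    )
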