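"""Synthetic data with the statistical structure of a two-group VOC study.

The generator emulates an untargeted urine-headspace GC-TOF-MS experiment
comparing interstitial-cystitis cases against healthy controls: ~113 peaks
quantified in 10 vs 10 samples, log-normal peak intensities spanning a few
orders of magnitude, per-sample scale factors (so total-metabolome
normalization is non-trivial), left-censored low-abundance cells plus sporadic
random dropout, and a minority of peaks carrying a planted log2 shift in the
case group (the flagship effect size, log2 FC -1.467 with log2 SD 1.381,
matches the magnitude of the strongest reported urinary marker, menthol).

A microarray counterpart simulates a multi-condition macrophage stimulation
experiment (e.g. control / menthol / LPS) for the downstream differential
expression and GO-enrichment stages.

Every generator is fully reproducible from a single integer seed, and returns
a ground-truth table so power and false-discovery behaviour can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CASE, CONTROL, ExpressionMatrix, PeakTable

__all__ = [
    "VocSimParams",
    "generate_voc_study",
    "generate_expression_study",
    "bundled_fixtures",
    "bundled_pathways",
]


@dataclass(frozen=True)
class VocSimParams:
    """Parameters of the simulated two-group VOC peak table.

    Defaults reproduce the study design the package targets: 10 cases vs 10
    controls, 113 peaks, a ~10% minority of differential peaks shifted by
    log2 FC -1.467 in cases, per-peak log2 SD 1.381. ``lod_quantile`` and
    ``missing_rate`` control the two missingness mechanisms (left censoring
    at a per-peak limit of detection, and random dropout); the deposited
    study does not report its missingness rate, so these defaults are
    conventional placeholders for GC-MS practice rather than measured values.
    """

    n_case: int = 10
    n_control: int = 10
    n_peaks: int = 113
    frac_differential: float = 0.1
    effect_log2: float = -1.467
    sigma_log2: float = 1.381
    lod_quantile: float = 0.2
    missing_rate: float = 0.05
    scale_jitter: float = 0.25
    seed: int = 0
    # log2 range of per-peak mean intensity; wide enough that peaks span
    # roughly 2.5 orders of magnitude, as in typical GC-MS peak tables.
    mu_log2_range: tuple[float, float] = (10.0, 18.0)

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be positive")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be positive")
        if self.scale_jitter < 0:
            raise ValueError("scale_jitter must be non-negative")
        if self.mu_log2_range[0] >= self.mu_log2_range[1]:
            raise ValueError("mu_log2_range must be an increasing pair")

    @property
    def n_differential(self) -> int:
        return int(round(self.frac_differential * self.n_peaks))


def generate_voc_study(params: VocSimParams) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate a two-group VOC peak table plus its ground truth.

    Model: per-peak log2 intensity is Normal(mu_j, sigma_log2) with mu_j
    drawn uniformly from ``mu_log2_range``; differential peaks add
    ``effect_log2`` to the case group only. Each sample is then multiplied by
    a private scale factor, log-uniform in [1/(1+scale_jitter),
    1+scale_jitter]. Missingness is (i) left censoring of cells below the
    peak's ``lod_quantile`` intensity quantile and (ii) independent dropout
    at ``missing_rate``.

    Returns
    -------
    (PeakTable, DataFrame)
        The truth frame has columns ``feature_id`` (index),
        ``is_differential`` and ``effect_log2`` (0.0 for null peaks).
    """
    n_diff = params.n_differential
    n_null = params.n_peaks - n_diff
    if n_diff > 0 and n_null == 0:
        raise ValueError(
            "frac_differential leaves zero null peaks; "
            "false-discovery evaluation would be impossible"
        )

    rng = np.random.default_rng(params.seed)
    n = params.n_case + params.n_control
    mu = rng.uniform(*params.mu_log2_range, size=params.n_peaks)
    diff_idx = np.sort(rng.choice(params.n_peaks, size=n_diff, replace=False))

    log2x = rng.normal(mu[:, None], params.sigma_log2, size=(params.n_peaks, n))
    log2x[diff_idx, : params.n_case] += params.effect_log2

    if params.scale_jitter > 0:
        half_width = np.log2(1.0 + params.scale_jitter)
        log2_scale = rng.uniform(-half_width, half_width, size=n)
    else:
        log2_scale = np.zeros(n)
    x = np.exp2(log2x + log2_scale[None, :])

    missing = np.zeros_like(x, dtype=bool)
    if params.lod_quantile > 0:
        lod = np.quantile(x, params.lod_quantile, axis=1, keepdims=True)
        missing |= x < lod
    if params.missing_rate > 0:
        missing |= rng.random(size=x.shape) < params.missing_rate
    x = np.where(missing, np.nan, x)

    width = max(3, len(str(params.n_peaks)))
    feature_ids = [f"peak_{i + 1:0{width}d}" for i in range(params.n_peaks)]
    sample_ids = [f"case_{i + 1:02d}" for i in range(params.n_case)] + [
        f"control_{i + 1:02d}" for i in range(params.n_control)
    ]
    groups = pd.Series(
        [CASE] * params.n_case + [CONTROL] * params.n_control,
        index=sample_ids,
        name="group",
    )
    table = PeakTable(pd.DataFrame(x, index=feature_ids, columns=sample_ids), groups)

    is_diff = np.zeros(params.n_peaks, dtype=bool)
    is_diff[diff_idx] = True
    truth = pd.DataFrame(
        {
            "is_differential": is_diff,
            "effect_log2": np.where(is_diff, params.effect_log2, 0.0),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return table, truth


def generate_expression_study(
    n_probes: int = 1000,
    n_per_condition: int = 3,
    conditions: tuple[str, ...] = ("C", "M", "LPS"),
    frac_de: float = 0.05,
    effect_log2: float = 1.0,
    sigma: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a normalized log2 expression matrix with planted DE probes.

    Baseline probe means are uniform on log2 [4, 12] (typical of normalized
    array signals). The first condition is the reference; differential probes
    are shifted by ``effect_log2`` in every non-reference condition, so any
    contrast against the reference carries the planted effect.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition names must be unique")
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2 (Welch test undefined otherwise)")
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must be in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    rng = np.random.default_rng(seed)
    n_de = int(round(frac_de * n_probes))
    mu = rng.uniform(4.0, 12.0, size=n_probes)
    de_idx = np.sort(rng.choice(n_probes, size=n_de, replace=False))

    cond_labels: list[str] = []
    sample_ids: list[str] = []
    for cond in conditions:
        for i in range(n_per_condition):
            cond_labels.append(cond)
            sample_ids.append(f"{cond}_{i + 1:02d}")
    n_samples = len(sample_ids)

    means = np.tile(mu[:, None], (1, n_samples))
    non_ref = np.array([c != conditions[0] for c in cond_labels])
    means[np.ix_(de_idx, np.nonzero(non_ref)[0])] += effect_log2
    values = rng.normal(means, sigma)

    width = max(4, len(str(n_probes)))
    probe_ids = [f"probe_{i + 1:0{width}d}" for i in range(n_probes)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pd.Series(cond_labels, index=sample_ids, name="condition"),
    )
    is_de = np.zeros(n_probes, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame(
        {
            "is_differential": is_de,
            "effect_log2": np.where(is_de, effect_log2, 0.0),
        },
        index=pd.Index(probe_ids, name="feature_id"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Bundled desk-scale fixtures
# ---------------------------------------------------------------------------

# Curated miniature CAS -> KEGG compound mapping for desk-scale runs. The
# entries are real registry-number/compound-ID pairs for common urinary
# volatiles (menthol, short-chain ketones, aldehydes, ethers). Note that the
# t-butyl ethyl ether row keeps the registry number as printed in the source
# quantification tables even though it fails the CAS checksum; `validate_cas`
# flags it, the mapping still resolves it.
_CAS_KEGG_FIXTURE: list[tuple[str, str, str]] = [
    ("89-78-1", "C00400", "Menthol"),
    ("21634-04-4", "C11344", "t-Butyl ethyl ether"),
    ("107-87-9", "C01949", "2-Pentanone"),
    ("64-17-5", "C00469", "Ethanol"),
    ("67-64-1", "C00207", "Acetone"),
    ("75-07-0", "C00084", "Acetaldehyde"),
    ("100-52-7", "C00261", "Benzaldehyde"),
    ("78-93-3", "C02845", "2-Butanone"),
]

# Miniature compound -> pathway table (KEGG-flavoured, desk scale; not a
# database export). Compounds C01949 and C02845 intentionally have no rows.
_PATHWAY_FIXTURE: list[tuple[str, str, str]] = [
    ("C00400", "map00902", "Monoterpenoid biosynthesis"),
    ("C00469", "map00010", "Glycolysis / Gluconeogenesis"),
    ("C00084", "map00010", "Glycolysis / Gluconeogenesis"),
    ("C00084", "map00620", "Pyruvate metabolism"),
    ("C00207", "map00072", "Synthesis and degradation of ketone bodies"),
    ("C00261", "map00360", "Phenylalanine metabolism"),
]

# Synthetic GO-biological-process term -> gene table for enrichment tests.
# Term IDs/names are real GOBP identifiers relevant to LPS-driven
# inflammation; the gene memberships are synthetic identifiers.
_TERM_FIXTURE: list[tuple[str, str, range]] = [
    ("GO:0006954", "inflammatory response", range(1, 16)),
    ("GO:0032496", "response to lipopolysaccharide", range(10, 21)),
    ("GO:0002376", "immune system process", range(1, 31)),
    ("GO:0031663", "lipopolysaccharide-mediated signaling pathway", range(12, 19)),
    ("GO:0008152", "metabolic process", range(25, 61)),
]


def bundled_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the packaged (CAS->KEGG mapping, GO term) fixture tables.

    The mapping frame has columns ``cas_rn``, ``kegg_id``, ``compound_name``;
    the term frame has ``term_id``, ``term_name``, ``gene_id`` (synthetic
    gene identifiers ``g001`` ... ``g060``).
    """
    mapping = pd.DataFrame(_CAS_KEGG_FIXTURE, columns=["cas_rn", "kegg_id", "compound_name"])
    rows = [
        (term_id, term_name, f"g{i:03d}")
        for term_id, term_name, gene_range in _TERM_FIXTURE
        for i in gene_range
    ]
    terms = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])
    return mapping, terms


def bundled_pathways() -> pd.DataFrame:
    """Return the packaged KEGG-compound -> pathway fixture table."""
    return pd.DataFrame(
        _PATHWAY_FIXTURE, columns=["kegg_compound_id", "pathway_id", "pathway_name"]
    )
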