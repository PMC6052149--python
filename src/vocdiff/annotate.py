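"""Peak annotation: CAS registry numbers -> KEGG compound IDs -> pathways.

All mapping is a local join against user-supplied (or bundled) tables — no
web-service calls — so counts are reproducible but depend on the mapping
tables used. Unmapped entries are represented as ``NA`` on disk and as NaN
in memory.

An annotation table has columns ``feature_id``, ``compound_name``,
``cas_rn``, ``kegg_id``, ``retention_time``; a pathway table has
``kegg_compound_id``, ``pathway_id``, ``pathway_name``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["validate_cas", "map_cas_to_kegg", "map_to_pathways", "annotation_funnel"]

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def validate_cas(cas_rn) -> bool:
    """Check CAS registry-number syntax and check digit.

    Format ``N{2,7}-NN-N``; the final digit is a checksum (digits weighted
    1, 2, 3, ... from the right, summed mod 10). Validation is advisory:
    vendor peak tables occasionally carry malformed registry numbers, so
    callers flag rather than drop failures.
    """
    if not isinstance(cas_rn, str):
        return False
    match = _CAS_RE.match(cas_rn.strip())
    if match is None:
        return False
    body = match.group(1) + match.group(2)
    check = int(match.group(3))
    weighted = sum(i * int(d) for i, d in enumerate(reversed(body), start=1))
    return weighted % 10 == check


def _is_absent(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == "NA" or value == ""


def _normalize_absent(series: pd.Series) -> pd.Series:
    return series.map(lambda v: np.nan if _is_absent(v) else v)


def map_cas_to_kegg(
    annotations: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill KEGG compound IDs from CAS registry numbers via a mapping table.

    ``mapping`` needs columns ``cas_rn`` and ``kegg_id``. Conflicting
    duplicate CAS entries (same registry number, different compound IDs) are
    an error; exact duplicate rows are tolerated. Returns the annotated copy
    and the annotation funnel counts
    (``n_total``, ``n_with_cas``, ``n_kegg_mapped``).
    """
    mapping = mapping.drop_duplicates(subset=["cas_rn", "kegg_id"])
    conflicts = mapping[mapping.duplicated(subset="cas_rn", keep=False)]
    if not conflicts.empty:
        pairs = conflicts.sort_values("cas_rn")[["cas_rn", "kegg_id"]].to_records(index=False)
        raise ValueError(f"conflicting CAS->KEGG mapping entries: {list(pairs)}")
    lookup = mapping.set_index("cas_rn")["kegg_id"]

    out = annotations.copy()
    if "kegg_id" not in out.columns:
        out["kegg_id"] = np.nan
    out["cas_rn"] = _normalize_absent(out["cas_rn"]).astype(object)
    out["kegg_id"] = _normalize_absent(out["kegg_id"]).astype(object)
    needs = out["kegg_id"].isna() & out["cas_rn"].notna()
    out.loc[needs, "kegg_id"] = out.loc[needs, "cas_rn"].map(lookup)

    funnel = {
        "n_total": int(len(out)),
        "n_with_cas": int(out["cas_rn"].notna().sum()),
        "n_kegg_mapped": int(out["kegg_id"].notna().sum()),
    }
    return out, funnel


def map_to_pathways(
    annotations: pd.DataFrame, pathways: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join KEGG compound IDs against a pathway table.

    Returns a copy of ``annotations`` with a ``pathways`` column
    (semicolon-joined sorted pathway IDs, empty string when none) and summary
    counts (``n_pathway_mapped``: compounds with >= 1 pathway;
    ``n_distinct_pathways``). Duplicate (compound, pathway) rows count once.
    """
    pathways = pathways.drop_duplicates(subset=["kegg_compound_id", "pathway_id"])
    by_compound = pathways.groupby("kegg_compound_id")["pathway_id"].agg(
        lambda s: ";".join(sorted(set(s)))
    )
    out = annotations.copy()
    kegg = _normalize_absent(out["kegg_id"])
    out["pathways"] = kegg.map(by_compound).fillna("")

    mapped = out[out["pathways"] != ""]
    distinct = set()
    for entry in mapped["pathways"]:
        distinct.update(entry.split(";"))
    summary = {
        "n_pathway_mapped": int(len(mapped)),
        "n_distinct_pathways": int(len(distinct)),
    }
    return out, summary


def annotation_funnel(
    annotations: pd.DataFrame, mapping: pd.DataFrame, pathways: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full annotation funnel: CAS -> KEGG -> pathways, with monotone counts."""
    annotated, funnel = map_cas_to_kegg(annotations, mapping)
    annotated, summary = map_to_pathways(annotated, pathways)
    funnel.update(summary)
    return annotated, funnel
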