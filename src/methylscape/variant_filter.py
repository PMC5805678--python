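"""Whole-exome artifact filtering: confidence score and exclusion cascade.

The confidence score starts at 10 and is deducted per true artifact
category: overlap with repeats, DUKE-excluded regions, DAC-blacklisted
regions, self-chain regions, or segmental-duplication records; for indels,
each set caller filter (alleleBias, badReads, MQ, SC, GOF, QD, strandBias)
deducts as well.  The deduction magnitude defaults to 1 point per category
and is configurable, as is merging repeats + DUKE into a single category.
Variants scoring below 8 (strict) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OVERLAP_FLAGS = (
    "repeats",
    "duke_excluded",
    "dac_blacklist",
    "self_chain",
    "segmental_duplication",
)
PLATYPUS_FILTERS = ("alleleBias", "badReads", "MQ", "SC", "GOF", "QD", "strandBias")
MAX_SCORE = 10

EXCLUSION_RULES = (
    "score",
    "depth",
    "not_properly_mapped",
    "dbsnp_common",
    "exac",
    "evs",
    "inhouse",
    "noncoding",
)


def _platypus_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError("platypus_filters must be annotated (may be empty string)")
    s = str(value).strip()
    if not s:
        return set()
    flags = {f for f in s.split(";") if f}
    unknown = flags - set(PLATYPUS_FILTERS)
    if unknown:
        raise ValueError(f"unknown Platypus filters: {sorted(unknown)}")
    return flags


def confidence_score(
    variant,
    deduction_per_category: int = 1,
    *,
    merge_repeats_duke: bool = False,
) -> int:
    """Confidence score of one variant record (row of a variant table).

    Missing annotation fields are an error, never assumed false.  The score
    never exceeds 10; it has no lower cap.
    """
    if deduction_per_category < 0:
        raise ValueError("deduction_per_category must be non-negative")
    for flag in OVERLAP_FLAGS:
        if flag not in variant or pd.isna(variant[flag]):
            raise ValueError(f"variant missing overlap flag {flag!r}")
    if "kind" not in variant or variant["kind"] not in ("SNV", "indel"):
        raise ValueError("variant kind must be 'SNV' or 'indel'")
    flags = {f: bool(variant[f]) for f in OVERLAP_FLAGS}
    if merge_repeats_duke:
        rep = flags.pop("repeats")
        duke = flags.pop("duke_excluded")
        n_categories = int(rep or duke) + sum(flags.values())
    else:
        n_categories = sum(flags.values())
    score = MAX_SCORE - deduction_per_category * n_categories
    if variant["kind"] == "indel":
        score -= deduction_per_category * len(_platypus_set(variant.get("platypus_filters", "")))
    return int(score)


def confidence_scores(
    table: pd.DataFrame,
    deduction_per_category: int = 1,
    *,
    merge_repeats_duke: bool = False,
) -> pd.Series:
    """Vectorized :func:`confidence_score` over a variant table."""
    scores = table.apply(
        lambda row: confidence_score(
            row,
            deduction_per_category,
            merge_repeats_duke=merge_repeats_duke,
        ),
        axis=1,
    )
    scores.name = "confidence_score"
    return scores.astype(int) if len(scores) else scores


@dataclass
class VariantFilterReport:
    n_input: int
    n_retained: int
    excluded_by_rule: dict[str, int] = field(default_factory=dict)


def filter_variants(
    table: pd.DataFrame,
    min_score: int | None = 8,
    depth_bounds: tuple[int, int] | None = None,
    *,
    dbsnp_common_excluded: bool = True,
    exac_max: float | None = 0.001,
    evs_max: float | None = 0.01,
    inhouse_max: float | None = 0.02,
    coding_only: bool = True,
    require_properly_mapped: bool = True,
    deduction_per_category: int = 1,
    merge_repeats_duke: bool = False,
) -> tuple[pd.DataFrame, VariantFilterReport]:
    """Apply the exclusion cascade to an annotated variant table.

    Rules, in order (first-rule attribution in the report):
    confidence score < ``min_score`` (strict); depth outside
    ``depth_bounds`` (inclusive bounds, mandatory when supplied — the source
    procedure names no values, so there is no default); improperly mapped
    reads; dbSNP-common unless rescued by an OMIM record; ExAC frequency
    > ``exac_max``; EVS frequency > ``evs_max``; in-house frequency
    > ``inhouse_max``; non-coding.  Any threshold set to ``None`` (or a flag
    set False) disables that rule; with everything disabled the output equals
    the input.  Returns the retained table (with a ``confidence_score``
    column) and the per-rule report.
    """
    df = table.copy()
    for col in ("exac_af", "evs_af", "inhouse_af"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"variant table missing population field {col!r}")
    for col in ("dbsnp_common", "omim_record", "coding"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"variant table missing annotation field {col!r}")
    df["confidence_score"] = confidence_scores(
        df, deduction_per_category, merge_repeats_duke=merge_repeats_duke
    )

    excluded = pd.Series(False, index=df.index)
    report_counts: dict[str, int] = {rule: 0 for rule in EXCLUSION_RULES}

    def apply_rule(rule: str, mask: pd.Series) -> None:
        new = mask & ~excluded
        report_counts[rule] += int(new.sum())
        excluded[new[new].index] = True

    if min_score is not None:
        apply_rule("score", df["confidence_score"] < min_score)
    if depth_bounds is not None:
        low, high = depth_bounds
        if low > high:
            raise ValueError("depth_bounds low must not exceed high")
        apply_rule("depth", (df["depth"] < low) | (df["depth"] > high))
    if require_properly_mapped and "properly_mapped" in df.columns:
        apply_rule("not_properly_mapped", ~df["properly_mapped"].astype(bool))
    if dbsnp_common_excluded:
        apply_rule(
            "dbsnp_common",
            df["dbsnp_common"].astype(bool) & ~df["omim_record"].astype(bool),
        )
    if exac_max is not None:
        apply_rule("exac", df["exac_af"] > exac_max)
    if evs_max is not None:
        apply_rule("evs", df["evs_af"] > evs_max)
    if inhouse_max is not None:
        apply_rule("inhouse", df["inhouse_af"] > inhouse_max)
    if coding_only:
        apply_rule("noncoding", ~df["coding"].astype(bool))

    retained = df[~excluded]
    report = VariantFilterReport(
        n_input=len(df),
        n_retained=len(retained),
        excluded_by_rule=report_counts,
    )
    return retained, report
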