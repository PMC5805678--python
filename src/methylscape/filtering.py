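"""Probe exclusion rules applied before any analysis.

Rules are applied in a fixed order for reproducible attribution:
detection p-value, sex chromosome, SNP contamination, self-hybridization.
A probe is attributed to the first rule that removes it.  The detection rule
removes a probe when its detection p exceeds the threshold in ANY sample
(strictest reading; per-sample masking is deliberately not implemented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import BetaMatrix, Manifest

RULE_ORDER = ("detection", "sex_chromosome", "snp", "self_hybridizing")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_by_rule: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed_by_rule.values())

    def counts(self) -> dict[str, int]:
        return {rule: len(v) for rule, v in self.removed_by_rule.items()}


def normalize_passthrough(beta: BetaMatrix) -> BetaMatrix:
    """Placeholder for array normalization, which is out of scope here:
    inputs are assumed normalized upstream.  Returns the input unchanged."""
    return beta


def filter_probes(
    beta: BetaMatrix,
    manifest: Manifest,
    detection_p: pd.DataFrame | None = None,
    p_threshold: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove confounded probes from a beta matrix.

    Parameters
    ----------
    detection_p
        Optional probes x samples table of detection p-values covering every
        probe and sample of ``beta``.  A probe with p > ``p_threshold`` in any
        sample is removed globally.

    Returns the filtered matrix and a per-rule removal report (first
    matching rule attribution).  Filtering is idempotent.
    """
    missing = beta.probe_ids[~beta.probe_ids.isin(manifest.probe_ids)]
    if len(missing):
        raise ValueError(
            f"{len(missing)} beta probes missing from manifest, e.g. {missing[0]!r}"
        )
    if detection_p is not None:
        if set(detection_p.columns) != set(beta.sample_ids):
            raise ValueError("detection p table samples do not match beta matrix")
        missing_det = beta.probe_ids[~beta.probe_ids.isin(detection_p.index)]
        if len(missing_det):
            raise ValueError(
                f"detection p table missing {len(missing_det)} probes present in beta"
            )

    ann = manifest.df.loc[beta.probe_ids]
    removed: dict[str, list[str]] = {rule: [] for rule in RULE_ORDER}
    attributed: set[str] = set()

    def claim(rule: str, probes) -> None:
        new = [p for p in probes if p not in attributed]
        removed[rule].extend(new)
        attributed.update(new)

    if detection_p is not None:
        det = detection_p.loc[beta.probe_ids, list(beta.sample_ids)]
        failing = det.index[(det > p_threshold).any(axis=1)]
        claim("detection", failing.tolist())
    claim("sex_chromosome", ann.index[ann["sex"]].tolist())
    claim("snp", ann.index[ann["snp"]].tolist())
    claim("self_hybridizing", ann.index[ann["selfhyb"]].tolist())

    keep = [p for p in beta.probe_ids if p not in attributed]
    out = beta.select_probes(keep)
    report = FilterReport(
        n_input=len(beta.probe_ids), n_retained=len(keep), removed_by_rule=removed
    )
    return out, report
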