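"""Cancer-methylome landscape statistics.

Substructure shifts and hyper/hypo fractions, region (e.g. LAD) shifts, and
the non-CpG analysis.  The across-probe t-tests treat probes as units; probe
dependence makes this inference descriptive, which is how it is used.

Sign convention everywhere: delta-beta = mean(group_b) - mean(group_a), with
``group_a`` the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialResult, moderated_group_test
from .types import (
    BetaMatrix,
    Manifest,
    RegionSet,
    SampleSheet,
    SUBSTRUCTURES,
    probes_in_regions,
    region_probe_union,
)


@dataclass
class SubstructureShift:
    summary: pd.DataFrame  # index substructure; columns mean_delta, p_value, n_probes
    deltas: dict[str, pd.Series]
    absent: list[str] = field(default_factory=list)
    group_a: str = ""
    group_b: str = ""


@dataclass
class RegionShift:
    mean_delta: float
    p_value: float
    n_probes: int
    deltas: pd.Series
    region_set: str = ""


@dataclass
class NonCpGResult:
    diff: DifferentialResult
    significant_probes: list[str]
    per_sample_mean: pd.Series


def _group_samples(samplesheet: SampleSheet, beta: BetaMatrix, group: str) -> list[str]:
    ids = [s for s in samplesheet.samples_in_group(group) if s in beta.sample_ids]
    if not ids:
        raise ValueError(f"group {group!r} has no samples in the beta matrix")
    return ids


def _per_probe_delta(
    beta: BetaMatrix, samplesheet: SampleSheet, group_a: str, group_b: str
) -> pd.Series:
    a = _group_samples(samplesheet, beta, group_a)
    b = _group_samples(samplesheet, beta, group_b)
    return beta.df[b].mean(axis=1, skipna=True) - beta.df[a].mean(axis=1, skipna=True)


def _one_sample_t(deltas: np.ndarray) -> float:
    """Two-sided one-sample t-test of per-probe deltas against 0.

    Degenerate cases: a single probe or zero spread with non-zero mean is
    NaN (undefined); an exactly all-zero delta vector is p = 1 (perfect null).
    """
    deltas = deltas[np.isfinite(deltas)]
    if len(deltas) < 2:
        return np.nan
    sd = deltas.std(ddof=1)
    if sd == 0:
        return 1.0 if np.all(deltas == 0) else np.nan
    t, p = stats.ttest_1samp(deltas, 0.0)
    return float(p)


def substructure_shift(
    beta: BetaMatrix,
    manifest: Manifest,
    samplesheet: SampleSheet,
    group_a: str,
    group_b: str,
) -> SubstructureShift:
    """Per-substructure delta-beta distribution between two groups.

    Restricted to CpG-context probes (the substructure view is a CpG
    analysis; CH probes have their own report).  Empty substructure classes
    are reported as absent rather than raising.
    """
    deltas = _per_probe_delta(beta, samplesheet, group_a, group_b)
    cpg = manifest.probes_by_context("CpG")
    rows = {}
    per_class: dict[str, pd.Series] = {}
    absent = []
    for sub in SUBSTRUCTURES:
        probes = manifest.probes_by_substructure(sub).intersection(cpg)
        probes = probes.intersection(beta.probe_ids)
        if len(probes) == 0:
            absent.append(sub)
            continue
        d = deltas.loc[probes]
        per_class[sub] = d
        rows[sub] = {
            "mean_delta": float(d.mean()),
            "p_value": _one_sample_t(d.to_numpy()),
            "n_probes": len(d),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "substructure"
    return SubstructureShift(
        summary=summary, deltas=per_class, absent=absent,
        group_a=group_a, group_b=group_b,
    )


def shift_fractions(diff: DifferentialResult, manifest: Manifest) -> pd.DataFrame:
    """Fractions of hyper-, hypo- and unchanged probes per substructure.

    hyper: significant with delta > 0; hypo: significant with delta < 0;
    a significant probe with delta exactly 0 counts as unchanged (tie rule).
    Fractions sum to 1 exactly per substructure.  CpG-context probes only.
    """
    table = diff.table
    cpg = manifest.probes_by_context("CpG")
    rows = {}
    for sub in SUBSTRUCTURES:
        probes = manifest.probes_by_substructure(sub).intersection(cpg)
        probes = probes.intersection(table.index)
        n = len(probes)
        if n == 0:
            continue
        t = table.loc[probes]
        hyper = int((t["significant"] & (t["delta_beta"] > 0)).sum())
        hypo = int((t["significant"] & (t["delta_beta"] < 0)).sum())
        rows[sub] = {
            "frac_hyper": hyper / n,
            "frac_hypo": hypo / n,
            "frac_unchanged": (n - hyper - hypo) / n,
            "n_probes": n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "substructure"
    return out


def region_shift(
    beta: BetaMatrix,
    manifest: Manifest,
    regions: RegionSet,
    samplesheet: SampleSheet,
    group_a: str,
    group_b: str,
) -> RegionShift:
    """Delta-beta over all probes contained in a region set (e.g. LADs)."""
    membership = probes_in_regions(manifest, regions)
    probes = [p for p in region_probe_union(membership) if p in beta.probe_ids]
    if not probes:
        raise ValueError(
            f"region set {regions.name!r} contains no probes of the beta matrix"
        )
    deltas = _per_probe_delta(beta, samplesheet, group_a, group_b).loc[probes]
    return RegionShift(
        mean_delta=float(deltas.mean()),
        p_value=_one_sample_t(deltas.to_numpy()),
        n_probes=len(deltas),
        deltas=deltas,
        region_set=regions.name,
    )


def noncpg_analysis(
    beta: BetaMatrix,
    manifest: Manifest,
    samplesheet: SampleSheet,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> NonCpGResult:
    """Differential CH-context probes plus per-sample means over them.

    Runs the moderated group test restricted to CH probes (multiple-testing
    correction over the CH universe only) and averages each sample's beta
    over the significant probes for box-plot-style reporting.
    """
    ch = manifest.probes_by_context("CH").intersection(beta.probe_ids)
    if len(ch) == 0:
        raise ValueError("manifest contains no CH-context probes")
    sub = beta.select_probes(list(ch))
    diff = moderated_group_test(
        sub, samplesheet, comparison=(group_a, group_b), statistic="F", alpha=alpha
    )
    sig = diff.significant_probes
    if sig:
        per_sample = sub.df.loc[sig].mean(axis=0, skipna=True)
    else:
        per_sample = pd.Series(np.nan, index=sub.sample_ids)
    per_sample.name = "mean_ch_beta"
    return NonCpGResult(diff=diff, significant_probes=sig, per_sample_mean=per_sample)
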