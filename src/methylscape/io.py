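"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV; region sets are BED3/BED4; missing beta values are the
``NA`` token.  Round-trips are value-exact (Python float repr).
"""

from __future__ import annotations

import io as _io
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    ClockModel,
    FormatError,
    Manifest,
    RegionSet,
    SampleSheet,
    normalize_chromosomes,
)

_NA = "NA"

VARIANT_BOOL_COLUMNS = (
    "repeats",
    "duke_excluded",
    "dac_blacklist",
    "self_chain",
    "segmental_duplication",
    "dbsnp_common",
    "omim_record",
    "coding",
    "properly_mapped",
)
VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "kind",
    *VARIANT_BOOL_COLUMNS[:5],
    "platypus_filters",
    "depth",
    "dbsnp_common",
    "omim_record",
    "exac_af",
    "evs_af",
    "inhouse_af",
    "coding",
    "properly_mapped",
)


def read_beta_matrix(path, manifest: Manifest | None = None) -> BetaMatrix:
    """Read a probes-x-samples beta TSV.

    First column is ``probe_id``, header row holds sample ids.  Values must
    parse as floats in [0, 1] or be the ``NA`` token; offending cells are
    reported with their row and column.  When a manifest is given, probes
    absent from it are dropped and recorded on the returned matrix as
    ``dropped_probes``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][:3].tolist()
        raise FormatError(f"duplicate probe_id in beta file: {dup}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].to_numpy()
        for i, cell in enumerate(cells):
            if cell == _NA:
                values[i, j] = np.nan
                continue
            try:
                # exact float() parse: bit-identical round-trips
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"malformed beta value {cell!r} at probe {raw.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    dropped: list[str] = []
    if manifest is not None:
        keep = df.index.isin(manifest.probe_ids)
        dropped = df.index[~keep].tolist()
        df = df.loc[keep]
    bm = BetaMatrix(df, copy=False)
    bm.dropped_probes = dropped
    return bm


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    bm.df.to_csv(path, sep="\t", na_rep=_NA)


def read_manifest(path) -> Manifest:
    df = pd.read_csv(
        path, sep="\t", index_col=0, keep_default_na=False, na_values=[]
    )
    for c in ("sex", "snp", "selfhyb"):
        if c in df.columns:
            df[c] = df[c].map(_parse_bool)
    return Manifest(df, copy=False)


def write_manifest(manifest: Manifest, path) -> None:
    manifest.df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    if "chronological_age" in df.columns:
        df["chronological_age"] = pd.to_numeric(
            df["chronological_age"].replace("", np.nan).replace(_NA, np.nan)
        )
    return SampleSheet(df, copy=False)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", na_rep=_NA)


def read_regions_bed(path, name: str) -> RegionSet:
    """Read a BED3/BED4 file into a :class:`RegionSet`.

    Intervals are loaded verbatim (0-based half-open, no merging).  The
    region id comes from column 4 when present, else ``chrom:start-end``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            region_id = fields[3] if len(fields) >= 4 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, region_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    return RegionSet(name=name, df=df)


def write_regions_bed(regions: RegionSet, path) -> None:
    regions.df[["chrom", "start", "end", "region_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_clock(path) -> ClockModel:
    """Read a clock TSV: ``#intercept`` / ``#adult_age`` header lines followed
    by a ``probe_id<TAB>weight`` table."""
    intercept = None
    adult_age = None
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#intercept"):
                intercept = float(line.split("\t")[1])
            elif line.startswith("#adult_age"):
                adult_age = float(line.split("\t")[1])
            else:
                body.append(line)
    if intercept is None or adult_age is None:
        raise FormatError("clock file missing #intercept or #adult_age header")
    table = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col=0)
    if "weight" not in table.columns:
        raise FormatError("clock file missing 'weight' column")
    return ClockModel(
        intercept=intercept, weights=table["weight"], adult_age=adult_age
    )


def write_clock(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept\t{clock.intercept!r}\n")
        fh.write(f"#adult_age\t{clock.adult_age!r}\n")
        fh.write("probe_id\tweight\n")
        for pid, w in clock.weights.items():
            fh.write(f"{pid}\t{w!r}\n")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no", ""):
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def read_variants(path) -> pd.DataFrame:
    """Read an annotated variant table (post-annotation TSV, not VCF)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing columns: {missing}")
    out = pd.DataFrame(index=df.index)
    out["chrom"] = normalize_chromosomes(df["chrom"]) if len(df) else df["chrom"]
    out["pos"] = df["pos"].astype(int) if len(df) else df["pos"]
    out["ref"] = df["ref"]
    out["alt"] = df["alt"]
    kinds = set(df["kind"]) - {"SNV", "indel"}
    if kinds:
        raise FormatError(f"unknown variant kinds: {sorted(kinds)}")
    out["kind"] = df["kind"]
    for c in VARIANT_BOOL_COLUMNS:
        out[c] = df[c].map(_parse_bool)
    out["platypus_filters"] = df["platypus_filters"]
    out["depth"] = df["depth"].astype(int) if len(df) else df["depth"]
    for c in ("exac_af", "evs_af", "inhouse_af"):
        out[c] = df[c].map(float) if len(df) else df[c]
    for c in ("exac_af", "evs_af", "inhouse_af"):
        if len(out) and ((out[c] < 0) | (out[c] > 1)).any():
            raise FormatError(f"{c} outside [0, 1]")
    return out


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, *, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=_NA, index=index)
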