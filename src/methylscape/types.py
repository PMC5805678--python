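"""Core domain objects: probe manifests, beta matrices, sample sheets, region
sets and clock models.

Coordinate conventions
----------------------
Manifest probe positions are 1-based cytosine sites (array-manifest
convention).  All :class:`RegionSet` intervals are 0-based half-open (BED
native).  The single conversion point is :func:`probes_in_regions`: a probe at
1-based position ``p`` is a member of ``(start, end)`` iff ``start < p <= end``
(equivalently, the 0-based position ``p - 1`` lies in ``[start, end)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUBSTRUCTURES = ("island", "shore", "shelf", "open_sea")
CONTEXTS = ("CpG", "CH")
SAMPLE_GROUPS = (
    "healthy",
    "AK",
    "cSCC",
    "reference_ESC",
    "reference_keratinocyte",
    "reference_EpSC",
    "reference_diffKC",
    "pan_cancer",
)
SUBCLASSES = ("EpSC_like", "keratinocyte_like")

MANIFEST_COLUMNS = (
    "chrom",
    "pos",
    "context",
    "substructure",
    "genes",
    "gene_region",
    "sex",
    "snp",
    "selfhyb",
)


class FormatError(ValueError):
    """A file or table violates its declared format."""


class ChromosomeDialectError(ValueError):
    """Chromosome naming dialects (``chr1`` vs ``1``) are inconsistent."""


def normalize_chromosomes(values: Iterable[str]) -> list[str]:
    """Normalize chromosome names to the ``chr``-prefixed dialect.

    A uniformly bare dialect (``1``, ``X``) is prefixed; a uniformly
    prefixed dialect is kept.  Mixed dialects within one input are an
    error, never silently repaired.
    """
    names = [str(v) for v in values]
    if not names:
        return names
    prefixed = [n.startswith("chr") for n in names]
    if all(prefixed):
        return names
    if not any(prefixed):
        return ["chr" + n for n in names]
    raise ChromosomeDialectError(
        "mixed chromosome naming dialects (chr-prefixed and bare) in one input"
    )


def _chrom_dialect(names: Iterable[str]) -> str:
    names = list(names)
    if not names:
        return "empty"
    prefixed = [str(n).startswith("chr") for n in names]
    if all(prefixed):
        return "chr"
    if not any(prefixed):
        return "bare"
    raise ChromosomeDialectError("mixed chromosome naming dialects")


class Manifest:
    """Per-probe genomic and functional metadata.

    Wraps a DataFrame indexed by ``probe_id`` with columns
    ``chrom, pos, context, substructure, genes, gene_region, sex, snp,
    selfhyb``.  ``genes`` and ``gene_region`` are aligned ``;``-joined lists
    (empty string for probes without gene links).
    """

    def __init__(self, df: pd.DataFrame, *, copy: bool = True):
        if copy:
            df = df.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate probe_id in manifest: {dup}")
        bad_ctx = set(df["context"]) - set(CONTEXTS)
        if bad_ctx:
            raise FormatError(f"unknown probe context values: {sorted(bad_ctx)}")
        bad_sub = set(df["substructure"]) - set(SUBSTRUCTURES)
        if bad_sub:
            raise FormatError(f"unknown substructure values: {sorted(bad_sub)}")
        if (df["pos"].astype(int) < 1).any():
            raise FormatError("manifest positions must be 1-based (>= 1)")
        df["pos"] = df["pos"].astype(int)
        df["chrom"] = normalize_chromosomes(df["chrom"])
        for c in ("sex", "snp", "selfhyb"):
            df[c] = df[c].astype(bool)
        df["genes"] = df["genes"].fillna("").astype(str)
        df["gene_region"] = df["gene_region"].fillna("").astype(str)
        df.index.name = "probe_id"
        self.df = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.df.index

    def probes_by_substructure(self, substructure: str) -> pd.Index:
        if substructure not in SUBSTRUCTURES:
            raise ValueError(f"unknown substructure {substructure!r}")
        return self.df.index[self.df["substructure"] == substructure]

    def probes_by_context(self, context: str) -> pd.Index:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.df.index[self.df["context"] == context]

    def gene_probe_map(
        self,
        genes: Iterable[str] | None = None,
        gene_region: str | None = None,
    ) -> dict[str, list[str]]:
        """Map gene symbol -> probe ids linked to it.

        ``gene_region`` restricts links to one region class (e.g.
        ``"promoter"``).  A probe linked to several genes contributes to each.
        """
        wanted = set(genes) if genes is not None else None
        out: dict[str, list[str]] = {}
        linked = self.df.loc[self.df["genes"] != "", ["genes", "gene_region"]]
        for probe_id, gene_str, region_str in linked.itertuples():
            gs = gene_str.split(";")
            rs = region_str.split(";") if region_str else [""] * len(gs)
            if len(rs) != len(gs):
                raise FormatError(
                    f"probe {probe_id}: genes/gene_region lists differ in length"
                )
            for g, r in zip(gs, rs):
                if wanted is not None and g not in wanted:
                    continue
                if gene_region is not None and r != gene_region:
                    continue
                out.setdefault(g, []).append(probe_id)
        return out


class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing values are NaN internally and the ``NA`` token on disk.
    """

    def __init__(self, df: pd.DataFrame, *, copy: bool = True):
        if copy:
            df = df.copy()
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate probe_id in beta matrix: {dup}")
        if not df.columns.is_unique:
            raise FormatError("duplicate sample_id in beta matrix")
        values = df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0, 1] at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {values[i, j]}"
            )
        df = df.astype(float)
        df.index.name = "probe_id"
        self.df = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.df.loc[list(probe_ids)], copy=False)

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.df[list(sample_ids)], copy=False)


class SampleSheet:
    """Sample metadata: group, chronological age and (synthetic-only)
    latent subclass truth.  Indexed by ``sample_id``."""

    def __init__(self, df: pd.DataFrame, *, copy: bool = True):
        if copy:
            df = df.copy()
        if "group" not in df.columns:
            raise FormatError("sample sheet missing 'group' column")
        if not df.index.is_unique:
            raise FormatError("duplicate sample_id in sample sheet")
        bad = set(df["group"]) - set(SAMPLE_GROUPS)
        if bad:
            raise FormatError(f"unknown sample groups: {sorted(bad)}")
        if "chronological_age" not in df.columns:
            df["chronological_age"] = np.nan
        df["chronological_age"] = pd.to_numeric(df["chronological_age"])
        if "latent_subclass" not in df.columns:
            df["latent_subclass"] = ""
        df["latent_subclass"] = df["latent_subclass"].fillna("").astype(str)
        bad_sub = set(df["latent_subclass"]) - set(SUBCLASSES) - {""}
        if bad_sub:
            raise FormatError(f"unknown latent subclasses: {sorted(bad_sub)}")
        non_lesion = ~df["group"].isin(["AK", "cSCC"])
        if (df.loc[non_lesion, "latent_subclass"] != "").any():
            raise FormatError("latent_subclass is only valid for AK/cSCC samples")
        df.index.name = "sample_id"
        self.df = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def samples_in_group(self, group: str) -> list[str]:
        return self.df.index[self.df["group"] == group].tolist()

    def groups(self) -> pd.Series:
        return self.df["group"]


@dataclass
class RegionSet:
    """Named set of genomic intervals, 0-based half-open."""

    name: str
    df: pd.DataFrame  # columns: chrom, start, end, region_id
    region_genes: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self):
        df = self.df.copy()
        for c in ("chrom", "start", "end", "region_id"):
            if c not in df.columns:
                raise FormatError(f"region set {self.name!r} missing column {c!r}")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"region set {self.name!r}: start >= end at "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        if df["region_id"].duplicated().any():
            raise FormatError(f"region set {self.name!r}: duplicate region_id")
        if len(df):
            df["chrom"] = normalize_chromosomes(df["chrom"])
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ClockModel:
    """Linear methylation clock: transformed age = intercept + sum(w * beta)."""

    intercept: float
    weights: pd.Series  # probe_id -> weight
    adult_age: float = 20.0

    def __post_init__(self):
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")
        if not self.weights.index.is_unique:
            raise FormatError("duplicate probe_id in clock weights")
        self.weights = self.weights.astype(float)
        self.intercept = float(self.intercept)

    @property
    def probe_ids(self) -> pd.Index:
        return self.weights.index


def probes_in_regions(
    manifest: Manifest, regions: RegionSet
) -> dict[str, list[str]]:
    """Resolve region membership of manifest probes.

    Returns a mapping ``region_id -> probe ids`` (ordered by genomic
    position).  Regions containing no probes map to an empty list so callers
    can flag them.  Raises :class:`ChromosomeDialectError` when manifest and
    regions use different chromosome naming dialects (no silent empty joins).
    """
    if len(regions):
        d_manifest = _chrom_dialect(manifest.df["chrom"].unique())
        d_regions = _chrom_dialect(regions.df["chrom"].unique())
        if "empty" not in (d_manifest, d_regions) and d_manifest != d_regions:
            raise ChromosomeDialectError(
                f"manifest uses {d_manifest!r} chromosome names but region set "
                f"{regions.name!r} uses {d_regions!r}"
            )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in manifest.df.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        by_chrom[chrom] = (
            sub["pos"].to_numpy()[order],
            sub.index.to_numpy()[order],
        )
    out: dict[str, list[str]] = {}
    for chrom, start, end, region_id in regions.df[
        ["chrom", "start", "end", "region_id"]
    ].itertuples(index=False):
        if chrom not in by_chrom:
            out[region_id] = []
            continue
        pos, ids = by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="right")  # pos > start
        hi = np.searchsorted(pos, end, side="right")  # pos <= end
        out[region_id] = ids[lo:hi].tolist()
    return out


def region_probe_union(membership: Mapping[str, Sequence[str]]) -> list[str]:
    """Deduplicated union of member probes, in first-seen order."""
    seen: dict[str, None] = {}
    for probes in membership.values():
        for p in probes:
            seen.setdefault(p, None)
    return list(seen)
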