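"""Synthetic cohorts with planted landscape effects and two latent subclasses.

The generator emulates the statistical structure of an epidermal
healthy / AK / cSCC methylation cohort: substructure-typical beta baselines,
planted island hyper- / open-sea hypo- / LAD hypo-methylation and non-CpG
gains in the lesion groups, and an EpSC-like signature planted in a subset
of lesion samples across three independent channels (EpSC-gained enhancer
hypermethylation, keratin-promoter hypomethylation, and a clock-probe shift
toward younger predicted age).  Reference methylomes, a synthetic clock, a
"pan-cancer" stand-in cohort and an annotated variant table round out the
inputs the analysis stages consume.

Effect magnitudes are invented and fully configurable; latent subclass truth
is recorded on the sample sheet only and never consumed by any analysis
operation.  Same config + seed gives byte-identical output.

Planting is disjoint by design: each probe carries at most one planted
effect (channel > LAD > substructure), so every recovery check reads back an
uncontaminated magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meth_age import age_transform
from .types import BetaMatrix, ClockModel, Manifest, RegionSet, SampleSheet
from .variant_filter import OVERLAP_FLAGS, PLATYPUS_FILTERS, confidence_scores


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


BASELINES = {"island": 0.15, "shore": 0.35, "shelf": 0.55, "open_sea": 0.80}
CH_BASELINE = 0.05
KERATIN_BASELINE = 0.50
ENHANCER_BASELINE = 0.60
GAINED_BASELINE = 0.30
LOST_BASELINE = 0.50

_N_CHROMOSOMES = 22


@dataclass
class CohortConfig:
    """Knobs for manifest and cohort generation (all magnitudes invented)."""

    n_probes: int = 20000
    island_fraction: float = 0.25
    shore_fraction: float = 0.20
    shelf_fraction: float = 0.10
    ch_fraction: float = 0.05
    ch_affected_fraction: float = 0.5
    lad_fraction: float = 0.12
    n_healthy: int = 12
    n_ak: int = 16
    n_cscc: int = 18
    island_hyper: float = 0.15
    open_sea_hypo: float = -0.15
    lad_hypo: float = -0.10
    ch_gain: float = 0.10
    subclass_separation: float = 0.30
    subclass_fraction: float = 0.5
    noise_sd: float = 0.05
    substructure_noise_scale: dict = field(
        default_factory=lambda: {s: 1.0 for s in BASELINES}
    )
    n_keratin_genes: int = 55
    probes_per_keratin_gene: int = 4
    enhancer_overlap: float = 0.25
    reference_margin: float = 0.30
    tumor_age_shift: float = -15.0
    epsc_age_shift: float = 0.0
    sex_fraction: float = 0.0
    snp_fraction: float = 0.0
    selfhyb_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "island_fraction": self.island_fraction,
            "shore_fraction": self.shore_fraction,
            "shelf_fraction": self.shelf_fraction,
            "ch_fraction": self.ch_fraction,
            "ch_affected_fraction": self.ch_affected_fraction,
            "lad_fraction": self.lad_fraction,
            "subclass_fraction": self.subclass_fraction,
            "sex_fraction": self.sex_fraction,
            "snp_fraction": self.snp_fraction,
            "selfhyb_fraction": self.selfhyb_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.island_fraction + self.shore_fraction + self.shelf_fraction > 1.0:
            raise ConfigError("substructure fractions exceed 1 in total")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0.0 < self.enhancer_overlap < 1.0:
            raise ConfigError("enhancer_overlap must lie in (0, 1)")


@dataclass
class SyntheticManifest:
    """Manifest plus region sets and the channel bookkeeping of the generator."""

    manifest: Manifest
    region_sets: dict[str, RegionSet]
    keratin_genes: list[str]
    keratin_promoter_probes: list[str]
    keratin_body_probes: list[str]
    shared_enhancer_probes: list[str]
    esc_only_probes: list[str]
    kc_only_probes: list[str]
    gained_probes: list[str]
    lost_probes: list[str]
    lad_probes: list[str]
    ch_probes: list[str]
    ch_affected: list[str]
    plain_probes: list[str]


@dataclass
class CohortResult:
    beta: BetaMatrix
    samples: SampleSheet
    report: dict


class _RunAllocator:
    """Hands out runs of consecutive probe indices within one chromosome."""

    def __init__(self, n: int, block: int):
        self.n = n
        self.block = block
        self.ptr = 0

    def take(self, length: int) -> list[int]:
        while True:
            if self.ptr >= self.n:
                raise ConfigError("n_probes too small for the requested structure")
            chrom_end = min(((self.ptr // self.block) + 1) * self.block, self.n)
            if self.ptr + length <= chrom_end:
                run = list(range(self.ptr, self.ptr + length))
                self.ptr += length
                return run
            self.ptr = chrom_end


def _probe_id(i: int) -> str:
    return f"cg{i + 1:08d}"


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def generate_manifest(config: CohortConfig) -> SyntheticManifest:
    """Deterministically generate a probe manifest plus region sets.

    Emits LAD, ESC_enhancer, KC_enhancer, EpSC_gained and EpSC_lost region
    sets; the two enhancer sets share about ``enhancer_overlap`` of their
    regions (Jaccard).  Every keratin-like gene receives at least one probe.
    """
    n = config.n_probes
    if n < 100:
        raise ConfigError("n_probes must be at least 100")
    block = math.ceil(n / _N_CHROMOSOMES)
    chroms = np.array([f"chr{i // block + 1}" for i in range(n)], dtype=object)
    positions = np.array([1000 * (i % block + 1) for i in range(n)], dtype=int)
    ids = np.array([_probe_id(i) for i in range(n)], dtype=object)

    def interval(run: list[int]) -> tuple[str, int, int]:
        return (chroms[run[0]], int(positions[run[0]] - 1), int(positions[run[-1]]))

    alloc = _RunAllocator(n, block)

    # keratin-like gene cluster: half promoter, half body probes per gene
    n_ker = min(config.n_keratin_genes, max(2, n // 40))
    ppg = max(2, config.probes_per_keratin_gene)
    keratin_genes = [f"KRT{i + 1}" for i in range(n_ker)]
    ker_prom: list[int] = []
    ker_body: list[int] = []
    gene_of: dict[int, tuple[str, str]] = {}
    for gene in keratin_genes:
        run = alloc.take(ppg)
        half = ppg // 2
        for idx in run[:half]:
            gene_of[idx] = (gene, "promoter")
            ker_prom.append(idx)
        for idx in run[half:]:
            gene_of[idx] = (gene, "body")
            ker_body.append(idx)

    # enhancer sets with controlled region overlap (Jaccard ~ enhancer_overlap)
    e = max(4, n // 100)
    j = config.enhancer_overlap
    n_shared = max(1, round(2 * e * j / (1 + j)))
    n_only = max(1, e - n_shared)

    def enhancer_regions(count: int, tag: str, probes_out: list[int]):
        rows = []
        for i in range(count):
            run = alloc.take(2)
            probes_out.extend(run)
            chrom, start, end = interval(run)
            rows.append((chrom, start, end, f"{tag}{i + 1:05d}"))
        return rows

    shared_idx: list[int] = []
    esc_only_idx: list[int] = []
    kc_only_idx: list[int] = []
    shared_rows = enhancer_regions(n_shared, "ENH_SH", shared_idx)
    esc_rows = enhancer_regions(n_only, "ENH_ES", esc_only_idx)
    kc_rows = enhancer_regions(n_only, "ENH_KC", kc_only_idx)

    n_gained = max(3, n // 300)
    gained_idx: list[int] = []
    gained_rows = []
    region_genes: dict[str, tuple[str, ...]] = {}
    for i in range(n_gained):
        run = alloc.take(2)
        gained_idx.extend(run)
        chrom, start, end = interval(run)
        rid = f"EPSC_G{i + 1:05d}"
        gained_rows.append((chrom, start, end, rid))
        region_genes[rid] = (f"DEVG{2 * i + 1:04d}", f"DEVG{2 * i + 2:04d}")

    n_lost = max(3, n // 150)
    lost_idx: list[int] = []
    lost_rows = []
    for i in range(n_lost):
        run = alloc.take(2)
        lost_idx.extend(run)
        chrom, start, end = interval(run)
        lost_rows.append((chrom, start, end, f"EPSC_L{i + 1:05d}"))

    # LADs: contiguous open-sea runs
    lad_target = round(config.lad_fraction * n)
    lad_idx: list[int] = []
    lad_rows = []
    run_len = 20
    i = 0
    while len(lad_idx) < lad_target:
        take = min(run_len, lad_target - len(lad_idx))
        run = alloc.take(take)
        lad_idx.extend(run)
        chrom, start, end = interval(run)
        lad_rows.append((chrom, start, end, f"LAD{i + 1:05d}"))
        i += 1

    channel = sorted(
        set(ker_prom) | set(ker_body) | set(shared_idx) | set(esc_only_idx)
        | set(kc_only_idx) | set(gained_idx) | set(lost_idx)
    )
    remaining = np.setdiff1d(
        np.arange(n), np.array(sorted(set(channel) | set(lad_idx)), dtype=int)
    )

    rng = _rng(config.seed, 1)
    ch_count = round(config.ch_fraction * n)
    if ch_count > len(remaining):
        raise ConfigError("ch_fraction infeasible after channel/LAD allocation")
    remaining = rng.permutation(remaining)
    ch_idx = np.sort(remaining[:ch_count])
    plain = np.sort(remaining[ch_count:])
    n_aff = round(config.ch_affected_fraction * len(ch_idx))
    ch_affected_idx = np.sort(rng.permutation(ch_idx)[:n_aff])

    substructure = np.empty(n, dtype=object)
    for pos_in_channel, idx in enumerate(channel):
        substructure[idx] = "shore" if pos_in_channel % 2 == 0 else "shelf"
    substructure[lad_idx] = "open_sea"
    substructure[ch_idx] = "open_sea"
    n_island = round(config.island_fraction * n)
    n_shore = max(0, round(config.shore_fraction * n) - sum(
        1 for i_ in range(len(channel)) if i_ % 2 == 0
    ))
    n_shelf = max(0, round(config.shelf_fraction * n) - sum(
        1 for i_ in range(len(channel)) if i_ % 2 == 1
    ))
    if n_island + n_shore + n_shelf > len(plain):
        raise ConfigError("substructure fractions infeasible at this n_probes")
    shuffled_plain = rng.permutation(plain)
    substructure[shuffled_plain[:n_island]] = "island"
    substructure[shuffled_plain[n_island : n_island + n_shore]] = "shore"
    substructure[
        shuffled_plain[n_island + n_shore : n_island + n_shore + n_shelf]
    ] = "shelf"
    substructure[shuffled_plain[n_island + n_shore + n_shelf :]] = "open_sea"

    context = np.full(n, "CpG", dtype=object)
    context[ch_idx] = "CH"

    genes = np.full(n, "", dtype=object)
    gene_region = np.full(n, "", dtype=object)
    for idx, (gene, region) in gene_of.items():
        genes[idx] = gene
        gene_region[idx] = region

    flags = {}
    for name, frac in (
        ("sex", config.sex_fraction),
        ("snp", config.snp_fraction),
        ("selfhyb", config.selfhyb_fraction),
    ):
        flags[name] = rng.random(n) < frac if frac > 0 else np.zeros(n, dtype=bool)

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "context": context,
            "substructure": substructure,
            "genes": genes,
            "gene_region": gene_region,
            "sex": flags["sex"],
            "snp": flags["snp"],
            "selfhyb": flags["selfhyb"],
        },
        index=pd.Index(ids, name="probe_id"),
    )
    manifest = Manifest(df, copy=False)

    def regions_of(name: str, rows, genes_map=None) -> RegionSet:
        return RegionSet(
            name=name,
            df=pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]),
            region_genes=genes_map,
        )

    region_sets = {
        "LAD": regions_of("LAD", lad_rows),
        "ESC_enhancer": regions_of("ESC_enhancer", shared_rows + esc_rows),
        "KC_enhancer": regions_of("KC_enhancer", shared_rows + kc_rows),
        "EpSC_gained": regions_of("EpSC_gained", gained_rows, region_genes),
        "EpSC_lost": regions_of("EpSC_lost", lost_rows),
    }
    pid = lambda idxs: [_probe_id(i) for i in idxs]
    return SyntheticManifest(
        manifest=manifest,
        region_sets=region_sets,
        keratin_genes=keratin_genes,
        keratin_promoter_probes=pid(ker_prom),
        keratin_body_probes=pid(ker_body),
        shared_enhancer_probes=pid(shared_idx),
        esc_only_probes=pid(esc_only_idx),
        kc_only_probes=pid(kc_only_idx),
        gained_probes=pid(gained_idx),
        lost_probes=pid(lost_idx),
        lad_probes=pid(lad_idx),
        ch_probes=pid(ch_idx),
        ch_affected=pid(ch_affected_idx),
        plain_probes=pid(plain),
    )


def _index_of(manifest: Manifest, probe_ids: list[str]) -> np.ndarray:
    return manifest.probe_ids.get_indexer(probe_ids)


def _baseline_mu(bundle: SyntheticManifest) -> np.ndarray:
    mdf = bundle.manifest.df
    mu = np.array([BASELINES[s] for s in mdf["substructure"]], dtype=float)
    m = bundle.manifest
    mu[_index_of(m, bundle.ch_probes)] = CH_BASELINE
    mu[_index_of(m, bundle.keratin_promoter_probes)] = KERATIN_BASELINE
    mu[_index_of(m, bundle.keratin_body_probes)] = KERATIN_BASELINE
    for probes in (
        bundle.shared_enhancer_probes,
        bundle.esc_only_probes,
        bundle.kc_only_probes,
    ):
        mu[_index_of(m, probes)] = ENHANCER_BASELINE
    mu[_index_of(m, bundle.gained_probes)] = GAINED_BASELINE
    mu[_index_of(m, bundle.lost_probes)] = LOST_BASELINE
    return mu


def _disease_shift(bundle: SyntheticManifest, config: CohortConfig) -> np.ndarray:
    mdf = bundle.manifest.df
    m = bundle.manifest
    shift = np.zeros(len(mdf))
    plain_idx = _index_of(m, bundle.plain_probes)
    sub = mdf["substructure"].to_numpy()
    plain_island = plain_idx[sub[plain_idx] == "island"]
    plain_os = plain_idx[sub[plain_idx] == "open_sea"]
    shift[plain_island] = config.island_hyper
    shift[plain_os] = config.open_sea_hypo
    shift[_index_of(m, bundle.lad_probes)] = config.lad_hypo
    shift[_index_of(m, bundle.ch_affected)] = config.ch_gain
    return shift


def _subclass_shift(bundle: SyntheticManifest, config: CohortConfig) -> np.ndarray:
    m = bundle.manifest
    extra = np.zeros(len(m))
    sep = config.subclass_separation
    extra[_index_of(m, bundle.keratin_promoter_probes)] = -sep
    extra[_index_of(m, bundle.gained_probes)] = +sep
    extra[_index_of(m, bundle.esc_only_probes)] = -sep
    return extra


def embed_age(clock: ClockModel, age: float) -> pd.Series:
    """Beta pattern over the clock probes whose linear score equals the
    transformed age exactly (noiseless inversion)."""
    w = clock.weights.to_numpy()
    target = age_transform(age, clock.adult_age)
    base_score = clock.intercept + float(w.sum()) * 0.5
    denom = float((w**2).sum())
    if denom == 0:
        if not np.isclose(target, clock.intercept):
            raise ValueError("zero-weight clock cannot embed a non-intercept age")
        beta = np.full(len(w), 0.5)
    else:
        beta = 0.5 + (target - base_score) * w / denom
    if (beta < 0).any() or (beta > 1).any():
        raise ValueError(f"age {age} is not embeddable within [0, 1] beta values")
    return pd.Series(beta, index=clock.probe_ids)


def generate_clock(
    source,
    n_clock_probes: int = 50,
    seed: int = 0,
    adult_age: float = 20.0,
) -> ClockModel:
    """Random sparse clock over gene-free CpG probes.

    The intercept is centered so that a flat beta = 0.5 profile predicts 60
    years, keeping embedded patterns for ordinary adult ages within [0, 1].
    """
    if isinstance(source, SyntheticManifest):
        candidates = pd.Index(source.plain_probes)
        manifest = source.manifest
    else:
        manifest = source
        mdf = manifest.df
        candidates = mdf.index[(mdf["context"] == "CpG") & (mdf["genes"] == "")]
    if len(candidates) < n_clock_probes:
        raise ConfigError("not enough candidate probes for the requested clock size")
    rng = _rng(seed, 21)
    probes = pd.Index(rng.choice(candidates, size=n_clock_probes, replace=False))
    weights = pd.Series(rng.normal(0.0, 0.5, size=n_clock_probes), index=probes)
    intercept = age_transform(60.0, adult_age) - float(weights.sum()) * 0.5
    return ClockModel(intercept=intercept, weights=weights, adult_age=adult_age)


def _make_noise(
    rng: np.random.Generator,
    bundle: SyntheticManifest,
    config: CohortConfig,
    n_samples: int,
) -> np.ndarray:
    scale = np.array(
        [
            config.substructure_noise_scale.get(s, 1.0)
            for s in bundle.manifest.df["substructure"]
        ]
    )
    if config.noise_sd == 0:
        return np.zeros((len(scale), n_samples))
    return rng.normal(0.0, 1.0, size=(len(scale), n_samples)) * (
        config.noise_sd * scale
    )[:, None]


def generate_cohort(
    bundle: SyntheticManifest,
    config: CohortConfig,
    clock: ClockModel | None = None,
) -> CohortResult:
    """Cohort beta matrix plus sample sheet with latent subclass truth.

    Healthy samples sit at substructure-typical baselines; AK/cSCC samples
    receive the configured landscape shifts; a ``subclass_fraction`` of each
    lesion group additionally receives the EpSC-like signature.  When a clock
    is supplied, its probes are overwritten with patterns embedding the
    per-sample target age (chronological for healthy, shifted for lesions).
    Clamping to [0, 1] is counted in the report.
    """
    rng = _rng(config.seed, 11)
    m = bundle.manifest
    groups = (
        [("healthy", f"H{i + 1:02d}") for i in range(config.n_healthy)]
        + [("AK", f"A{i + 1:02d}") for i in range(config.n_ak)]
        + [("cSCC", f"S{i + 1:02d}") for i in range(config.n_cscc)]
    )
    sample_ids = [sid for _, sid in groups]
    group_labels = [g for g, _ in groups]
    ages = rng.integers(50, 81, size=len(groups)).astype(float)

    latent = np.array([""] * len(groups), dtype=object)
    for label, n_in_group in (("AK", config.n_ak), ("cSCC", config.n_cscc)):
        idx = [i for i, g in enumerate(group_labels) if g == label]
        n_epsc = round(config.subclass_fraction * n_in_group)
        chosen = rng.permutation(idx)[:n_epsc]
        latent[idx] = "keratinocyte_like"
        latent[chosen] = "EpSC_like"

    base = _baseline_mu(bundle)
    shift = _disease_shift(bundle, config)
    extra = _subclass_shift(bundle, config)

    mu = np.tile(base[:, None], (1, len(groups)))
    lesion_cols = np.array([g in ("AK", "cSCC") for g in group_labels])
    mu[:, lesion_cols] += shift[:, None]
    epsc_cols = latent == "EpSC_like"
    mu[:, epsc_cols] += extra[:, None]

    target_ages = ages.copy()
    if clock is not None:
        clock_rows = _index_of(m, list(clock.probe_ids))
        if (clock_rows < 0).any():
            raise ConfigError("clock probes missing from the manifest")
        for col in range(len(groups)):
            t = ages[col]
            if lesion_cols[col]:
                t += config.tumor_age_shift
                if epsc_cols[col]:
                    t += config.epsc_age_shift
            target_ages[col] = t
            mu[clock_rows, col] = embed_age(clock, t).to_numpy()

    noise = _make_noise(rng, bundle, config, len(groups))
    raw = mu + noise
    values = np.clip(raw, 0.0, 1.0)
    clamp_events = int((raw != values).sum())

    beta = BetaMatrix(
        pd.DataFrame(values, index=m.probe_ids, columns=sample_ids), copy=False
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": group_labels,
                "chronological_age": ages,
                "latent_subclass": latent,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        copy=False,
    )
    report = {
        "clamp_events": clamp_events,
        "target_ages": pd.Series(target_ages, index=sample_ids),
    }
    return CohortResult(beta=beta, samples=sheet, report=report)


def generate_references(
    bundle: SyntheticManifest, config: CohortConfig
) -> BetaMatrix:
    """Noise-free reference methylomes: ESC, keratinocyte, EpSC, diffKC.

    Each reference is the healthy baseline with its signature probes moved by
    ``reference_margin``: ESC and keratinocyte are hypomethylated at their
    own enhancer probes; EpSC and diffKC differ at the gained/lost regions.
    A zero margin makes all references indistinguishable.
    """
    m = bundle.manifest
    base = _baseline_mu(bundle)
    margin = config.reference_margin
    cols = {}
    esc = base.copy()
    esc_rows = _index_of(m, bundle.shared_enhancer_probes + bundle.esc_only_probes)
    esc[esc_rows] = np.clip(esc[esc_rows] - margin, 0, 1)
    cols["ESC"] = esc
    kc = base.copy()
    kc_rows = _index_of(m, bundle.shared_enhancer_probes + bundle.kc_only_probes)
    kc[kc_rows] = np.clip(kc[kc_rows] - margin, 0, 1)
    cols["keratinocyte"] = kc
    gained_rows = _index_of(m, bundle.gained_probes)
    lost_rows = _index_of(m, bundle.lost_probes)
    epsc = base.copy()
    epsc[gained_rows] = np.clip(epsc[gained_rows] - margin, 0, 1)
    epsc[lost_rows] = np.clip(epsc[lost_rows] + margin, 0, 1)
    cols["EpSC"] = epsc
    diffkc = base.copy()
    diffkc[gained_rows] = np.clip(diffkc[gained_rows] + margin, 0, 1)
    diffkc[lost_rows] = np.clip(diffkc[lost_rows] - margin, 0, 1)
    cols["diffKC"] = diffkc
    return BetaMatrix(pd.DataFrame(cols, index=m.probe_ids), copy=False)


def generate_pan_cancer(
    bundle: SyntheticManifest,
    config: CohortConfig,
    n_samples: int = 20,
    seed: int = 0,
    probe_subset_fraction: float = 0.6,
) -> CohortResult:
    """Stand-in for an external dedifferentiated tumor cohort on a smaller
    probe platform: a random probe subset with keratin-promoter
    hypomethylation planted in every sample."""
    rng = _rng(seed, 31)
    m = bundle.manifest
    base = _baseline_mu(bundle) + _disease_shift(bundle, config)
    dediff = np.zeros(len(m))
    dediff[_index_of(m, bundle.keratin_promoter_probes)] = -config.subclass_separation
    mu = base + dediff
    noise = _make_noise(rng, bundle, config, n_samples)
    values = np.clip(mu[:, None] + noise, 0.0, 1.0)
    sample_ids = [f"P{i + 1:02d}" for i in range(n_samples)]
    keep_mask = rng.random(len(m)) < probe_subset_fraction
    df = pd.DataFrame(values, index=m.probe_ids, columns=sample_ids).loc[keep_mask]
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": "pan_cancer", "chronological_age": np.nan},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        copy=False,
    )
    return CohortResult(
        beta=BetaMatrix(df, copy=False),
        samples=sheet,
        report={"clamp_events": 0, "n_probes_kept": int(keep_mask.sum())},
    )


@dataclass
class VariantConfig:
    """Marginal rates for the synthetic annotated variant table."""

    overlap_rate: float = 0.05
    platypus_rate: float = 0.05
    indel_fraction: float = 0.2
    depth_mean: float = 180.0
    depth_sd: float = 50.0
    dbsnp_common_rate: float = 0.05
    omim_given_common: float = 0.3
    af_nonzero_rate: float = 0.05
    coding_rate: float = 0.9
    improper_mapping_rate: float = 0.0
    inject_edge_cases: bool = True

    def __post_init__(self):
        for name in (
            "overlap_rate",
            "platypus_rate",
            "indel_fraction",
            "dbsnp_common_rate",
            "omim_given_common",
            "af_nonzero_rate",
            "coding_rate",
            "improper_mapping_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


_BASES = np.array(list("ACGT"))


def generate_variants(
    n: int, config: VariantConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Annotated variant table with controlled marginal rates.

    When edge-case injection is on (and the overlap rate is non-zero) the
    first rows are crafted: a fully clean SNV, a dbSNP-common variant rescued
    by OMIM, and SNVs sitting exactly at and just below the score-8
    retention boundary.  A ``confidence_score`` column is included.
    """
    config = config or VariantConfig()
    rng = _rng(seed, 41)
    df = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n)],
            "pos": rng.integers(1, 50_000_000, size=n),
            "ref": rng.choice(_BASES, size=n),
            "alt": rng.choice(_BASES, size=n),
            "kind": np.where(
                rng.random(n) < config.indel_fraction, "indel", "SNV"
            ),
        }
    )
    for flag in OVERLAP_FLAGS:
        df[flag] = rng.random(n) < config.overlap_rate
    platypus = []
    for i in range(n):
        if df.at[i, "kind"] == "indel":
            chosen = [
                f for f in PLATYPUS_FILTERS if rng.random() < config.platypus_rate
            ]
            platypus.append(";".join(chosen))
        else:
            platypus.append("")
    df["platypus_filters"] = platypus
    df["depth"] = np.maximum(
        1, rng.normal(config.depth_mean, config.depth_sd, size=n).astype(int)
    )
    df["dbsnp_common"] = rng.random(n) < config.dbsnp_common_rate
    df["omim_record"] = df["dbsnp_common"] & (
        rng.random(n) < config.omim_given_common
    )
    for col in ("exac_af", "evs_af", "inhouse_af"):
        nonzero = rng.random(n) < config.af_nonzero_rate
        df[col] = np.where(nonzero, rng.uniform(0.0, 0.05, size=n), 0.0)
    df["coding"] = rng.random(n) < config.coding_rate
    df["properly_mapped"] = rng.random(n) >= config.improper_mapping_rate

    if config.inject_edge_cases and config.overlap_rate > 0 and n >= 4:
        clean = {
            **{f: False for f in OVERLAP_FLAGS},
            "kind": "SNV",
            "platypus_filters": "",
            "dbsnp_common": False,
            "omim_record": False,
            "exac_af": 0.0,
            "evs_af": 0.0,
            "inhouse_af": 0.0,
            "coding": True,
            "properly_mapped": True,
        }
        for col, val in clean.items():
            df.loc[0, col] = val
            df.loc[1, col] = val
            df.loc[2, col] = val
            df.loc[3, col] = val
        df.loc[1, ["dbsnp_common", "omim_record"]] = True, True
        df.loc[2, ["repeats", "dac_blacklist"]] = True, True  # score exactly 8
        df.loc[3, ["repeats", "dac_blacklist", "self_chain"]] = True, True, True

    df["confidence_score"] = confidence_scores(df)
    return df
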