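import numpy as np
import pandas as pd
import pytest

from methylscape.synthetic import (
    CohortConfig,
    generate_clock,
    generate_cohort,
    generate_manifest,
    generate_references,
)
from methylscape.types import BetaMatrix, Manifest, RegionSet, SampleSheet


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_probes=2000, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_clock(small_bundle):
    return generate_clock(small_bundle, n_clock_probes=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_bundle, small_config, small_clock):
    return generate_cohort(small_bundle, small_config, clock=small_clock)


@pytest.fixture(scope="session")
def small_references(small_bundle, small_config):
    return generate_references(small_bundle, small_config)


@pytest.fixture
def tiny_manifest():
    """Hand-built 6-probe manifest on two chromosomes."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "pos": [100, 101, 150, 200, 100, 500],
            "context": ["CpG", "CpG", "CH", "CpG", "CpG", "CpG"],
            "substructure": [
                "island",
                "shore",
                "open_sea",
                "open_sea",
                "shelf",
                "island",
            ],
            "genes": ["GENEA", "GENEA;GENEB", "", "", "GENEB", ""],
            "gene_region": ["promoter", "body;promoter", "", "", "body", ""],
            "sex": [False] * 6,
            "snp": [False] * 6,
            "selfhyb": [False] * 6,
        },
        index=pd.Index([f"cg{i:02d}" for i in range(6)], name="probe_id"),
    )
    return Manifest(df)


@pytest.fixture
def tiny_beta(tiny_manifest):
    rng = np.random.default_rng(0)
    values = rng.uniform(0.1, 0.9, size=(6, 4))
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=tiny_manifest.probe_ids,
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "group": ["healthy", "healthy", "AK", "AK"],
                "chronological_age": [60.0, 70.0, 65.0, 75.0],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


def brute_force_membership(manifest, regions):
    """Independent O(n*m) oracle for probes_in_regions."""
    out = {}
    for row in regions.df.itertuples(index=False):
        members = []
        for probe_id, ann in manifest.df.iterrows():
            if ann["chrom"] == row.chrom and row.start < ann["pos"] <= row.end:
                members.append((ann["pos"], probe_id))
        out[row.region_id] = [p for _, p in sorted(members)]
    return out


def make_region_set(name, rows):
    return RegionSet(
        name=name,
        df=pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]),
    )
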