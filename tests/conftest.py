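"""Shared fixtures: a small simulated experiment and toy inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mendelscan import SimulationConfig, gscore_table, simulate_dataset

SMALL_CONFIG = SimulationConfig(
    n_blocks=2,
    n_linkage_groups=2,
    lg_length_bp=400_000,
    n_snps_per_lg=80,
    depth_law=("negative-binomial", 30.0, 0.5),
    missing_family_fraction=0.2,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_gscores(small_dataset):
    ds = small_dataset
    return gscore_table(ds.counts, ds.parents, ds.design)


@pytest.fixture()
def toy_gtable():
    """Hand-built per-SNP G table: 2 families x 2 treatments x 6 loci on one
    chromosome, positions straddling the 100-kb window boundary."""
    rows = []
    positions = [10_000, 50_000, 90_000, 99_999, 100_000, 100_001]
    # windows of size 100_000: first five positions in window 0, last in window 1
    g_values = {
        ("F1", "low"): [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        ("F1", "reference"): [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        ("F2", "low"): [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        ("F2", "reference"): [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    }
    for (fam, treat), gs in g_values.items():
        for pos, g in zip(positions, gs):
            rows.append(
                {
                    "family_id": fam,
                    "treatment": treat,
                    "chrom": "LG1",
                    "pos": pos,
                    "o_ref": 10.0,
                    "o_alt": 10.0,
                    "e_ref": 10.0,
                    "e_alt": 10.0,
                    "usable": True,
                    "g": g,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
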