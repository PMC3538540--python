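"""Shared fixtures: tiny hand-built datasets and small simulated panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from catld.genotype_io import GenotypeDataset
from catld.simulate import BreedConfig, SimConfig, simulate_panel


def make_dataset(calls, populations=None, chroms=None, positions=None) -> GenotypeDataset:
    """Build a GenotypeDataset from a genotype-code matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations or ["P"] * n,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"x{j}" for j in range(m)],
            "chrom": chroms or ["1"] * m,
            "region": chroms or ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1),
        }
    )
    return GenotypeDataset(samples, snps, calls)


def small_breed_config(
    seed: int,
    bottleneck_ne: int = 50,
    sample_n: int = 20,
    n_regions: int = 2,
    snps_per_region: int = 50,
    missing_rate: float = 0.02,
    recomb_rate: float = 1e-8,
    founder_count: int = 30,
) -> SimConfig:
    """One-breed panel at desk scale; bottleneck severity is the dial."""
    breed = BreedConfig(
        name="B",
        pool="east",
        sample_n=sample_n,
        founder_count=founder_count,
        bottleneck_ne=bottleneck_ne,
        bottleneck_generations=15,
        expansion_ne=200,
        total_generations=25,
    )
    return SimConfig(
        seed=seed,
        n_regions=n_regions,
        snps_per_region=snps_per_region,
        dense_end_snps=max(1, snps_per_region // 3),
        pool_size=100,
        pool_generations=80,
        missing_rate=missing_rate,
        recomb_rate=recomb_rate,
        breeds=[breed],
    )


@pytest.fixture(scope="session")
def small_panel():
    """A 20-cat, 2-region panel with its phased truth (seed-fixed)."""
    return simulate_panel(small_breed_config(seed=3, missing_rate=0.0, sample_n=50))


@pytest.fixture(scope="session")
def multi_pop_panel():
    """Six small populations from two diverged pools, for F_st/tree stages."""
    breeds = [
        BreedConfig(name=name, pool=pool, sample_n=12, founder_count=25,
                    bottleneck_ne=25, bottleneck_generations=8,
                    expansion_ne=80, total_generations=20)
        for name, pool in [
            ("E1", "east"), ("E2", "east"), ("E3", "east"),
            ("W1", "west"), ("W2", "west"), ("W3", "west"),
        ]
    ]
    cfg = SimConfig(seed=11, n_regions=3, snps_per_region=40, dense_end_snps=13,
                    pool_size=100, pool_generations=80, split_F=0.08,
                    missing_rate=0.02, breeds=breeds)
    return simulate_panel(cfg)
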