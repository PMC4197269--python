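from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methpanel.methio import CpGSite, MethylationCall, TargetRegion
from methpanel.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition synthetic cohort at a fixed seed (15 samples,
    500 regions, 50 planted DMRs, 30 coupled pairs)."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit tests."""
    return generate_cohort(
        SimConfig(n_regions=60, n_planted_dmrs=8, n_planted_pairs=6, seed=3)
    )


def random_calls(rng, n_sites=30, chroms=("chr1", "chr2", "chrX"), max_cov=25):
    """Random per-sample methylation calls over a shared site pool."""
    sites = [
        CpGSite(chroms[int(rng.integers(len(chroms)))], int(rng.integers(0, 5000)))
        for _ in range(n_sites)
    ]
    sites = list(dict.fromkeys(sites))
    calls = []
    for site in sites:
        if rng.random() < 0.1:
            continue  # site absent in this sample
        cov = int(rng.integers(0, max_cov))
        m = int(rng.binomial(cov, rng.random())) if cov else 0
        calls.append(MethylationCall(site, m, cov - m))
    return calls


def random_regions(rng, n, chrom_pool=("chr1", "chr2"), max_pos=50_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            TargetRegion(
                chrom_pool[int(rng.integers(len(chrom_pool)))],
                start,
                start + int(rng.integers(100, 2000)),
                f"r{i}",
            )
        )
    return out


def random_region_means(rng, n_regions, samples):
    df = pd.DataFrame(
        rng.random((n_regions, len(samples))),
        index=[f"r{i}" for i in range(n_regions)],
        columns=samples,
    )
    # sprinkle missing values
    mask = rng.random(df.shape) < 0.03
    return df.where(~mask)
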