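import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from poolmaf import (
    CohortGenotypes,
    assign_pools,
    make_site_table,
    random_site_table,
    simulate_cohort,
    simulate_pool_counts,
)


@pytest.fixture(scope="session")
def wes_cohort():
    """Exome-style cohort: 100 diploid individuals, 500 sites spanning
    rare, low-frequency and common variants."""
    sites = random_site_table(500, seed=7)
    return simulate_cohort(100, sites, seed=7)


@pytest.fixture(scope="session")
def wes_design(wes_cohort):
    """10 pools of 10 (ploidy 20 per pool, 200 allele copies in total)."""
    return assign_pools(wes_cohort, pool_size=10, seed=7)


@pytest.fixture(scope="session")
def wes_counts(wes_cohort, wes_design):
    """Pooled counts at mean depth 200x with a 0.5% per-read error rate."""
    return simulate_pool_counts(
        wes_cohort,
        wes_design,
        depth_model=("negative_binomial", 200.0, 8.0),
        error_rate=0.005,
        seed=7,
    )


@pytest.fixture()
def tiny_cohort():
    """Hand-specified 6-individual, 4-site cohort for exact-value tests."""
    sites = make_site_table([0.05, 0.2, 0.0, 0.5], seed=3)
    genotypes = np.array(
        [
            [0, 1, 0, 2],
            [0, 0, 0, 1],
            [1, 1, 0, 0],
            [0, 2, 0, 1],
            [0, 0, 0, 2],
            [0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return CohortGenotypes(sites=sites, genotypes=genotypes)


@pytest.fixture()
def tiny_counts():
    """Two pools, three sites, fixed hand-written depths."""
    rows = []
    data = {
        ("1", 100): {"poolA": (95, 5), "poolB": (100, 0)},
        ("1", 200): {"poolA": (50, 50), "poolB": (40, 60)},
        ("1", 300): {"poolA": (120, 0), "poolB": (80, 0)},
    }
    for (chrom, pos), pools in data.items():
        for pool, (r, a) in pools.items():
            rows.append(
                {"chrom": chrom, "pos": pos, "pool": pool, "ref_depth": r, "alt_depth": a}
            )
    from poolmaf import PooledSiteCounts

    return PooledSiteCounts(counts=pd.DataFrame(rows))
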