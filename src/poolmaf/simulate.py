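"""Synthetic pooled-sequencing cohorts.

Generates individual-level diploid genotypes under Hardy-Weinberg
equilibrium, partitions individuals into labelled pools, and draws pooled
read counts per site with a configurable depth model and a symmetric
per-read substitution error.  This emulates the two study designs the
package targets -- exome sequencing of 100 individuals in 10 pools of 10,
and genome sequencing of 20 individuals in a case and a control pool of
10 each -- so every downstream stage can be tested without external data.

Sites are simulated independently (no linkage disequilibrium); only
biallelic autosomal SNVs are represented.  Counts are generated directly:
there is no read-level simulation, alignment or duplicate modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import classify_frequency

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "q", "freq_class", "functional", "gene"]
COUNT_COLUMNS = ["chrom", "pos", "pool", "ref_depth", "alt_depth"]

_BASES = np.array(list("ACGT"))


@dataclass
class CohortGenotypes:
    """Individual-level truth panel: site metadata plus a genotype matrix.

    ``genotypes[i, s]`` is the number of copies of the alternative allele
    (0, 1 or 2) carried by individual ``i`` at site ``s``.  ``sites`` holds
    one row per site with the true population alternative-allele frequency
    ``q`` and its frequency class.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[1] != len(self.sites):
            raise ValueError("genotype matrix shape inconsistent with site table")
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("genotypes must be allele-copy counts in {0, 1, 2}")
        self.genotypes = g.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def cohort_aaf(self) -> np.ndarray:
        """Realized alternative-allele frequency per site (alt copies / 2n)."""
        return self.genotypes.sum(axis=0) / (2 * self.n_individuals)

    def cohort_maf(self) -> np.ndarray:
        aaf = self.cohort_aaf()
        return np.minimum(aaf, 1.0 - aaf)


@dataclass(frozen=True)
class Pool:
    label: str
    role: str
    members: tuple[int, ...]
    weights: tuple[float, ...]


@dataclass
class PoolDesign:
    """Partition of cohort individuals into labelled, weighted pools."""

    pools: list[Pool]
    pool_size: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.pools:
            if p.role not in ("case", "control"):
                raise ValueError(f"pool {p.label!r}: unknown role {p.role!r}")
            if len(p.members) != self.pool_size:
                raise ValueError(f"pool {p.label!r}: expected {self.pool_size} members")
            if any(w <= 0 for w in p.weights):
                raise ValueError(f"pool {p.label!r}: weights must be positive")
            if not np.isclose(sum(p.weights), 1.0):
                raise ValueError(f"pool {p.label!r}: weights must sum to 1")
            if seen & set(p.members):
                raise ValueError("individual assigned to more than one pool")
            seen |= set(p.members)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def ploidy(self) -> int:
        """Allele copies per pool: 2k for k diploid members."""
        return 2 * self.pool_size

    @property
    def total_alleles(self) -> int:
        """Denominator of the allele-count frequency estimate (n_pools * 2k)."""
        return self.n_pools * self.ploidy

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pools]

    def pools_by_role(self, role: str) -> list[str]:
        return [p.label for p in self.pools if p.role == role]


@dataclass
class PooledSiteCounts:
    """Per (site, pool) reference/alternative read depths.

    ``counts`` columns: chrom, pos, pool, ref_depth, alt_depth.  The error
    rate and depth model used to generate the counts travel along as
    metadata; they are informational for simulated data and None for
    counts read from real files.
    """

    counts: pd.DataFrame
    error_rate: float | None = None
    depth_model: tuple | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if len(self.counts):
            if (self.counts["ref_depth"] < 0).any() or (self.counts["alt_depth"] < 0).any():
                raise ValueError("read depths must be non-negative")

    @property
    def total_depth(self) -> pd.Series:
        return self.counts["ref_depth"] + self.counts["alt_depth"]

    @property
    def pools(self) -> list[str]:
        return sorted(self.counts["pool"].unique())


def make_site_table(
    qs,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 1_000,
    functional=None,
    genes=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a site table from true population frequencies.

    Ref/alt bases are drawn (distinct) from a seeded generator purely for
    record realism; positions are evenly spaced 1-based coordinates.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.ndim != 1 or len(qs) == 0:
        raise ValueError("site frequencies must be a non-empty 1-D sequence")
    if (qs < 0).any() or (qs > 1).any():
        raise ValueError("population frequency q must lie in [0, 1]")
    n = len(qs)
    rng = np.random.default_rng(0 if seed is None else seed)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    if functional is None:
        functional = np.ones(n, dtype=bool)
    if genes is None:
        genes = [f"GENE{i // 10 + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "q": qs,
            "freq_class": [classify_frequency(q) for q in qs],
            "functional": np.asarray(functional, dtype=bool),
            "gene": list(genes),
        }
    )


def random_site_table(
    n_sites: int,
    seed: int,
    class_fractions: dict[str, float] | None = None,
    chrom: str = "1",
) -> pd.DataFrame:
    """Site table spanning rare, low-frequency and common variants.

    Class fractions default to 30% rare (q in [0.005, 0.01)), 30%
    low-frequency (q in [0.01, 0.05]) and 40% common (q in (0.05, 0.5]),
    a mix that exercises the full range a rare-variant screen cares about.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    fractions = class_fractions or {"rare": 0.3, "low": 0.3, "common": 0.4}
    rng = np.random.default_rng(seed)
    bounds = {"rare": (0.005, 0.01), "low": (0.01, 0.05), "common": (0.05, 0.5)}
    classes = rng.choice(
        list(fractions), size=n_sites, p=np.array(list(fractions.values()))
    )
    lo = np.array([bounds[c][0] for c in classes])
    hi = np.array([bounds[c][1] for c in classes])
    qs = rng.uniform(lo, hi)
    return make_site_table(qs, chrom=chrom, seed=seed)


def simulate_cohort(n_individuals: int, sites: pd.DataFrame, seed: int) -> CohortGenotypes:
    """Draw diploid genotypes under Hardy-Weinberg equilibrium.

    Each individual's genotype at a site with population frequency ``q``
    is an independent Binomial(2, q) draw, so heterozygosity follows the
    2q(1-q) expectation.  Deterministic for a fixed seed.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if len(sites) == 0:
        raise ValueError("site table is empty")
    qs = np.asarray(sites["q"], dtype=float)
    if (qs < 0).any() or (qs > 1).any():
        raise ValueError("population frequency q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, qs, size=(n_individuals, len(qs)))
    return CohortGenotypes(sites=sites.reset_index(drop=True), genotypes=genotypes)


def assign_pools(
    cohort: CohortGenotypes,
    pool_size: int,
    roles: list[str] | None = None,
    weights=None,
    seed: int | None = None,
) -> PoolDesign:
    """Partition the cohort into pools of ``pool_size`` individuals.

    Individuals are shuffled (seeded) before partitioning so pool
    membership is random but reproducible; ``seed=None`` keeps cohort
    order.  ``weights`` are per-member DNA contribution fractions within
    a pool; they default to equal (1/k) and are normalized to sum to 1.
    """
    n = cohort.n_individuals
    if pool_size < 1 or n % pool_size != 0:
        raise ValueError(
            f"cohort of {n} individuals is not divisible into pools of {pool_size}"
        )
    n_pools = n // pool_size
    if roles is None:
        roles = ["case"] * n_pools
    if len(roles) != n_pools:
        raise ValueError(f"expected {n_pools} pool roles, got {len(roles)}")
    order = np.arange(n)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    if weights is None:
        weights = np.full(pool_size, 1.0 / pool_size)
    else:
        weights = np.asarray(weights, dtype=float)
        if (weights <= 0).any():
            raise ValueError("contribution weights must be positive")
        weights = weights / weights.sum()
    pools = []
    for j in range(n_pools):
        members = tuple(int(i) for i in order[j * pool_size : (j + 1) * pool_size])
        pools.append(
            Pool(
                label=f"pool{j + 1:02d}",
                role=roles[j],
                members=members,
                weights=tuple(weights),
            )
        )
    return PoolDesign(pools=pools, pool_size=pool_size)


def _draw_depths(rng, model: tuple, size: int) -> np.ndarray:
    name, mean, *rest = model
    if name in ("negative_binomial", "negbin", "nb"):
        dispersion = rest[0] if rest else 8.0
        if dispersion <= 0:
            raise ValueError("negative binomial dispersion must be > 0")
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=size)
    if name == "poisson":
        return rng.poisson(mean, size=size)
    if name in ("fixed", "constant"):
        return np.full(size, int(round(mean)))
    raise ValueError(f"unknown depth model {name!r}")


def simulate_pool_counts(
    cohort: CohortGenotypes,
    design: PoolDesign,
    depth_model: tuple = ("negative_binomial", 200.0, 8.0),
    error_rate: float = 0.005,
    seed: int = 0,
) -> PooledSiteCounts:
    """Draw pooled read counts for every (site, pool).

    The pool allele fraction is the contribution-weighted mean of member
    genotypes divided by 2.  Total depth D comes from ``depth_model``
    (negative binomial by default -- capture depth is over-dispersed;
    Poisson and fixed depth are selectable).  Alternative-read counts are
    Binomial(D, p(1-e) + (1-p)e) with the symmetric per-read substitution
    rate ``e``, so reads flip ref<->alt with equal probability.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5): the flip model degenerates")
    for p in design.pools:
        if max(p.members) >= cohort.n_individuals:
            raise ValueError(f"pool {p.label!r} references individuals outside the cohort")
    rng = np.random.default_rng(seed)
    n_sites = cohort.n_sites
    frames = []
    for pool in design.pools:
        w = np.asarray(pool.weights)
        g = cohort.genotypes[list(pool.members), :]  # k x n_sites
        p_alt = w @ g / 2.0
        p_read = p_alt * (1 - error_rate) + (1 - p_alt) * error_rate
        depth = _draw_depths(rng, depth_model, n_sites)
        alt = rng.binomial(depth, p_read)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cohort.sites["chrom"].to_numpy(),
                    "pos": cohort.sites["pos"].to_numpy(),
                    "pool": pool.label,
                    "ref_depth": depth - alt,
                    "alt_depth": alt,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    return PooledSiteCounts(counts=counts, error_rate=error_rate, depth_model=depth_model)
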