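"""Allele-frequency estimation from pooled read counts.

Two estimation strategies are implemented.  The *read-depth* strategy
takes the fraction of reads supporting the alternative allele, summed
over pools.  The *allele-count* strategy first calls an integer
alternative-allele count per pool under a ploidy of 2k (k diploid
individuals per pool), then divides the summed counts by the total number
of allele copies across pools -- e.g. n = 200 for 10 pools of 10
diploids, giving a minimum representable frequency of 1/200 = 0.5%.

The per-pool integer count is the maximum-likelihood value of
c in {0..2k} under a binomial read model with a symmetric per-read error
rate e: with p_c = (c/2k)(1-e) + (1-c/2k)e, the call is
argmax_c Binom(a; D, p_c), ties broken toward the smaller c (fewer
alternative alleles, the conservative choice).  Site polymorphism is
scored from the posterior odds of {c >= 1} against {c = 0} under a flat
prior on c, reported as a phred-scaled quality Q with
P(polymorphic) = 1 - 10^(-Q/10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)


def aaf_to_maf(aaf):
    """Fold an alternative-allele frequency onto [0, 0.5]."""
    aaf = np.asarray(aaf, dtype=float)
    if (aaf < 0).any() or (aaf > 1).any():
        raise ValueError("allele frequency must lie in [0, 1]")
    out = np.minimum(aaf, 1.0 - aaf)
    return float(out) if out.ndim == 0 else out


def quality_to_probability(q):
    """Probability of true polymorphism encoded by a phred-scaled quality.

    P = 1 - 10^(-Q/10): Q = 3 is just under a 50% chance of being a real
    polymorphism, Q = 10 is 90%.
    """
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("phred quality must be >= 0")
    out = 1.0 - np.power(10.0, -q / 10.0)
    return float(out) if out.ndim == 0 else out


def probability_to_quality(p):
    """Inverse of :func:`quality_to_probability`; P = 1 maps to +inf."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p >= 1).any():
        raise ValueError("probability must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        out = -10.0 * np.log10(1.0 - p)
    return float(out) if out.ndim == 0 else out


def _count_loglik(a: int, depth: int, ploidy: int, error_rate: float) -> np.ndarray:
    c = np.arange(ploidy + 1)
    p = (c / ploidy) * (1 - error_rate) + (1 - c / ploidy) * error_rate
    return binom.logpmf(a, depth, p)


def call_pool_allele_count(a: int, depth: int, ploidy: int, error_rate: float = 0.0) -> int:
    """Maximum-likelihood integer alternative-allele count for one pool."""
    if depth <= 0:
        raise ValueError("no call possible at zero depth")
    if not 0 <= a <= depth:
        raise ValueError("alt depth must satisfy 0 <= a <= D")
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    # argmax over ascending c returns the first maximum: smaller-c tie-break
    return int(np.argmax(_count_loglik(a, depth, ploidy, error_rate)))


def call_pool_allele_counts(alt, depth, ploidy: int, error_rate: float = 0.0) -> np.ndarray:
    """Elementwise ML allele counts for arrays of (alt, depth) pairs.

    Same model and tie-break as :func:`call_pool_allele_count`; entries
    with zero depth are returned as -1 (no call).
    """
    a = np.asarray(alt, dtype=float)
    d = np.asarray(depth, dtype=float)
    if a.shape != d.shape:
        raise ValueError("alt and depth arrays must align")
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    covered = d > 0
    if ((a < 0) | (a > d))[covered].any():
        raise ValueError("alt depth must satisfy 0 <= a <= D")
    c = np.arange(ploidy + 1)
    p = (c / ploidy) * (1 - error_rate) + (1 - c / ploidy) * error_rate
    out = np.full(a.shape, -1, dtype=int)
    if covered.any():
        ll = binom.logpmf(a[covered][..., None], d[covered][..., None], p)
        out[covered] = np.argmax(ll, axis=-1)
    return out


@dataclass(frozen=True)
class SiteCall:
    """Polymorphism call for one site with phred-scaled confidence."""

    polymorphic: bool
    quality: float
    probability: float


def classify_site(
    a: int, depth: int, ploidy: int, error_rate: float = 0.005, threshold: float = 0.5
) -> SiteCall:
    """Score a site as polymorphic from pooled counts.

    P(polymorphic) is the posterior mass on {c >= 1} under a flat prior
    over c in {0..2k}; Q = -10 log10(1 - P).  The flag is P > threshold
    (default 0.5, i.e. quality above ~3).
    """
    if depth <= 0:
        raise ValueError("no call possible at zero depth")
    ll = _count_loglik(a, depth, ploidy, error_rate)
    log_total = logsumexp(ll)
    log_p_mono = ll[0] - log_total  # log(1 - P)
    prob = float(-np.expm1(log_p_mono))
    quality = float(-10.0 * log_p_mono / LN10)
    return SiteCall(polymorphic=prob > threshold, quality=quality, probability=prob)


def estimate_aaf_read_depth(alt_depths, total_depths) -> float:
    """Pooled-read AAF: alternative reads over total reads across pools."""
    a = np.asarray(alt_depths, dtype=float)
    d = np.asarray(total_depths, dtype=float)
    covered = d > 0
    if not covered.any() or d.sum() == 0:
        raise ValueError("site uncovered: zero total depth across selected pools")
    return float(a[covered].sum() / d[covered].sum())


def estimate_aaf_allele_count(pool_counts, ploidy: int) -> float:
    """AAF from per-pool integer allele counts: sum(c_j) / (n_pools * 2k)."""
    c = np.asarray(pool_counts, dtype=float)
    if c.size == 0:
        raise ValueError("no pool counts supplied")
    if (c < 0).any() or (c > ploidy).any():
        raise ValueError(f"allele counts must lie in 0..{ploidy}")
    return float(c.sum() / (c.size * ploidy))


def estimate_maf_table(
    counts,
    ploidy: int,
    error_rate: float = 0.005,
    methods: tuple[str, ...] = ("read_depth", "allele_count"),
) -> pd.DataFrame:
    """Per-site AAF/MAF estimates by one or both strategies.

    ``counts`` is a :class:`~poolmaf.simulate.PooledSiteCounts` or its
    underlying data frame.  Pools with zero depth at a site are excluded
    from the read-depth estimate; for the allele-count method the site is
    dropped entirely (with a logged warning), since a per-pool count
    cannot be called without coverage.  Output columns: chrom, pos,
    method, pool_counts (comma-joined per-pool calls, allele_count only),
    aaf, maf, depth.
    """
    df = getattr(counts, "counts", counts)
    bad = set(methods) - {"read_depth", "allele_count"}
    if bad:
        raise ValueError(f"unknown estimation method(s): {sorted(bad)}")
    alt_m = df.pivot_table(
        index=["chrom", "pos"], columns="pool", values="alt_depth", sort=True
    )
    dep_m = (
        df.assign(depth=df["ref_depth"] + df["alt_depth"])
        .pivot_table(index=["chrom", "pos"], columns="pool", values="depth", sort=True)
    )
    alt = alt_m.fillna(0).to_numpy()
    dep = dep_m.fillna(0).to_numpy()
    total = dep.sum(axis=1).astype(int)
    rows = []
    if "read_depth" in methods:
        with np.errstate(invalid="ignore"):
            aaf = np.where(total > 0, alt.sum(axis=1) / np.maximum(total, 1), np.nan)
        for (chrom, pos), f, t in zip(alt_m.index, aaf, total):
            if t > 0:
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "method": "read_depth",
                        "pool_counts": "",
                        "aaf": float(f),
                        "maf": aaf_to_maf(float(f)),
                        "depth": int(t),
                    }
                )
    if "allele_count" in methods:
        fully_covered = (dep > 0).all(axis=1)
        n_dropped = int((~fully_covered).sum())
        if n_dropped:
            logger.warning(
                "allele-count estimation dropped %d site(s) with an uncovered pool",
                n_dropped,
            )
        calls = call_pool_allele_counts(alt, dep, ploidy, error_rate)
        for i, (chrom, pos) in enumerate(alt_m.index):
            if not fully_covered[i]:
                continue
            aaf = estimate_aaf_allele_count(calls[i], ploidy)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "method": "allele_count",
                    "pool_counts": ",".join(str(int(c)) for c in calls[i]),
                    "aaf": aaf,
                    "maf": aaf_to_maf(aaf),
                    "depth": int(total[i]),
                }
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "method", "pool_counts", "aaf", "maf", "depth"]
    )
    return out.sort_values(["chrom", "pos", "method"], kind="stable").reset_index(drop=True)
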