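"""Robustness experiments: read subsampling and pool-subset MAF deviation.

Two experiments probe how much the pooled MAF estimate depends on
sequencing depth and on the number of pools used.  Read subsampling
thins every pool's ref/alt counts to a fraction of the reads (each read
kept independently, i.e. binomial thinning) over several rounds and
re-estimates MAFs with the allele-count method, averaging rounds.  The
pool-subset experiment re-estimates the total MAF from k of the pools
only, for k from 1 up to the full design, recording the deviation from
validated truth per subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .estimate import aaf_to_maf, call_pool_allele_counts


def thin_counts(ref, alt, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Keep each read independently with probability ``fraction``.

    Binomial thinning of ref and alt depths; preserves the expected
    alternative-read fraction and reduces to the identity at fraction 1.
    """
    if not 0 < fraction <= 1:
        raise ValueError("retained fraction must lie in (0, 1]")
    ref = np.asarray(ref, dtype=int)
    alt = np.asarray(alt, dtype=int)
    return rng.binomial(ref, fraction), rng.binomial(alt, fraction)


@dataclass
class SubsampleResult:
    """Per-site mean MAF over thinning rounds at one retained fraction."""

    fraction: float
    rounds: int
    per_round: pd.DataFrame  # chrom, pos, round, maf
    mean_maf: pd.DataFrame  # chrom, pos, mean_maf, n_rounds_used
    seed: int


def subsample_reads(
    counts,
    fraction: float,
    rounds: int,
    ploidy: int,
    error_rate: float = 0.005,
    seed: int = 0,
) -> SubsampleResult:
    """Binomially thin read counts and re-estimate MAFs per round.

    Every (site, pool) keeps Binomial(depth, fraction) of its ref and alt
    reads independently, preserving the expected alt fraction.  MAF is
    re-estimated per round with the allele-count method; at fraction 1
    every round reproduces the full-data estimate exactly.  Sites where
    thinning leaves a pool with zero depth are skipped for that round
    (the allele-count method needs every pool covered), and the per-site
    mean is taken over the usable rounds.
    """
    if not 0 < fraction <= 1:
        raise ValueError("retained fraction must lie in (0, 1]")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    df = getattr(counts, "counts", counts)
    rng = np.random.default_rng(seed)
    ref_m = df.pivot_table(
        index=["chrom", "pos"], columns="pool", values="ref_depth", sort=True
    ).fillna(0).to_numpy().astype(int)
    alt_m = df.pivot_table(
        index=["chrom", "pos"], columns="pool", values="alt_depth", sort=True
    ).fillna(0).to_numpy().astype(int)
    index = df.pivot_table(
        index=["chrom", "pos"], columns="pool", values="alt_depth", sort=True
    ).index
    n_pools = ref_m.shape[1]
    frames = []
    for rnd in range(rounds):
        thin_ref, thin_alt = thin_counts(ref_m, alt_m, fraction, rng)
        dep = thin_ref + thin_alt
        usable = (dep > 0).all(axis=1)
        if not usable.any():
            continue
        calls = call_pool_allele_counts(thin_alt[usable], dep[usable], ploidy, error_rate)
        aaf = calls.sum(axis=1) / (n_pools * ploidy)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": index.get_level_values(0)[usable],
                    "pos": index.get_level_values(1)[usable],
                    "round": rnd,
                    "maf": np.minimum(aaf, 1.0 - aaf),
                }
            )
        )
    per_round = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "round", "maf"])
    )
    if len(per_round):
        mean_maf = (
            per_round.groupby(["chrom", "pos"], sort=True)["maf"]
            .agg(mean_maf="mean", n_rounds_used="size")
            .reset_index()
        )
    else:
        mean_maf = pd.DataFrame(columns=["chrom", "pos", "mean_maf", "n_rounds_used"])
    return SubsampleResult(
        fraction=fraction, rounds=rounds, per_round=per_round, mean_maf=mean_maf, seed=seed
    )


@dataclass
class PoolCurveResult:
    """MAF deviation from truth as a function of pools used."""

    deviations: pd.DataFrame  # site, k, draw, deviation
    summary: pd.DataFrame  # k, mean_abs_deviation, sd_deviation, n_draws
    seed: int


def pool_subset_deviation(
    pool_counts: np.ndarray,
    validated_maf,
    ploidy: int,
    k_range=None,
    draws: int = 200,
    seed: int = 0,
) -> PoolCurveResult:
    """Estimate MAFs from random pool subsets and record deviation from truth.

    ``pool_counts`` is a (sites x pools) matrix of called integer
    alternative-allele counts.  For each subset size k, pools are drawn
    without replacement within a draw; when the number of distinct
    subsets is at most ``draws`` all subsets are enumerated instead (so
    k = n_pools yields the single full-design deviation).  The estimate
    from a subset uses the allele-count method over k * 2k allele copies.
    """
    counts = np.asarray(pool_counts, dtype=int)
    if counts.ndim != 2:
        raise ValueError("pool_counts must be a (sites x pools) matrix")
    truth = np.asarray(validated_maf, dtype=float)
    n_sites, n_pools = counts.shape
    if truth.shape != (n_sites,):
        raise ValueError("validated MAFs must align with the site axis")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    k_values = list(k_range) if k_range is not None else list(range(1, n_pools + 1))
    if any(k < 1 or k > n_pools for k in k_values):
        raise ValueError(f"subset sizes must lie in 1..{n_pools}")
    rng = np.random.default_rng(seed)
    site_idx = np.arange(n_sites)
    frames = []
    for k in k_values:
        if comb(n_pools, k) <= draws:
            subsets = list(combinations(range(n_pools), k))
        else:
            subsets = [
                tuple(sorted(rng.choice(n_pools, size=k, replace=False)))
                for _ in range(draws)
            ]
        for draw, subset in enumerate(subsets):
            aaf = counts[:, list(subset)].sum(axis=1) / (k * ploidy)
            dev = np.minimum(aaf, 1.0 - aaf) - truth
            frames.append(
                pd.DataFrame({"site": site_idx, "k": k, "draw": draw, "deviation": dev})
            )
    deviations = pd.concat(frames, ignore_index=True)
    summary = (
        deviations.assign(abs_dev=lambda d: d["deviation"].abs())
        .groupby("k")
        .agg(
            mean_abs_deviation=("abs_dev", "mean"),
            sd_deviation=("deviation", "std"),
            n_draws=("draw", "nunique"),
        )
        .reset_index()
    )
    return PoolCurveResult(deviations=deviations, summary=summary, seed=seed)
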