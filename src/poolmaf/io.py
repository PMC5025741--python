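"""Readers and writers for the formats the pipeline exchanges.

Pooled counts and site truth travel as TSV; the individual-level truth
panel as PLINK text .ped/.map; pooled calls as VCF 4.2 with one sample
column per pool (AD/DP per pool); target regions as BED (0-based
half-open, against the 1-based variant coordinates used everywhere
else); gene blacklists as one label per line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .estimate import aaf_to_maf
from .simulate import COUNT_COLUMNS, SITE_COLUMNS, CohortGenotypes, PooledSiteCounts

logger = logging.getLogger(__name__)

MISSING_GT = -1


# ---------------------------------------------------------------- TSV tables

def write_counts_tsv(counts: PooledSiteCounts, path) -> None:
    counts.counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> PooledSiteCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pool": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return PooledSiteCounts(counts=df)


def write_truth_tsv(sites: pd.DataFrame, path) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_reference_panel(path) -> dict[tuple, float]:
    """Reference AAF table: chrom, pos, ref, alt, aaf -> keyed lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "aaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if ((df["aaf"] < 0) | (df["aaf"] > 1)).any():
        raise ValueError(f"{path}: reference AAF outside [0, 1]")
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.aaf) for r in df.itertuples()
    }


def read_blacklist(path) -> frozenset[str]:
    """Unreliable-gene list: one gene label per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


# ------------------------------------------------------------ PLINK text

def write_plink_text(cohort: CohortGenotypes, prefix) -> tuple[Path, Path]:
    """Write the truth panel as a PLINK text .ped/.map pair.

    Genotype coding: 0 -> ref/ref, 1 -> ref/alt, 2 -> alt/alt; missing
    (negative) -> "0 0".  Family/phenotype columns are filled with
    placeholder values, as only genotypes matter downstream.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sites = cohort.sites
    with open(map_path, "w") as fh:
        for i, row in sites.iterrows():
            fh.write(f"{row.chrom}\tsnp{i + 1}\t0\t{row.pos}\n")
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(cohort.n_individuals):
            fields = [f"FAM{i + 1}", f"IND{i + 1}", "0", "0", "0", "-9"]
            for s, g in enumerate(cohort.genotypes[i]):
                if g < 0:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref[s], ref[s]]
                elif g == 1:
                    fields += [ref[s], alt[s]]
                else:
                    fields += [alt[s], alt[s]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_plink_text(ped_path, map_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a PLINK text .ped/.map pair into sites and an allele-copy matrix.

    Returns (site table with chrom/pos/id and the two observed alleles,
    genotype matrix of alt-allele copies with -1 for missing).  The minor
    and major allele per marker are resolved from the data: the rarer
    observed allele is taken as the counted (alt) allele.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{map_path}: malformed line {line!r}")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    n_markers = len(map_rows)
    individuals = []
    allele_rows = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise ValueError(
                f"{ped_path}: expected {6 + 2 * n_markers} fields for "
                f"{n_markers} markers, got {len(parts)}"
            )
        individuals.append(parts[1])
        alleles = parts[6:]
        allele_rows.append([(alleles[2 * m], alleles[2 * m + 1]) for m in range(n_markers)])
    valid = set("ACGT0")
    genotypes = np.full((len(allele_rows), n_markers), MISSING_GT, dtype=np.int8)
    counted, other = [], []
    for m in range(n_markers):
        obs: dict[str, int] = {}
        for row in allele_rows:
            for a in row[m]:
                if a not in valid:
                    raise ValueError(f"{ped_path}: invalid allele {a!r}")
                if a != "0":
                    obs[a] = obs.get(a, 0) + 1
        if len(obs) > 2:
            raise ValueError(f"{ped_path}: marker {m + 1} is multi-allelic")
        # counted allele = rarer observed allele (stable tie-break by base)
        ranked = sorted(obs.items(), key=lambda kv: (kv[1], kv[0]))
        minor = ranked[0][0] if obs else "0"
        major = ranked[-1][0] if obs else "0"
        counted.append(minor)
        other.append(major if major != minor else "0")
        for i, row in enumerate(allele_rows):
            a1, a2 = row[m]
            if a1 == "0" or a2 == "0":
                continue
            genotypes[i, m] = (a1 == minor) + (a2 == minor)
    sites = pd.DataFrame(
        {
            "chrom": [r[0] for r in map_rows],
            "snp_id": [r[1] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "counted_allele": counted,
            "other_allele": other,
        }
    )
    sites.attrs["individuals"] = individuals
    return sites, genotypes


# ------------------------------------------------------------------- VCF

def write_vcf_pooled(
    counts: PooledSiteCounts, sites: pd.DataFrame, path, estimates: pd.DataFrame | None = None
) -> None:
    """Write pooled counts as VCF 4.2 text, one sample column per pool.

    Per-pool FORMAT carries AD (ref,alt) and DP; INFO carries the total
    AAF and MAF (read-depth estimates unless ``estimates`` provides
    per-site values).
    """
    df = counts.counts
    pools = sorted(df["pool"].unique())
    site_meta = sites.set_index(["chrom", "pos"])
    est = None
    if estimates is not None and len(estimates):
        est = estimates.set_index(["chrom", "pos"])
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AAF,Number=1,Type=Float,Description="Estimated alternative allele frequency across pools">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Estimated minor allele frequency across pools">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for ref and alt alleles">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools),
    ]
    for (chrom, pos), site in df.groupby(["chrom", "pos"], sort=True):
        meta = site_meta.loc[(chrom, pos)]
        by_pool = site.set_index("pool")
        total_a = int(site["alt_depth"].sum())
        total_d = int((site["ref_depth"] + site["alt_depth"]).sum())
        if est is not None and (chrom, pos) in est.index:
            aaf = float(est.loc[(chrom, pos), "aaf"])
        else:
            aaf = total_a / total_d if total_d else 0.0
        info = f"AAF={aaf:.6g};MAF={aaf_to_maf(aaf):.6g}"
        samples = []
        for pool in pools:
            if pool in by_pool.index:
                r = int(by_pool.loc[pool, "ref_depth"])
                a = int(by_pool.loc[pool, "alt_depth"])
                samples.append(f"{r},{a}:{r + a}")
            else:
                samples.append(".:.")
        lines.append(
            f"{chrom}\t{pos}\t.\t{meta['ref']}\t{meta['alt']}\t.\tPASS\t{info}\tAD:DP\t"
            + "\t".join(samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_pooled(path) -> tuple[PooledSiteCounts, pd.DataFrame, int]:
    """Read a pooled VCF (samples = pools, FORMAT AD/DP).

    Returns (counts, site table, number of multi-allelic records
    skipped).  Only biallelic SNVs are loaded; records with more than one
    alternative allele are skipped and counted.
    """
    vcf = pysam.VariantFile(str(path))
    pools = list(vcf.header.samples)
    if "AD" not in vcf.header.formats:
        raise ValueError(f"{path}: FORMAT/AD is required for pooled counts")
    rows, site_rows = [], []
    n_multiallelic = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multiallelic += 1
            continue
        site_rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alts[0]}
        )
        for pool in pools:
            ad = rec.samples[pool].get("AD")
            if ad is None or ad[0] is None:
                raise ValueError(f"{path}: missing AD for {pool} at {rec.chrom}:{rec.pos}")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "pool": pool,
                    "ref_depth": int(ad[0]),
                    "alt_depth": int(ad[1]),
                }
            )
    if not rows:
        logger.warning("%s: no biallelic records loaded", path)
    counts = PooledSiteCounts(
        counts=pd.DataFrame(rows, columns=COUNT_COLUMNS)
    )
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
    return counts, sites, n_multiallelic


# ------------------------------------------------------------------- BED

def read_bed(path) -> dict[str, np.ndarray]:
    """Target regions as merged, sorted half-open intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed BED line {line!r}")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end < start:
            raise ValueError(f"{path}: interval end before start in {line!r}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=int)
    return merged


def in_target_regions(chrom, pos, regions: dict[str, np.ndarray]) -> np.ndarray:
    """Membership of 1-based positions in 0-based half-open BED regions."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=int)
    hit = np.zeros(pos.shape, dtype=bool)
    for c in np.unique(chrom):
        ivals = regions.get(str(c))
        if ivals is None or not len(ivals):
            continue
        mask = chrom == c
        zero_based = pos[mask] - 1
        idx = np.searchsorted(ivals[:, 0], zero_based, side="right") - 1
        ok = idx >= 0
        ok[ok] &= zero_based[ok] < ivals[idx[ok], 1]
        hit[mask] = ok
    return hit


def filter_counts_to_bed(counts: PooledSiteCounts, regions) -> PooledSiteCounts:
    """Drop off-target sites before estimation when a BED is supplied."""
    df = counts.counts
    keep = in_target_regions(df["chrom"].to_numpy(), df["pos"].to_numpy(), regions)
    return PooledSiteCounts(
        counts=df[keep].reset_index(drop=True),
        error_rate=counts.error_rate,
        depth_model=counts.depth_model,
    )
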