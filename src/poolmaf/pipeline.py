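"""End-to-end orchestration: simulate, estimate, filter, evaluate, resample.

A single seeded configuration drives all five stages; every artifact is
written under an output directory together with a JSON manifest listing
the stages completed, the seed, and the package version.  All randomness
descends from the one config seed (per-stage child seeds are spawned
deterministically), so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .estimate import estimate_maf_table
from .evaluate import concordance_report
from .filtering import FilterConfig, apply_filter_cascade
from .io import (
    filter_counts_to_bed,
    read_bed,
    read_blacklist,
    write_counts_tsv,
    write_plink_text,
    write_truth_tsv,
    write_vcf_pooled,
)
from .resample import pool_subset_deviation, subsample_reads
from .simulate import (
    assign_pools,
    random_site_table,
    simulate_cohort,
    simulate_pool_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Seeded parameters for a full simulated pooled-sequencing analysis.

    Defaults reproduce the exome-style design: 100 diploid individuals in
    10 pools of 10 (ploidy 20 per pool, 200 allele copies in total),
    mean depth 200x with negative-binomial over-dispersion, and a 0.5%
    per-read error rate.
    """

    seed: int = 1
    n_individuals: int = 100
    pool_size: int = 10
    n_sites: int = 500
    roles: list[str] = field(default_factory=list)  # empty -> all case
    depth_model: tuple = ("negative_binomial", 200.0, 8.0)
    error_rate: float = 0.005
    min_depth: float = 10.0
    maf_ratio: float | None = 1.5
    polymorphism_threshold: float = 0.5
    subsample_fractions: tuple[float, ...] = (0.7, 0.8)
    subsample_rounds: int = 10
    poolcurve_draws: int = 200
    bed_path: str | None = None
    blacklist_path: str | None = None

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")
        if self.min_depth < 0:
            raise ValueError("min depth must be >= 0")
        if not 0 < self.polymorphism_threshold < 1:
            raise ValueError("polymorphism threshold must lie in (0, 1)")
        if any(not 0 < f <= 1 for f in self.subsample_fractions):
            raise ValueError("subsample fractions must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["depth_model"] = list(d["depth_model"])
        d["subsample_fractions"] = list(d["subsample_fractions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "depth_model" in d:
            d["depth_model"] = tuple(d["depth_model"])
        if "subsample_fractions" in d:
            d["subsample_fractions"] = tuple(d["subsample_fractions"])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


def _child_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-stage seeds below 2**31, derived from the one config seed
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all five stages and write artifacts plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
    }
    stage = "simulate"
    try:
        sites = random_site_table(config.n_sites, seed=seeds[0])
        cohort = simulate_cohort(config.n_individuals, sites, seed=seeds[0])
        roles = config.roles or None
        design = assign_pools(cohort, config.pool_size, roles=roles, seed=seeds[0])
        counts = simulate_pool_counts(
            cohort,
            design,
            depth_model=config.depth_model,
            error_rate=config.error_rate,
            seed=seeds[0],
        )
        if config.bed_path:
            counts = filter_counts_to_bed(counts, read_bed(config.bed_path))
        write_truth_tsv(cohort.sites, outdir / "truth_sites.tsv")
        write_plink_text(cohort, outdir / "truth_panel")
        write_counts_tsv(counts, outdir / "pool_counts.tsv")
        manifest["stages"].append(stage)
        manifest["design"] = {
            "n_pools": design.n_pools,
            "pool_size": config.pool_size,
            "ploidy": design.ploidy,
            "total_alleles": design.total_alleles,
        }

        stage = "estimate"
        estimates = estimate_maf_table(
            counts, ploidy=design.ploidy, error_rate=config.error_rate
        )
        estimates.to_csv(outdir / "maf_estimates.tsv", sep="\t", index=False)
        write_vcf_pooled(
            counts,
            cohort.sites,
            outdir / "pooled_calls.vcf",
            estimates=estimates[estimates["method"] == "read_depth"],
        )
        manifest["stages"].append(stage)

        stage = "filter"
        ac = estimates[estimates["method"] == "allele_count"].reset_index(drop=True)
        per_pool = {
            (r.chrom, r.pos): [int(c) for c in r.pool_counts.split(",")]
            for r in ac.itertuples()
        }
        import pandas as pd

        site_meta = sites.set_index(["chrom", "pos"])
        variant_rows = []
        for r in ac.itertuples():
            calls = per_pool[(r.chrom, r.pos)]
            present = [design.labels[j] for j, c in enumerate(calls) if c > 0]
            meta = site_meta.loc[(r.chrom, r.pos)]
            variant_rows.append(
                {
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "pools_present": present,
                    "total_depth": r.depth,
                    "freq_class": meta["freq_class"],
                    "functional": bool(meta["functional"]),
                    "gene": meta["gene"],
                    "cohort_maf": r.maf,
                }
            )
        variants = pd.DataFrame(variant_rows)
        blacklist = (
            read_blacklist(config.blacklist_path) if config.blacklist_path else frozenset()
        )
        fconfig = FilterConfig(
            case_pools=tuple(design.pools_by_role("case")),
            control_pools=tuple(design.pools_by_role("control")),
            min_depth=config.min_depth,
            maf_ratio=None,  # no external reference panel in the simulated run
            blacklist=blacklist,
        )
        report = apply_filter_cascade(variants, fconfig)
        (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["stages"].append(stage)

        stage = "evaluate"
        truth_maf = pd.Series(
            cohort.cohort_maf(), index=pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
        )
        merged = ac.set_index(["chrom", "pos"]).join(truth_maf.rename("true_maf"))
        eval_report = concordance_report(
            merged["true_maf"].to_numpy(), merged["maf"].to_numpy()
        )
        (outdir / "concordance_report.json").write_text(json.dumps(eval_report, indent=2))
        manifest["stages"].append(stage)

        stage = "resample"
        sub_summaries = {}
        for frac in config.subsample_fractions:
            res = subsample_reads(
                counts,
                fraction=frac,
                rounds=config.subsample_rounds,
                ploidy=design.ploidy,
                error_rate=config.error_rate,
                seed=seeds[4],
            )
            res.mean_maf.to_csv(
                outdir / f"subsample_f{int(round(frac * 100))}.tsv", sep="\t", index=False
            )
            sub_summaries[str(frac)] = {
                "rounds": res.rounds,
                "n_sites": int(len(res.mean_maf)),
            }
        count_matrix = np.array([per_pool[(r.chrom, r.pos)] for r in ac.itertuples()])
        curve = pool_subset_deviation(
            count_matrix,
            merged["true_maf"].to_numpy(),
            ploidy=design.ploidy,
            draws=config.poolcurve_draws,
            seed=seeds[4],
        )
        curve.summary.to_csv(outdir / "pool_curve.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
        manifest["resample"] = sub_summaries
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
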