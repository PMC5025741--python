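"""Reference-frequency classification and the candidate-variant filter cascade.

Candidate rare/low-frequency variants for validation are selected by an
ordered cascade over per-site records: pool-level presence rules, a
frequency-class/functional/depth gate, a gene blacklist, and an optional
cohort-vs-reference MAF enrichment ratio.  Each stage only removes sites,
and the report records input/surviving counts per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

FREQ_CLASSES = ("rare", "low", "common", "unknown")


def classify_frequency(q: float) -> str:
    """Frequency class of an allele frequency: rare <1%, low 1-5%, common >5%.

    The 1% and 5% boundaries are inclusive for the low-frequency class.
    """
    if not 0 <= q <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    if q < 0.01:
        return "rare"
    if q <= 0.05:
        return "low"
    return "common"


def classify_by_reference(panel_aaf: float | None) -> str:
    """Class of a site from its reference-panel AAF; ``unknown`` if absent."""
    if panel_aaf is None or pd.isna(panel_aaf):
        return "unknown"
    return classify_frequency(panel_aaf)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and pool roles for the candidate cascade.

    min_depth: total read depth a site must exceed (strict) to survive.
    maf_ratio: cohort-MAF / reference-MAF enrichment threshold (strict);
        None disables the ratio stage.  A reference MAF of 0 passes the
        stage (infinite enrichment) and is logged.
    """

    case_pools: tuple[str, ...]
    control_pools: tuple[str, ...] = ()
    min_depth: float = 10.0
    maf_ratio: float | None = 1.5
    blacklist: frozenset[str] = frozenset()
    max_control_pools: int = 1


@dataclass(frozen=True)
class FilterStage:
    name: str
    predicate: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    surviving: pd.DataFrame | None = None

    @property
    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "predicate": s.predicate,
                    "input": s.n_in,
                    "surviving": s.n_out,
                }
                for s in self.stages
            ],
            "n_candidates": 0 if self.surviving is None else len(self.surviving),
        }


VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "pools_present",
    "total_depth",
    "freq_class",
    "functional",
    "gene",
    "cohort_maf",
]


def _presence(row_pools, wanted: tuple[str, ...]) -> int:
    present = set(row_pools)
    return sum(1 for p in wanted if p in present)


def apply_filter_cascade(variants: pd.DataFrame, config: FilterConfig) -> FilterReport:
    """Run the ordered candidate-selection cascade and report per-stage counts.

    Stages, in order, over per-site records (``pools_present`` is the
    collection of pool labels the variant was observed in):

    1a. drop pool-level singletons whose single pool is a case pool --
        a variant seen in exactly one pooled sample cannot be told apart
        from a technical artefact;
    1b. drop sites present in more than ``max_control_pools`` control pools;
    2.  keep rare/low-frequency, functional sites with total depth
        strictly above ``min_depth``;
    3.  drop sites whose gene is on the unreliable-gene blacklist;
    4.  (optional) keep sites whose cohort MAF exceeds ``maf_ratio`` times
        the reference MAF (column ``reference_maf``; absent or zero
        reference passes).

    Each stage only removes sites, so surviving counts are non-increasing
    and the result is independent of input row order.
    """
    unknown = set(config.case_pools) & set(config.control_pools)
    if unknown:
        raise ValueError(f"pools with both roles: {sorted(unknown)}")
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")

    report = FilterReport()
    df = variants.copy()

    def stage(name: str, predicate: str, keep: pd.Series) -> None:
        nonlocal df
        report.stages.append(FilterStage(name, predicate, len(df), int(keep.sum())))
        df = df[keep]

    if len(df) == 0:
        for name, pred in [
            ("singleton_case", "not a pool-level singleton in one case pool"),
            ("multi_control", "present in <= max control pools"),
            ("class_functional_depth", "rare/low AND functional AND depth > min"),
            ("gene_blacklist", "gene not blacklisted"),
            ("maf_ratio", "cohort MAF / reference MAF > threshold"),
        ]:
            report.stages.append(FilterStage(name, pred, 0, 0))
        report.surviving = df
        return report

    n_total = df["pools_present"].map(len)
    n_case = df["pools_present"].map(lambda ps: _presence(ps, config.case_pools))
    n_control = df["pools_present"].map(lambda ps: _presence(ps, config.control_pools))

    singleton = (n_total == 1) & (n_case == 1)
    stage(
        "singleton_case",
        "drop variants seen in exactly one pool when that pool is a case pool",
        ~singleton,
    )

    keep = df["pools_present"].map(
        lambda ps: _presence(ps, config.control_pools) <= config.max_control_pools
    )
    stage(
        "multi_control",
        f"drop variants present in more than {config.max_control_pools} control pool(s)",
        keep,
    )

    keep = (
        df["freq_class"].isin(["rare", "low"])
        & df["functional"].astype(bool)
        & (df["total_depth"] > config.min_depth)
    )
    stage(
        "class_functional_depth",
        f"keep rare/low-frequency functional variants with depth > {config.min_depth}x",
        keep,
    )

    keep = ~df["gene"].isin(config.blacklist)
    stage("gene_blacklist", "drop variants in blacklisted (unreliable) genes", keep)

    if config.maf_ratio is not None:
        ref = df.get("reference_maf")
        if ref is None:
            ref = pd.Series(0.0, index=df.index)
        zero_ref = ref.fillna(0.0) == 0.0
        if zero_ref.any():
            logger.info(
                "%d site(s) with reference MAF 0 pass the ratio stage "
                "(infinite enrichment)",
                int(zero_ref.sum()),
            )
        keep = zero_ref | (df["cohort_maf"] / ref.where(~zero_ref, 1.0) > config.maf_ratio)
        stage(
            "maf_ratio",
            f"keep variants with cohort MAF / reference MAF > {config.maf_ratio}",
            keep,
        )

    report.surviving = df.reset_index(drop=True)
    return report
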