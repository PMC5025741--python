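"""Concordance between pooled estimates and individual-level truth.

Covers the evaluation statistics used to benchmark pooled sequencing
against individual genotyping: RMSD and Pearson correlation of MAF
estimates, the variant-detection confusion matrix with its five derived
performance percentages, per-pool minor-allele-count difference binning,
array marker QC accounting, and genotyping validation rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def rmsd(validated, estimated) -> float:
    """Root-mean-square deviation between validated and estimated MAFs."""
    v = np.asarray(validated, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if v.size == 0 or v.shape != e.shape:
        raise ValueError("need one or more (validated, estimated) pairs")
    return float(np.sqrt(np.mean((v - e) ** 2)))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; undefined when either margin is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need at least two pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant margin")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Agreement counts between sequencing calls and genotyping truth.

    TP: polymorphic in both; TN: monomorphic in both; FP: polymorphic in
    sequencing only; FN: polymorphic in the truth panel only.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(calls: dict, truth: dict) -> ConfusionMatrix:
    """Count TP/TN/FP/FN over the shared site universe.

    ``calls`` and ``truth`` map site keys to polymorphic flags.  Sites
    present on only one side are dropped with a warning; an empty
    intersection is an error.
    """
    shared = set(calls) & set(truth)
    dropped = (len(calls) - len(shared)) + (len(truth) - len(shared))
    if dropped:
        logger.warning("%d site(s) outside the shared universe dropped", dropped)
    if not shared:
        raise ValueError("no shared sites between calls and truth")
    tp = tn = fp = fn = 0
    for site in shared:
        c, t = bool(calls[site]), bool(truth[site])
        if c and t:
            tp += 1
        elif not c and not t:
            tn += 1
        elif c:
            fp += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def performance_metrics(cm: ConfusionMatrix, decimals: int = 2) -> dict[str, float]:
    """Sensitivity, specificity, precision, NPV and accuracy as percentages.

    A metric with a zero denominator is reported as NaN rather than
    raising, so a degenerate truth panel still yields the others.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return round(100.0 * num / den, decimals) if den > 0 else float("nan")

    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
    }


@dataclass
class AlleleCountDifference:
    """Histogram of |minor-allele-count| differences between platforms.

    Bins 0, 1, 2 and >= 3 over the polymorphic comparison universe
    (pairs monomorphic on both platforms excluded).  ``concordance_all``
    is the fraction of identical counts when monomorphic-in-both pairs
    are kept.
    """

    bin_counts: dict[str, int]
    n_polymorphic: int
    n_total: int
    concordance_all: float

    @property
    def bin_fractions(self) -> dict[str, float]:
        if self.n_polymorphic == 0:
            return {k: float("nan") for k in self.bin_counts}
        return {k: v / self.n_polymorphic for k, v in self.bin_counts.items()}


def allele_count_difference(seq_counts, truth_counts, ploidy: int) -> AlleleCountDifference:
    """Bin per-(site, pool) minor-allele-count differences.

    Inputs are aligned vectors of integer minor-allele counts (0..2k)
    from pooled sequencing and from the truth platform, one entry per
    (marker, pool) pair.  Pairs monomorphic on both platforms are
    excluded before binning; the all-pairs concordance (identical counts
    including monomorphic-in-both) is reported alongside.
    """
    s = np.asarray(seq_counts, dtype=int)
    t = np.asarray(truth_counts, dtype=int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("count vectors must be aligned 1-D arrays")
    for arr, name in ((s, "sequencing"), (t, "truth")):
        if arr.size and (arr.min() < 0 or arr.max() > ploidy):
            raise ValueError(f"{name} counts outside 0..{ploidy}")
    n_total = s.size
    identical_all = int((s == t).sum())
    poly = ~((s == 0) & (t == 0))
    diff = np.abs(s[poly] - t[poly])
    bins = {
        "0": int((diff == 0).sum()),
        "1": int((diff == 1).sum()),
        "2": int((diff == 2).sum()),
        "3+": int((diff >= 3).sum()),
    }
    return AlleleCountDifference(
        bin_counts=bins,
        n_polymorphic=int(poly.sum()),
        n_total=n_total,
        concordance_all=identical_all / n_total if n_total else float("nan"),
    )


def marker_qc_accounting(
    total_autosomal: int, failed_per_pool, monomorphic_per_pool
) -> dict:
    """Array marker bookkeeping for the per-pool comparison universe.

    From a common autosomal marker count, subtract per-pool QC failures
    to get remaining markers per pool; the monomorphic universe is the
    sum of per-pool monomorphic counts, and the polymorphic comparison
    universe is the summed remaining markers minus it.  This is the
    (marker, pool)-pair accounting under which difference-bin fractions
    are computed.
    """
    failed = np.asarray(failed_per_pool, dtype=int)
    mono = np.asarray(monomorphic_per_pool, dtype=int)
    if failed.shape != mono.shape:
        raise ValueError("failed and monomorphic counts must align per pool")
    remaining = total_autosomal - failed
    if (remaining < 0).any():
        raise ValueError("more failed markers than total markers")
    poly_universe = int(remaining.sum() - mono.sum())
    if poly_universe < 0:
        raise ValueError("monomorphic universe exceeds remaining markers")
    return {
        "remaining_per_pool": [int(r) for r in remaining],
        "monomorphic_universe": int(mono.sum()),
        "polymorphic_universe": poly_universe,
    }


def validation_rate(assayed_per_study, monomorphic_per_study) -> float:
    """Percent of assayed variants confirmed polymorphic, pooled over studies."""
    assayed = np.asarray(assayed_per_study, dtype=int)
    mono = np.asarray(monomorphic_per_study, dtype=int)
    if assayed.shape != mono.shape or assayed.size == 0:
        raise ValueError("need aligned per-study assayed/monomorphic counts")
    if assayed.sum() == 0:
        raise ValueError("no assayed variants")
    if (mono > assayed).any():
        raise ValueError("monomorphic count exceeds assayed count")
    return round(100.0 * (assayed - mono).sum() / assayed.sum(), 1)


def percentage(part: int, whole: int, decimals: int = 1) -> float:
    """Share of ``part`` in ``whole`` as a rounded percentage."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)


def concordance_report(
    validated_maf, estimated_maf, bins: AlleleCountDifference | None = None
) -> dict:
    """Bundle the paired-MAF statistics into one JSON-friendly report."""
    v = np.asarray(validated_maf, dtype=float)
    e = np.asarray(estimated_maf, dtype=float)
    report = {
        "n_pairs": int(v.size),
        "rmsd": rmsd(v, e),
        "pearson_r": pearson_r(v, e) if v.size >= 2 and np.ptp(v) and np.ptp(e) else None,
    }
    if bins is not None:
        report["allele_count_difference"] = {
            "bin_counts": bins.bin_counts,
            "bin_fractions": bins.bin_fractions,
            "n_polymorphic_pairs": bins.n_polymorphic,
            "concordance_including_monomorphic": bins.concordance_all,
        }
    return report
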