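# Methods

## Generative model for pooled sequencing

The simulator produces the three objects every downstream stage
consumes: a truth panel of individual genotypes, a pool design, and
pooled read counts.

**Cohort.** Each site is biallelic and autosomal with a true population
alternative-allele frequency q; each individual's genotype is an
independent Binomial(2, q) draw (Hardy–Weinberg equilibrium). Sites are
simulated independently — there is no linkage disequilibrium — because
every statistic computed here treats sites marginally. Frequency
classes follow the usual screening convention: rare (q < 1%),
low-frequency (1% ≤ q ≤ 5%, boundaries inclusive), common (q > 5%).
With n diploid individuals, any nonzero realized cohort frequency is at
least 1/(2n); for the default 100-individual design that floor is 0.5%,
which is also the granularity of the allele-count estimator.

**Pools.** Individuals are partitioned into pools of k (default 10),
each pool carrying 2k allele copies ("ploidy 20"). Member contribution
weights default to exactly 1/k; unequal weights are accepted for
sensitivity studies of uneven DNA input, which is a known failure mode
of pooled designs.

**Counts.** For a pool with weighted allele fraction
p = Σ wᵢgᵢ/2, total depth D is drawn from the depth model and the
alternative-read count from Binomial(D, p(1−e) + (1−p)e).

Tunable parameters, defaults and rationale:

| parameter | default | units | why |
|---|---|---|---|
| mean depth | 200 | reads/site/pool | upper end of the 100–200× exome-style range; per-pool depth in that range is where the design is claimed to work |
| depth model | negative binomial, dispersion 8 | — | capture depth is over-dispersed relative to Poisson; dispersion 8 gives CV ≈ 0.37 at 200×, a realistic capture profile. Poisson and fixed depth are selectable |
| error rate e | 0.005 | flips/read | typical post-filter Illumina substitution rate; the flip model is symmetric, so e ≥ 0.5 is rejected as degenerate |
| pool size k | 10 | individuals | the 10-plex design under study |
| sites | 500, 30% rare / 30% low / 40% common | — | spans the classes a rare-variant screen must handle while keeping the default run in seconds |

## Estimators

The read-depth estimator Σa/ΣD is unbiased for the pool-averaged read
fraction but inherits depth-weighting across pools. The allele-count
estimator mimics what a ploidy-aware variant caller exports: an integer
allele count per pool, here the exact binomial maximum-likelihood count
(scanned over c = 0..2k, ties to the smaller c — the conservative,
fewer-alternative-alleles choice). Its estimate is an exact multiple of
1/(n_pools·2k). At high depth with e = 0 the caller recovers the true
pool count exactly; this consistency is tested at D = 10,000.

A pool with zero depth at a site is excluded from the read-depth sum;
for the allele-count method the whole site is dropped (with a logged
warning) rather than imputing a count for an unobserved pool — the
comparable real-data workflows never define such an imputation.

Polymorphism calls put a flat prior on c ∈ {0..2k} and report the
posterior mass on {c ≥ 1} as P, phred-scaled as Q = −10·log10(1−P),
flagged polymorphic at P > 0.5 (equivalently Q above ≈ 3). The flat
prior is deliberate: the score is a per-site evidence summary, not a
population-calibrated posterior.

## Filter cascade

Candidate rare/low-frequency variants pass, in order: (1a) removal of
pool-level singletons whose single pool is a case pool — one pooled
observation cannot be distinguished from a technical artefact; (1b)
removal of sites present in more than one control pool; (2) retention
of rare/low-frequency, functional sites with total depth > 10×; (3)
removal of blacklisted ("unreliable") genes; (4) optionally, retention
of sites with cohort-MAF/reference-MAF > 1.5. Stage 1's two clauses are
applied as two independent removals. A reference MAF of 0 passes the
ratio stage (infinite enrichment) and is logged. Every stage only
removes, so the report's survivor counts are non-increasing and the
result is invariant to input order — both are property-tested. The
"functional" flag is an input annotation, not computed here.

## Evaluation

RMSD = √(mean (MAF_validated − MAF_estimated)²) and the sample Pearson
r summarize paired estimates; r is refused (not silently NaN) when a
margin is constant. Detection is scored against a truth panel as
TP (polymorphic in both), TN (monomorphic in both), FP (sequencing
only), FN (truth only), with sensitivity, specificity, precision, NPV
and accuracy reported as percentages and any zero-denominator metric
as NaN.

Minor-allele-count concordance uses the (marker, pool) pair as its
comparison unit: per-pool counts from sequencing and from the truth
platform are differenced directly, pairs monomorphic on both platforms
are excluded, and |difference| is binned into 0, 1, 2, ≥3. This pair
unit is the only reading under which per-pool marker accounting
(remaining markers per pool summed, minus the shared monomorphic
universe) is consistent with the binned fractions. A concordance rate
*including* monomorphic-in-both pairs is reported separately, as the
fraction of pairs with identical counts — an interpretation, flagged as
such, since "concordance including monomorphic" admits more than one
definition. Minor-allele orientation is resolved per marker from the
pooled truth data (the rarer observed allele is counted).

## Resampling experiments

**Read thinning.** Each (site, pool) keeps Binomial(D, f) of its reads
— per-read Bernoulli retention, chosen over exact ⌊fD⌋ selection
because reads have no identity at the count level; it preserves the
expected alternative fraction, and f = 1 is the exact identity (both
property-tested). Defaults follow the depth-titration protocol: f ∈
{0.7, 0.8}, 10 rounds, per-site means over rounds. Rounds in which
thinning leaves a pool uncovered drop that site for that round.

**Pool curve.** For each subset size k the total MAF is re-estimated
from k pools only (over k·2k allele copies) and differenced against
validated truth; subsets are drawn without replacement within a draw,
and enumerated exhaustively when there are no more than the requested
draws (so k = n_pools is the single full-design deviation). Mean
absolute deviation shrinks as k grows; the suite asserts the end-to-end
decrease and allows ~1e-3 wiggle between neighbouring k for Monte-Carlo
noise at 200 draws.

## Numerical and design notes

- All likelihood work is in log space (`scipy.stats.binom.logpmf`,
  `logsumexp`); P(polymorphic) is computed via `expm1` so Q is accurate
  even when P ≈ 1.
- The phred↔probability round-trip is stable to 1e-9 over the operative
  range (Q ≤ ~30); in double precision P saturates at 1 near Q ≈ 300
  and the inverse is undefined there.
- Coordinates are 1-based in all variant records (VCF convention); BED
  target regions are 0-based half-open and are applied before
  estimation when supplied.
- Determinism: every stage takes an explicit seed; the pipeline derives
  per-stage child seeds from a single config seed via `SeedSequence`,
  and a rerun with the same config is byte-identical (tested).
- VCF output represents pools as sample columns (per-pool AD/DP), the
  way ploidy-aware callers emit pooled genotypes; multi-allelic records
  are skipped on read, with a count. Indels and sex chromosomes are out
  of scope.

## What the simulation does and does not show

The generator reproduces the statistical skeleton of pooled sequencing
— binomial allele sampling, over-dispersed depth, symmetric read error,
exact or uneven pooling weights — so passing tests show the estimators,
filters and evaluation arithmetic are correct under that model, and
that the pooled design's information loss at realistic depth is small
(recovery slope within [0.9, 1.1], r ≥ 0.9 at 200×, ~500 sites). It
does not model alignment or mapping artefacts, PCR duplicates,
reference bias, batch effects between pools, or linkage — so real-data
concordance will generally be somewhat worse than the simulated
figures, and agreement here does not by itself validate any particular
wet-lab protocol. Published real-data benchmarks of this design (r in
the 0.85–0.94 range, RMSD ≈ 0.03) are context, not targets: the raw
data behind them are not public, and this package does not attempt to
reproduce them.

## Problem sizes

Default test and pipeline scales — 100 individuals × 500 sites × 10
pools at 200×, 10 thinning rounds, 200 subset draws per k — were chosen
so a full run completes in seconds on one CPU while keeping Monte-Carlo
standard errors well inside the asserted tolerances.
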