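# poolmaf

Minor-allele-frequency estimation and evaluation for pooled DNA
sequencing (pool-seq).

## The problem

Sequencing a mixture of equal DNA amounts from many individuals is a
cheap way to screen a cohort for rare and low-frequency variants, but it
only yields aggregate read counts per site: the individual genotypes are
gone. Two questions decide whether the strategy is usable for
association screening: can rare variants be *detected* reliably from
pooled reads, and do the *minor allele frequencies* (MAFs) estimated
from pooled counts track the values one would get by genotyping every
individual? `poolmaf` implements the full analysis needed to answer
both, for designs such as 100 diploid individuals sequenced in 10 pools
of 10 (exome-style, mean depth 100–200×) or 20 individuals in a case and
a control pool (genome-style, ~133–135×).

## The model

For a pool of k diploid individuals (2k allele copies) with alternative
allele fraction p, sequencing error is modelled as a symmetric per-read
flip with rate e, so an observed read is alternative with probability
p(1−e) + (1−p)e. Two frequency estimators are provided per site:

- **read depth** — AAF = Σⱼ aⱼ / Σⱼ Dⱼ, the fraction of alternative
  reads pooled over pools;
- **allele count** — each pool gets an integer count
  ĉ = argmax_{c ∈ 0..2k} Binom(a; D, p_c) with
  p_c = (c/2k)(1−e) + (1−c/2k)e (ties to the smaller c), and
  AAF = Σⱼ ĉⱼ / (n_pools · 2k). With 10 pools of 10 the denominator is
  n = 200, so the smallest nonzero frequency is 0.5%.

MAF = min(AAF, 1−AAF). Site polymorphism is scored by the posterior
mass on {c ≥ 1} under a flat prior over c, reported as a phred-scaled
quality Q with P(polymorphic) = 1 − 10^(−Q/10) (Q = 3 ≈ 50%, Q = 10 = 90%).

Around the estimators sit: a Hardy–Weinberg cohort simulator with a
negative-binomial depth model (the synthetic truth panel), a candidate
filter cascade for rare/low-frequency functional variants (pool-level
singleton and control-presence rules, depth > 10×, gene blacklist,
cohort/reference MAF ratio > 1.5), concordance evaluation (RMSD, Pearson
r, TP/TN/FP/FN with sensitivity/specificity/precision/NPV/accuracy,
minor-allele-count difference bins), and two robustness experiments
(binomial read thinning at 70%/80% over 10 rounds; MAF deviation versus
the number of pools used).

## Worked example

```python
from poolmaf import (random_site_table, simulate_cohort, assign_pools,
                     simulate_pool_counts, estimate_maf_table, pearson_r, rmsd)

sites = random_site_table(500, seed=7)            # rare/low/common mix
cohort = simulate_cohort(100, sites, seed=7)      # HWE diploid genotypes
design = assign_pools(cohort, pool_size=10, seed=7)
print(design.n_pools, design.ploidy, design.total_alleles)
# 10 20 200

counts = simulate_pool_counts(cohort, design,
                              depth_model=("negative_binomial", 200.0, 8.0),
                              error_rate=0.005, seed=7)
est = estimate_maf_table(counts, ploidy=design.ploidy, error_rate=0.005,
                         methods=("allele_count",))
truth = cohort.cohort_maf()                       # realized cohort MAF
print(round(rmsd(truth, est["maf"]), 4), round(pearson_r(truth, est["maf"]), 3))
# 0.0076 0.999
```

The three numbers say: the simulated exome design has 10 pools at ploidy
20 (200 allele copies, hence a 0.5% frequency floor), and at mean depth
200× the allele-count estimator recovers the cohort's true MAFs with an
RMSD of about 0.008 and near-perfect correlation — pooled counts retain
almost all of the frequency information at this depth.

The same analysis runs end to end from the shell:

```bash
poolmaf run --outdir out          # simulate → estimate → filter → evaluate → resample
poolmaf simulate --n-individuals 100 --pool-size 10 --out-prefix out/sim
poolmaf estimate --counts out/sim_counts.tsv --ploidy 20 --out out/maf.tsv
```

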