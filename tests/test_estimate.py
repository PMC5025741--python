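"""Allele-frequency estimators, the integer allele-count caller and
phred-scaled polymorphism calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolmaf import (
    aaf_to_maf,
    call_pool_allele_count,
    classify_site,
    estimate_aaf_allele_count,
    estimate_aaf_read_depth,
    estimate_maf_table,
    probability_to_quality,
    quality_to_probability,
)
from poolmaf.estimate import call_pool_allele_counts


def brute_force_call(a, depth, ploidy, error_rate):
    """Independent oracle: explicit likelihood scan with math-module
    arithmetic, keeping the smallest count on ties."""
    best_lik, best_c = -1.0, 0
    for c in range(ploidy + 1):
        p = (c / ploidy) * (1 - error_rate) + (1 - c / ploidy) * error_rate
        lik = math.comb(depth, a) * p**a * (1 - p) ** (depth - a)
        if lik > best_lik:
            best_lik, best_c = lik, c
    return best_c


class TestReadDepthEstimator:
    def test_summation_across_pools(self):
        assert estimate_aaf_read_depth([5, 0], [100, 100]) == pytest.approx(0.025)

    def test_no_alternative_reads(self):
        assert estimate_aaf_read_depth([0, 0, 0], [50, 80, 120]) == 0.0

    def test_all_alternative(self):
        assert estimate_aaf_read_depth([200], [200]) == 1.0

    def test_zero_depth_pool_excluded(self):
        assert estimate_aaf_read_depth([5, 0], [100, 0]) == pytest.approx(0.05)

    def test_uncovered_site_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="uncovered"):
            estimate_aaf_read_depth([0, 0], [0, 0])


class TestAlleleCountCaller:
    def test_zero_alt_zero_error(self):
        assert call_pool_allele_count(0, 150, 20, 0.0) == 0

    def test_fixation(self):
        assert call_pool_allele_count(150, 150, 20, 0.0) == 20

    def test_one_tenth_alt_fraction(self):
        assert call_pool_allele_count(15, 150, 20, 0.005) == 2

    def test_zero_depth_is_no_call(self):
        with pytest.raises(ValueError, match="zero depth"):
            call_pool_allele_count(0, 0, 20)

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError, match="ploidy"):
            call_pool_allele_count(1, 10, 7)

    @pytest.mark.parametrize("error_rate", [0.0, 0.005, 0.02])
    def test_matches_brute_force_scan(self, error_rate):
        # exhaustive agreement with the likelihood-scan oracle, all a <= D <= 60
        pairs = [(a, d) for d in range(1, 61) for a in range(d + 1)]
        expected = [brute_force_call(a, d, 20, error_rate) for a, d in pairs]
        got = call_pool_allele_counts(
            [a for a, _ in pairs], [d for _, d in pairs], 20, error_rate
        )
        assert list(got) == expected

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        d = rng.integers(1, 500, size=200)
        a = rng.integers(0, d + 1)
        vec = call_pool_allele_counts(a, d, 20, 0.005)
        assert all(
            v == call_pool_allele_count(int(ai), int(di), 20, 0.005)
            for v, ai, di in zip(vec, a, d)
        )

    def test_high_depth_zero_error_recovers_truth_exactly(self, wes_cohort, wes_design):
        # consistency: at D = 10,000 and e = 0 the caller recovers the true
        # pool allele count at every site of the simulated design
        from poolmaf import simulate_pool_counts

        counts = simulate_pool_counts(
            wes_cohort, wes_design, depth_model=("fixed", 10_000), error_rate=0.0, seed=3
        )
        df = counts.counts
        labels = {p.label: p for p in wes_design.pools}
        truth = {
            (row.chrom, row.pos, row.pool): int(
                wes_cohort.genotypes[list(labels[row.pool].members), :][
                    :, wes_cohort.sites.index[wes_cohort.sites["pos"] == row.pos][0]
                ].sum()
            )
            for row in df.sample(n=200, random_state=0).itertuples()
        }
        for (chrom, pos, pool), true_c in truth.items():
            row = df[(df["pos"] == pos) & (df["pool"] == pool)].iloc[0]
            called = call_pool_allele_count(
                int(row["alt_depth"]),
                int(row["ref_depth"] + row["alt_depth"]),
                wes_design.ploidy,
                0.0,
            )
            assert called == true_c


class TestAlleleCountEstimator:
    def test_single_copy_across_ten_pools(self):
        # one alternative allele among 200 copies: the 0.5% floor
        assert estimate_aaf_allele_count([1] + [0] * 9, 20) == pytest.approx(0.005)

    def test_single_pool_convention(self):
        # one pool of 10 diploids: counts divided by 20
        assert estimate_aaf_allele_count([3], 20) == pytest.approx(0.15)

    def test_all_zero(self):
        assert estimate_aaf_allele_count([0] * 10, 20) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_aaf_allele_count([], 20)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_aaf_allele_count([21], 20)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=10))
    def test_granularity(self, counts):
        # the estimate is an exact multiple of 1/(n_pools * 2k)
        aaf = estimate_aaf_allele_count(counts, 20)
        denom = len(counts) * 20
        assert aaf * denom == pytest.approx(round(aaf * denom))


class TestMafFolding:
    @pytest.mark.parametrize("aaf,maf", [(0.7, 0.3), (0.15, 0.15), (0.5, 0.5), (0.0, 0.0), (1.0, 0.0)])
    def test_examples(self, aaf, maf):
        assert aaf_to_maf(aaf) == pytest.approx(maf)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aaf_to_maf(1.2)

    @given(st.floats(0, 1))
    def test_folding_properties(self, aaf):
        maf = aaf_to_maf(aaf)
        assert 0 <= maf <= 0.5
        assert maf == pytest.approx(aaf_to_maf(1 - aaf))


class TestPolymorphismCall:
    def test_clean_reference_site_not_polymorphic(self):
        call = classify_site(0, 500, 20, 0.005)
        assert not call.polymorphic
        assert call.probability < 0.5

    def test_heterozygous_fraction_confident(self):
        call = classify_site(100, 200, 20, 0.005)
        assert call.polymorphic
        assert call.quality > 10

    def test_phred_probability_relation(self):
        call = classify_site(5, 120, 20, 0.005)
        assert call.probability == pytest.approx(
            quality_to_probability(call.quality), abs=1e-9
        )

    def test_zero_depth_no_call(self):
        with pytest.raises(ValueError):
            classify_site(0, 0, 20)


class TestQualityProbability:
    def test_quality_three_is_under_half(self):
        p = quality_to_probability(3)
        assert p == pytest.approx(0.499, abs=5e-4)
        assert p < 0.5

    def test_quality_ten_is_ninety_percent(self):
        assert quality_to_probability(10) == pytest.approx(0.90)

    def test_quality_zero(self):
        assert quality_to_probability(0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quality_to_probability(-1)

    @given(st.floats(0, 30))
    @settings(max_examples=50)
    def test_round_trip_and_monotonicity(self, q):
        # over the operative phred range; beyond ~Q300 the probability
        # saturates at 1.0 in double precision and the inverse is undefined
        p = quality_to_probability(q)
        assert probability_to_quality(p) == pytest.approx(q, abs=1e-9)
        assert quality_to_probability(q + 1) > p


class TestEstimateTable:
    def test_both_methods_per_site(self, tiny_counts):
        table = estimate_maf_table(tiny_counts, ploidy=20, error_rate=0.005)
        assert set(table["method"]) == {"read_depth", "allele_count"}
        rd = table[table["method"] == "read_depth"].set_index("pos")
        assert rd.loc[100, "aaf"] == pytest.approx(5 / 200)
        assert rd.loc[200, "aaf"] == pytest.approx(110 / 200)
        assert rd.loc[200, "maf"] == pytest.approx(90 / 200)

    def test_allele_count_granularity(self, tiny_counts):
        table = estimate_maf_table(tiny_counts, ploidy=20)
        ac = table[table["method"] == "allele_count"]
        denom = 2 * 20  # 2 pools
        assert np.allclose(ac["aaf"] * denom, np.round(ac["aaf"] * denom))

    def test_uncovered_pool_drops_site_for_allele_count_only(self, tiny_counts):
        df = tiny_counts.counts.copy()
        df.loc[(df["pos"] == 100) & (df["pool"] == "poolB"), ["ref_depth", "alt_depth"]] = 0
        table = estimate_maf_table(df, ploidy=20)
        ac = table[table["method"] == "allele_count"]
        rd = table[table["method"] == "read_depth"]
        assert 100 not in set(ac["pos"])
        assert 100 in set(rd["pos"])
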