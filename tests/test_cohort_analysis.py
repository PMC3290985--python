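"""Cohort statistics: centile subgroups, splits, trend tests, comparisons.

The Kendall and rank-sum routines are checked against brute-force oracles:
tau by direct concordant/discordant pair counting with tie corrections, and
the rank-sum p-value by exhaustive enumeration of group assignments using
the pair-counting Mann-Whitney U statistic (a formulation independent of
the rank-based implementation).
"""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcrscreen import (
    CentileRange,
    MixtureResult,
    NDCase,
    centile_subgroup,
    grouped_median_trend,
    kendall_trend,
    run_full_analysis,
    split_by_hi,
    summarize_group,
    wilcoxon_compare,
)
from conftest import detect, mixture, nondetect


def result(sample_id, hi, mcr=2.0, n_detects=10, n_analytes=50, nd_case=NDCase.CASE1):
    return MixtureResult(
        sample_id=sample_id,
        hi=hi,
        mhq=hi / mcr if mcr and not math.isnan(mcr) else 0.0,
        mcr=mcr,
        n_detects=n_detects,
        n_analytes=n_analytes,
        nd_case=nd_case,
        top_chemical="X",
    )


# ---------------------------------------------------------------- oracles


def tau_b_oracle(x, y):
    """Tie-corrected Kendall tau by O(n^2) pair counting."""
    n = len(x)
    concordant = discordant = 0
    for i, j in combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        concordant += s > 0
        discordant += s < 0
    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (concordant - discordant) / denom if denom else float("nan")


def rank_sum_p_oracle(a, b):
    """Exact two-sided p by enumerating assignments of the pooled values,
    scoring each with the pair-counting Mann-Whitney U statistic."""
    def u_stat(ga, gb):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb
        )
    pooled = list(a) + list(b)
    m = len(a)
    center = m * len(b) / 2.0
    obs = abs(u_stat(a, b) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), m):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(ga, gb) - center) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


# ------------------------------------------------------------- subgroups


class TestCentileSubgroup:
    def test_hundred_distinct_values_band_49_51(self):
        results = [result(f"s{i:03d}", hi=float(i)) for i in range(1, 101)]
        members = centile_subgroup(results, CentileRange(49, 51))
        assert sorted(m.hi for m in members) == [50.0, 51.0]

    def test_full_range_selects_everyone(self):
        results = [result(f"s{i}", hi=float(i)) for i in range(10)]
        assert len(centile_subgroup(results, CentileRange(0, 100))) == 10

    def test_618_band_size_matches_survey_scale(self):
        results = [result(f"s{i:04d}", hi=float(i)) for i in range(618)]
        members = centile_subgroup(results, CentileRange(49, 51))
        assert 11 <= len(members) <= 13

    def test_deterministic_under_ties(self):
        results = [result(f"s{i}", hi=1.0) for i in range(20)]
        first = centile_subgroup(results, CentileRange(40, 60))
        second = centile_subgroup(list(reversed(results)), CentileRange(40, 60))
        assert [m.sample_id for m in first] == [m.sample_id for m in second]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centile_subgroup([], CentileRange(49, 51))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            CentileRange(51, 49)


class TestSummarizeGroup:
    def test_singleton(self):
        s = summarize_group([result("a", 1.0, mcr=2.0)])
        assert (s.min_mcr, s.max_mcr, s.mean_mcr) == (2.0, 2.0, 2.0)

    def test_pair(self):
        s = summarize_group([result("a", 1.0, mcr=1.0), result("b", 1.0, mcr=3.0)])
        assert (s.min_mcr, s.max_mcr, s.mean_mcr) == (1.0, 3.0, 2.0)

    def test_random_vector_matches_brute_force(self):
        rng = np.random.default_rng(7)
        mcrs = 1 + rng.random(20) * 4
        members = [result(f"s{i}", 1.0, mcr=float(v)) for i, v in enumerate(mcrs)]
        s = summarize_group(members)
        assert s.min_mcr == pytest.approx(min(mcrs))
        assert s.max_mcr == pytest.approx(max(mcrs))
        assert s.mean_mcr == pytest.approx(sum(mcrs) / len(mcrs))
        assert s.min_mcr <= s.mean_mcr <= s.max_mcr

    def test_undefined_mcr_members_dropped(self):
        members = [result("a", 0.0, mcr=float("nan")), result("b", 1.0, mcr=2.0)]
        assert summarize_group(members).n_members == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])


class TestSplitByHI:
    def test_even_split(self):
        split = split_by_hi([result("a", 0.5), result("b", 1.5)])
        assert len(split.below) == 1 and len(split.above) == 1
        assert split.frac_above == 0.5

    def test_all_below(self):
        split = split_by_hi([result("a", 0.1), result("b", 0.2)])
        assert split.above == () and split.frac_above == 0.0

    def test_threshold_value_goes_above(self):
        split = split_by_hi([result("a", 1.0)], threshold=1.0)
        assert len(split.above) == 1


# ----------------------------------------------------------------- trends


class TestKendall:
    def test_strictly_increasing(self):
        assert kendall_trend([1, 2, 3, 4], [10, 20, 30, 40]).tau == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        assert kendall_trend([1, 2, 3, 4], [4, 3, 2, 1]).tau == pytest.approx(-1.0)

    def test_tied_vector_matches_pair_counting(self):
        x = [1, 2, 2, 3, 3, 3, 4]
        y = [5, 5, 4, 4, 6, 6, 7]
        assert kendall_trend(x, y).tau == pytest.approx(tau_b_oracle(x, y), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_trend([1, 2], [1, 2, 3])

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=2, max_size=8
        )
    )
    def test_matches_oracle_on_small_inputs(self, data):
        x, y = zip(*data)
        expected = tau_b_oracle(x, y)
        got = kendall_trend(x, y).tau
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestWilcoxon:
    def test_identical_samples(self):
        assert wilcoxon_compare([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_separated_samples_exact_value(self):
        # only 2 of the C(6,3)=20 assignments are as extreme as the observed
        assert wilcoxon_compare([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1, 2, 3], [10, 11, 12]),
            ([1.5, 2.5], [2.0, 3.0, 4.0]),
            ([1, 1, 2, 2], [1, 2, 3, 3]),  # heavy ties
            ([0.1], [0.2, 0.3]),
            ([5, 1, 4, 2], [3, 6, 7, 8]),
        ],
    )
    def test_matches_permutation_oracle(self, a, b):
        assert wilcoxon_compare(a, b) == pytest.approx(rank_sum_p_oracle(a, b), abs=1e-12)

    def test_large_shift_large_n(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        assert wilcoxon_compare(a, b) < 1e-4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])

    def test_paired_identical(self):
        assert wilcoxon_compare([1, 2, 3], [1, 2, 3], paired=True) == 1.0

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.integers(0, 4), min_size=1, max_size=4),
        b=st.lists(st.integers(0, 4), min_size=1, max_size=4),
    )
    def test_property_matches_oracle_on_small_inputs(self, a, b):
        assert wilcoxon_compare(a, b) == pytest.approx(rank_sum_p_oracle(a, b), abs=1e-12)


class TestGroupedMedianTrend:
    @staticmethod
    def grouped(sizes_and_values):
        out = []
        for n, (size, values) in sizes_and_values.items():
            for i in range(size):
                out.append(result(f"n{n}_{i}", hi=values[i % len(values)], n_detects=n))
        return out

    def test_small_groups_excluded(self):
        results = self.grouped(
            {10: (4, [1.0]), 20: (5, [2.0]), 30: (6, [3.0]), 40: (5, [4.0])}
        )
        tr = grouped_median_trend(results, group_key="n_detects", min_group=5)
        assert tr.n == 3  # the size-4 group at n=10 is dropped

    def test_equal_medians_give_zero_tau(self):
        results = self.grouped({10: (5, [2.0]), 20: (5, [2.0]), 30: (5, [2.0])})
        tr = grouped_median_trend(results, group_key="n_detects", min_group=5)
        assert tr.tau == pytest.approx(0.0) or math.isnan(tr.tau)

    def test_three_group_toy_matches_hand_computation(self):
        # medians: n=10 -> 2.0, n=20 -> 5.0, n=30 -> 3.0; Kendall on
        # (10,2),(20,5),(30,3): pairs +1, -1, +1 -> tau = 1/3
        results = self.grouped(
            {
                10: (5, [1.0, 2.0, 2.0, 3.0, 2.0]),
                20: (5, [5.0, 4.0, 5.0, 6.0, 5.0]),
                30: (5, [3.0, 3.0, 2.0, 4.0, 3.0]),
            }
        )
        tr = grouped_median_trend(results, group_key="n_detects", min_group=5)
        assert tr.tau == pytest.approx(1 / 3)

    def test_insufficient_groups_returns_none(self):
        results = self.grouped({10: (5, [1.0]), 20: (3, [2.0])})
        assert grouped_median_trend(results, group_key="n_detects", min_group=5) is None


# ------------------------------------------------------------ full run


class TestRunFullAnalysis:
    def small_cohort(self):
        cohort = []
        rng = np.random.default_rng(11)
        for i in range(30):
            ms = [
                detect("Arsenic", float(rng.lognormal(np.log(0.003), 1.0)), dl=1e-4),
                nondetect("Benzene", 0.002),
            ]
            for j in range(6):
                ms.append(detect("Toluene", 0.001 * (j + 1), dl=1e-5))
            cohort.append(mixture(f"s{i:02d}", *ms))
        return cohort

    def test_deterministic_report(self, registry, assumptions):
        cohort = self.small_cohort()
        a = run_full_analysis(cohort, registry, assumptions)
        b = run_full_analysis(cohort, registry, assumptions)
        assert a.to_text() == b.to_text()

    def test_identical_samples_give_identical_mcr(self, registry, assumptions):
        ms = (
            detect("Arsenic", 0.003, dl=1e-4),
            detect("Benzene", 0.01, dl=1e-4),
            detect("Toluene", 0.001, dl=1e-5),
            detect("Zinc", 0.5, dl=1e-3),
            detect("Nickel", 0.01, dl=1e-4),
        )
        cohort = [mixture(f"s{i}", *ms) for i in range(20)]
        summary = run_full_analysis(cohort, registry, assumptions)
        for case in (NDCase.CASE1, NDCase.CASE2):
            mcrs = {r.mcr for r in summary.results[case]}
            assert len(mcrs) == 1
        # subgroup means cannot differ when every sample is the same mixture
        per_case = summary.centile_summary.groupby("nd_case")["mean_mcr"].nunique()
        assert (per_case <= 1).all()

    def test_dominance_tuned_cohort_shows_negative_mcr_hi_trend(self, default_summary):
        tr = default_summary.trends
        rows = tr[(tr.relation == "mcr_vs_hi") & (tr.scope == "individual")]
        assert len(rows) == 2
        assert (rows["tau"] < 0).all()
        assert (rows["p_value"] < 0.0001).all()

    def test_case2_hi_dominates_case1(self, default_summary):
        res1 = {r.sample_id: r.hi for r in default_summary.results[NDCase.CASE1]}
        res2 = {r.sample_id: r.hi for r in default_summary.results[NDCase.CASE2]}
        assert all(res2[s] >= res1[s] for s in res1)
        diffs = [res2[s] - res1[s] for s in res1]
        assert np.mean(diffs) > 0

    def test_subgroup_mean_mcr_declines_with_hi(self, default_summary):
        cs = default_summary.centile_summary
        for case in ("case1", "case2"):
            means = cs[cs.nd_case == case].set_index("centile_range")["mean_mcr"]
            assert means["49-51"] >= means["94-96"] >= means["98-100"]
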