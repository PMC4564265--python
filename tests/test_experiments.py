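"""Rank pairing, exact binomial tests, performance models, nonparametrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from leafsignal import (
    compare_performance,
    exact_binomial_two_tailed,
    mann_whitney,
    pair_by_rank,
    percent_difference,
    quasibinomial_proportion_test,
    relative_growth_rate,
    wilcoxon_matched,
)
from leafsignal.simulate import PerformanceConfig, generate_performance


class TestPairByRank:
    def test_two_plants(self):
        assert pair_by_rank({"a": 7, "b": 2}, k=1) == [("a", "b")]

    def test_four_plants_by_stated_rule(self):
        # high group ranked 9 > 5, low group ranked 1 < 3
        pairs = pair_by_rank({"w": 5, "x": 1, "y": 9, "z": 3}, k=2)
        assert pairs == [("y", "x"), ("w", "z")]

    def test_full_partition_uses_every_plant_once(self):
        rng = np.random.default_rng(0)
        values = {f"p{i}": v for i, v in enumerate(rng.permutation(20).astype(float))}
        pairs = pair_by_rank(values, k=10)
        used = [p for pair in pairs for p in pair]
        assert sorted(used) == sorted(values)
        highs = {h for h, _ in pairs}
        assert min(values[h] for h in highs) > max(values[l] for _, l in pairs)

    def test_too_few_plants_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            pair_by_rank({"a": 1, "b": 2, "c": 3}, k=2)


class TestExactBinomial:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (23, 32, 0.020),   # aphids choosing a plant over no plant
            (19, 30, 0.20),    # butterflies choosing high DR:G
            (16, 30, 0.86),    # butterflies choosing high B:G
            (13, 30, 0.58),    # aphids choosing dull plants
        ],
    )
    def test_published_choice_examples(self, k, n, expected):
        assert exact_binomial_two_tailed(k, n) == pytest.approx(expected, abs=5e-3)

    def test_observed_equal_expected_gives_one(self):
        assert exact_binomial_two_tailed(15, 30) == 1.0

    def test_extreme_small_sample_closed_form(self):
        assert exact_binomial_two_tailed(0, 5) == pytest.approx(2 * 0.5**5, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 60), data=st.data())
    def test_symmetry_at_half(self, n, data):
        k = data.draw(st.integers(0, n))
        assert exact_binomial_two_tailed(k, n) == pytest.approx(
            exact_binomial_two_tailed(n - k, n), rel=1e-12
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_two_tailed(5, 3)


class TestComparePerformance:
    def _frame(self, high, low):
        rows = []
        for i, v in enumerate(high):
            rows.append({"plant_id": f"h{i}", "group": "high", "resp": v})
        for i, v in enumerate(low):
            rows.append({"plant_id": f"l{i}", "group": "low", "resp": v})
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero(self):
        df = self._frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = compare_performance(df, "resp")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = compare_performance(self._frame(a, b), "resp")
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)

    def test_larvae_sharing_plant_are_averaged(self):
        df = pd.DataFrame(
            {
                "plant_id": ["p1", "p1", "p2", "p3", "p4"],
                "group": ["high", "high", "high", "low", "low"],
                "resp": [1.0, 3.0, 4.0, 2.0, 5.0],
            }
        )
        res = compare_performance(df, "resp")
        stats_ = res.fit_info["group_stats"]
        assert stats_["high"]["n"] == 2  # p1 collapsed to its mean of 2.0
        assert stats_["high"]["mean"] == pytest.approx(3.0)

    def test_log_transform_requires_positive(self):
        df = self._frame([1.0, 0.0, 2.0], [3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="positive"):
            compare_performance(df, "resp", transform="log")

    def test_power_at_published_effect_sizes(self):
        """The growth-rate contrast is detected in most synthetic replicates."""
        hits = 0
        reps = 20
        for s in range(reps):
            perf = generate_performance(PerformanceConfig(), np.random.default_rng(70 + s))
            res = compare_performance(perf.larvae, "growth_rate")
            hits += res.p_value < 0.05
        assert hits > reps / 2


class TestQuasibinomial:
    def test_equal_proportions_no_effect(self):
        res = quasibinomial_proportion_test(
            [5, 5, 5, 5], [10, 10, 10, 10], ["a", "a", "b", "b"]
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_overdispersion_detected(self):
        rng = np.random.default_rng(13)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = np.full(30, 60)
            p = rng.beta(0.3 / 0.1 * (1 - 0.1), 0.7 / 0.1 * (1 - 0.1), 30)  # rho = 0.1
            k = rng.binomial(n, p)
            res = quasibinomial_proportion_test(k, n, ["a"] * 15 + ["b"] * 15)
            hits += res.fit_info["dispersion"] > 1.0
        assert hits >= 0.9 * reps

    def test_unit_dispersion_reduces_to_binomial_chi2(self):
        rng = np.random.default_rng(14)
        n = np.full(40, 50)
        k = rng.binomial(n, np.where(np.arange(40) < 20, 0.4, 0.6))
        group = ["a"] * 20 + ["b"] * 20
        res = quasibinomial_proportion_test(k, n, group)
        phi = res.fit_info["dispersion"]
        # F * phi equals the deviance change; with phi near 1 the F statistic
        # approximates the chi-square/df scale of an ordinary binomial GLM
        import statsmodels.api as sm

        X = np.column_stack([np.ones(40), np.arange(40) >= 20])
        full = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial()).fit()
        null = sm.GLM(np.column_stack([k, n - k]), np.ones((40, 1)),
                      family=sm.families.Binomial()).fit()
        chi2 = null.deviance - full.deviance
        assert res.statistic * phi == pytest.approx(chi2, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            quasibinomial_proportion_test([5], [0], ["a"])


def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    u_obs = sum((xi > yj) for xi in x for yj in y)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = combined[list(idx)]
        ys = np.delete(combined, list(idx))
        u = sum((xi > yj) for xi in xs for yj in ys)
        total += 1
        if min(u, n * m - u) <= min(u_obs, n * m - u_obs):
            count += 1
    return count / total


def wilcoxon_signflip_oracle(diffs):
    """Two-sided exact signed-rank p by enumerating all sign flips."""
    d = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total_rank = ranks.sum()
    centre = total_rank / 2.0
    count = 0
    n = d.size
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - centre) >= abs(w_obs - centre) - 1e-12:
            count += 1
    return count / 2**n


class TestNonparametrics:
    def test_identical_samples_uninformative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_separated_samples_exact_enumeration(self):
        res = mann_whitney([10, 11, 12, 13], [1, 2, 3, 4])
        assert res.fit_info["method"] == "exact"
        assert res.p_value == pytest.approx(2.0 / 70.0, rel=1e-12)

    def test_six_positive_differences_exact(self):
        before = np.zeros(6)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_matched(before, after)
        assert res.fit_info["method"] == "exact"
        assert res.p_value == pytest.approx(2.0 / 64.0, rel=1e-12)
        assert res.statistic == pytest.approx(21.0)  # full positive rank sum

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_matched([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 4), m=st.integers(2, 4), data=st.data(),
    )
    def test_mann_whitney_matches_enumeration(self, n, m, data):
        pool = data.draw(
            st.lists(st.integers(0, 100), min_size=n + m, max_size=n + m, unique=True)
        )
        x, y = pool[:n], pool[n:]
        res = mann_whitney(x, y)
        assert res.fit_info["method"] == "exact"
        assert res.p_value == pytest.approx(mw_exact_oracle(x, y), rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(3, 8), data=st.data())
    def test_wilcoxon_matches_signflip_enumeration(self, n, data):
        mags = data.draw(
            st.lists(st.integers(1, 50), min_size=n, max_size=n, unique=True)
        )
        signs = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n))
        diffs = np.array([m * s for m, s in zip(mags, signs)], dtype=float)
        res = wilcoxon_matched(np.zeros(n), diffs)
        assert res.p_value == pytest.approx(wilcoxon_signflip_oracle(diffs), rel=1e-9)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (1.74, 0.64, 171.9),   # constitutive total aliphatics, low vs high blue
            (12.46, 10.42, 19.6),  # relative growth rate
            (1.0, 1.0, 0.0),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestGrowthRate:
    def test_log_difference_over_interval(self):
        assert relative_growth_rate(10.0, 100.0, 9.0, 24.0) == pytest.approx(
            np.log(10.0) / 15.0, rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_growth_rate(0.0, 10.0, 0, 5)
        with pytest.raises(ValueError):
            relative_growth_rate(1.0, 2.0, 5, 5)
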