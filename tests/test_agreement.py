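"""Agreement statistics: pairing schemes, Bland-Altman, KS, thin-cap fractions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capseg.agreement import (
    bland_altman,
    ks_two_sample,
    pair_inter,
    pair_intra,
    pair_vs_automated,
    summarize_distribution,
    thin_cap_fraction,
)


class TestPairingSchemes:
    def test_intra_three_pairs_per_case(self):
        pairs = pair_intra({"c1": [100.0, 110.0, 120.0]})
        assert pairs == [(100.0, 110.0), (100.0, 120.0), (110.0, 120.0)]

    def test_intra_many_cases(self):
        readings = {i: [1.0, 2.0, 3.0] for i in range(200)}
        assert len(pair_intra(readings)) == 600

    def test_intra_identical_readings_zero_differences(self):
        pairs = pair_intra({"c": [5.0, 5.0, 5.0]})
        assert all(a - b == 0 for a, b in pairs)

    def test_intra_wrong_count_raises(self):
        with pytest.raises(ValueError):
            pair_intra({"c": [1.0, 2.0]})

    def test_vs_automated_three_pairs_per_case(self):
        pairs = pair_vs_automated({"c": [100.0, 110.0, 120.0]}, {"c": 105.0})
        assert pairs == [(100.0, 105.0), (110.0, 105.0), (120.0, 105.0)]

    def test_vs_automated_missing_case_skipped(self, caplog):
        manual = {i: [1.0, 2.0, 3.0] for i in range(200)}
        automated = {i: 2.0 for i in range(200)}
        automated[57] = None
        with caplog.at_level("WARNING"):
            pairs = pair_vs_automated(manual, automated)
        assert len(pairs) == 597
        assert any("57" in r.message for r in caplog.records)

    def test_inter_by_repetition_and_all_crossings(self):
        o1 = {"c": [1.0, 2.0, 3.0]}
        o2 = {"c": [10.0, 20.0, 30.0]}
        assert pair_inter(o1, o2) == [(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)]
        assert len(pair_inter(o1, o2, scheme="all-crossings")) == 9


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([(100.0, 100.0), (120.0, 120.0), (90.0, 90.0)])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        r = bland_altman([(100.0, 90.0), (110.0, 100.0)])
        assert r.bias == pytest.approx(10.0)
        assert r.sd_diff == 0.0
        assert (r.loa_low, r.loa_high) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_hand_computed_sample_sd(self):
        # d = [0, 2]: bias 1, sample SD sqrt(2), LoA 1 -/+ 1.96*sqrt(2)
        r = bland_altman([(0.0, 0.0), (2.0, 0.0)])
        assert r.bias == pytest.approx(1.0, abs=1e-9)
        assert r.sd_diff == pytest.approx(math.sqrt(2), abs=1e-9)
        assert r.loa_low == pytest.approx(1 - 1.96 * math.sqrt(2), abs=1e-9)
        assert r.loa_high == pytest.approx(1 + 1.96 * math.sqrt(2), abs=1e-9)
        assert r.loa_range == pytest.approx(2 * 1.96 * math.sqrt(2), abs=1e-9)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=2, max_size=50),
           st.floats(-500, 500))
    def test_antisymmetry_and_shift(self, pairs, c):
        r = bland_altman(pairs)
        swapped = bland_altman([(b, a) for a, b in pairs])
        assert swapped.bias == pytest.approx(-r.bias, abs=1e-6)
        assert swapped.loa_low == pytest.approx(-r.loa_high, abs=1e-6)
        assert swapped.loa_high == pytest.approx(-r.loa_low, abs=1e-6)
        shifted = bland_altman([(a + c, b) for a, b in pairs])
        assert shifted.bias == pytest.approx(r.bias + c, abs=1e-6)
        assert shifted.sd_diff == pytest.approx(r.sd_diff, abs=1e-6)


def ks_statistic_oracle(x, y):
    """sup |ECDF_x - ECDF_y| evaluated over the pooled support."""
    x, y = np.asarray(x), np.asarray(y)
    support = np.concatenate([x, y])
    d = 0.0
    for t in support:
        d = max(d, abs(np.mean(x <= t) - np.mean(y <= t)))
    return d


def ks_pvalue_oracle(x, y):
    """Exact permutation null: enumerate all label assignments of the pooled
    sample and count arrangements with D at least as large as observed."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    d_obs = ks_statistic_oracle(x, y)
    total = 0
    at_least = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if ks_statistic_oracle(xs, ys) >= d_obs - 1e-12:
            at_least += 1
    return at_least / total


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_worked_small_sample(self):
        d, p = ks_two_sample([1.0, 2.0], [1.5, 2.5])
        assert d == pytest.approx(0.5)
        assert p == pytest.approx(ks_pvalue_oracle([1.0, 2.0], [1.5, 2.5]), abs=1e-9)

    def test_statistic_matches_ecdf_oracle_all_small_sizes(self):
        rng = np.random.default_rng(3)
        for n in range(1, 7):
            for m in range(1, 7):
                for _ in range(5):
                    x = rng.normal(size=n)
                    y = rng.normal(0.5, 1.2, size=m)
                    d, _ = ks_two_sample(x, y)
                    assert d == pytest.approx(ks_statistic_oracle(x, y), abs=1e-12)

    def test_exact_pvalue_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for n, m in [(3, 3), (4, 5), (5, 4), (6, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(1.0, size=m)
            _, p = ks_two_sample(x, y)
            assert p == pytest.approx(ks_pvalue_oracle(x, y), abs=1e-9)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(1, 2, size=15)
        dxy, pxy = ks_two_sample(x, y)
        dyx, pyx = ks_two_sample(y, x)
        assert dxy == dyx and pxy == pyx
        assert 0.0 <= dxy <= 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestThinCapFraction:
    def test_worked_example(self):
        f = thin_cap_fraction([60.0, 70.0, 90.0, 100.0], thresholds=[65.0, 80.0, 95.0])
        assert f[65.0] == pytest.approx(25.0)
        assert f[80.0] == pytest.approx(50.0)
        assert f[95.0] == pytest.approx(75.0)

    def test_strict_inequality_at_threshold(self):
        f = thin_cap_fraction([65.0], thresholds=[65.0])
        assert f[65.0] == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 300, 500)
        f = thin_cap_fraction(v, thresholds=[65, 80, 95, 100, 200])
        vals = list(f.values())
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_uniform_draws_near_half(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(0, 200, 1000)
        f = thin_cap_fraction(v, thresholds=[100.0])
        assert f[100.0] == pytest.approx(50.0, abs=5.0)


class TestSummarizeDistribution:
    def test_per_case_order_statistics(self):
        out = summarize_distribution(triplicates={"c": [100.0, 120.0, 110.0]})
        assert out["min_of_repeats"]["mean"] == 100.0
        assert out["median_of_repeats"]["mean"] == 110.0
        assert out["max_of_repeats"]["mean"] == 120.0

    def test_identical_cases_give_identical_subdistributions(self):
        trip = {i: [90.0, 100.0, 110.0] for i in range(5)}
        out = summarize_distribution(triplicates=trip)
        assert out["min_of_repeats"]["sd"] == 0.0
        assert out["median_of_repeats"]["mean"] == 100.0

    def test_noise_orders_the_repeat_series(self):
        rng = np.random.default_rng(5)
        trip = {i: list(150 + 20 * rng.standard_normal(3)) for i in range(100)}
        out = summarize_distribution(triplicates=trip)
        assert out["max_of_repeats"]["mean"] > out["min_of_repeats"]["mean"]

    def test_overall_stats(self):
        out = summarize_distribution(values=[1.0, 2.0, 3.0, 4.0])
        assert out["overall"]["mean"] == pytest.approx(2.5)
        assert out["overall"]["median"] == pytest.approx(2.5)
        assert out["overall"]["n"] == 4
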