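"""Hodges-Lehmann shift estimation with exact rank-based intervals."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bectoss import (
    compute_endpoints,
    endpoints_frame,
    hodges_lehmann_shift,
    period_differences,
    simulate_trial,
    tmax_shift_analysis,
)
from bectoss.nonparam_tmax import mann_whitney_cdf


class TestPeriodDifferences:
    def test_half_difference_arithmetic(self):
        data = pd.DataFrame(
            [
                {"subject_id": "S1", "sequence": "AB", "period": 1, "tmax": 2.5},
                {"subject_id": "S1", "sequence": "AB", "period": 2, "tmax": 4.5},
                {"subject_id": "S2", "sequence": "BA", "period": 1, "tmax": 4.0},
                {"subject_id": "S2", "sequence": "BA", "period": 2, "tmax": 3.0},
            ]
        )
        d_ab, d_ba = period_differences(data)
        assert d_ab.tolist() == [-1.0]
        assert d_ba.tolist() == [0.5]

    def test_swapping_periods_negates_differences(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            seq = "AB" if i % 2 else "BA"
            for p in (1, 2):
                rows.append({"subject_id": f"S{i}", "sequence": seq,
                             "period": p, "tmax": float(rng.uniform(1, 8))})
        data = pd.DataFrame(rows)
        swapped = data.copy()
        swapped["period"] = swapped["period"].map({1: 2, 2: 1})
        d1 = period_differences(data)
        d2 = period_differences(swapped)
        assert np.allclose(d1[0], -d2[0]) and np.allclose(d1[1], -d2[1])

    def test_missing_period_excluded_with_warning(self):
        data = pd.DataFrame(
            [
                {"subject_id": "S1", "sequence": "AB", "period": 1, "tmax": 2.0},
                {"subject_id": "S2", "sequence": "AB", "period": 1, "tmax": 3.0},
                {"subject_id": "S2", "sequence": "AB", "period": 2, "tmax": 4.0},
            ]
        )
        with pytest.warns(UserWarning, match="S1"):
            d_ab, _ = period_differences(data)
        assert d_ab.size == 1


class TestMannWhitneyNull:
    def test_counts_match_exhaustive_enumeration(self):
        """Null distribution equals brute-force enumeration of all rank
        assignments at small sizes."""
        for m, n in ((3, 3), (4, 5), (6, 6)):
            total = comb(m + n, m)
            freq = np.zeros(m * n + 1)
            ranks = range(m + n)
            for combo in itertools.combinations(ranks, m):
                u = sum(combo) - m * (m - 1) // 2
                freq[u] += 1
            for u in range(m * n + 1):
                assert mann_whitney_cdf(u, m, n) == pytest.approx(
                    freq[: u + 1].sum() / total, abs=1e-14
                )

    def test_cdf_matches_scipy_exact_pvalue_at_study_size(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        u = sum(1 for xi in x for yj in y if xi > yj)
        p = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        assert mann_whitney_cdf(u, 12, 12) == pytest.approx(p, abs=1e-12)


class TestHodgesLehmann:
    def test_tiny_example_brute_force(self):
        """{1,2} vs {-1,0}: differences {2,1,3,2} -> HL = 2."""
        r = hodges_lehmann_shift([1, 2], [-1, 0], confidence=0.5)
        assert r.hl_estimate == 2.0
        assert r.ci_lower == 1.0 and r.ci_upper == 3.0

    def test_identical_groups_estimate_zero(self):
        r = hodges_lehmann_shift([1, 2, 3], [1, 2, 3], confidence=0.5)
        assert r.hl_estimate == 0.0

    def test_matches_full_enumeration_at_n12(self):
        """Estimate and CI equal an independent enumeration of all 144
        pairwise differences with scipy-derived exact critical ranks."""
        rng = np.random.default_rng(5)
        g1 = rng.normal(0.8, 1.0, 12)
        g2 = rng.normal(0.0, 1.0, 12)
        diffs = sorted(g1[i] - g2[j] for i in range(12) for j in range(12))
        hl = 0.5 * (diffs[71] + diffs[72])
        # critical rank: largest k with P(U <= k-1) <= 0.05 under the exact
        # null (the recurrence itself is validated against enumeration and
        # scipy above)
        k = max(kk for kk in range(1, 73)
                if mann_whitney_cdf(kk - 1, 12, 12) <= 0.05)
        r = hodges_lehmann_shift(g1, g2, confidence=0.90)
        assert r.hl_estimate == pytest.approx(hl, abs=1e-12)
        assert r.ci_lower == pytest.approx(diffs[k - 1], abs=1e-12)
        assert r.ci_upper == pytest.approx(diffs[144 - k], abs=1e-12)
        assert r.achieved_confidence >= 0.90

    def test_too_small_for_requested_confidence(self):
        with pytest.raises(ValueError, match="maximum achievable"):
            hodges_lehmann_shift([1, 2], [3, 4], confidence=0.99)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(8)
        g1 = rng.normal(size=10)
        g2 = rng.normal(size=9)
        base = hodges_lehmann_shift(g1, g2)
        moved = hodges_lehmann_shift(g1 + shift, g2)
        assert moved.hl_estimate == pytest.approx(base.hl_estimate + shift, abs=1e-9)
        assert moved.ci_lower == pytest.approx(base.ci_lower + shift, abs=1e-9)
        assert moved.ci_upper == pytest.approx(base.ci_upper + shift, abs=1e-9)

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(2)
        g1 = rng.integers(1, 6, 12).astype(float)  # heavy ties
        g2 = rng.integers(1, 6, 12).astype(float)
        a = hodges_lehmann_shift(g1, g2)
        b = hodges_lehmann_shift(np.flip(g1), rng.permutation(g2))
        assert (a.hl_estimate, a.ci_lower, a.ci_upper) == (
            b.hl_estimate, b.ci_lower, b.ci_upper
        )


class TestCrossoverTmaxAnalysis:
    def test_constant_food_advance_recovered_exactly(self, quiet_config):
        """Noise-free trial: every fed tmax is 1.5 h earlier on the sampling
        grid, so both difference groups are constant and the shift is -1.5."""
        frame = endpoints_frame(compute_endpoints(simulate_trial(quiet_config)))
        r = tmax_shift_analysis(frame)
        assert r.hl_estimate == pytest.approx(-1.5)
        assert r.ci_lower == pytest.approx(-1.5) and r.ci_upper == pytest.approx(-1.5)

    def test_null_coverage_of_exact_interval(self):
        """Under zero shift with continuous data the exact-rank 90% interval
        covers 0 at least 90% of the time (and near the achieved level)."""
        rng = np.random.default_rng(12)
        n_rep = 2000
        covered = 0
        achieved = None
        for _ in range(n_rep):
            g1 = rng.normal(size=12)
            g2 = rng.normal(size=12)
            r = hodges_lehmann_shift(g1, g2, confidence=0.90)
            achieved = r.achieved_confidence
            covered += r.ci_lower <= 0.0 <= r.ci_upper
        rate = covered / n_rep
        se = (achieved * (1 - achieved) / n_rep) ** 0.5
        assert rate >= 0.90 - 3 * se
        assert abs(rate - achieved) <= 4 * se
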