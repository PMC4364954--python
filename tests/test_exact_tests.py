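"""Exact binomial, exact Wilcoxon, and the expected-inequality value."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from dyadbargain.core import EXP2_DESIGN
from dyadbargain.exact_tests import (
    binom_two_sided,
    expected_abs_diff,
    observed_vs_expected_test,
    wilcoxon_exact,
)

from conftest import build_dataset


# -- independent oracles ------------------------------------------------------


def brute_force_expected_abs_diff(k: int, delta: int) -> Fraction:
    """Mean |sum| over all 2^k explicit +/-delta sequences."""
    if k == 0:
        return Fraction(0)
    total = Fraction(0)
    for seq in itertools.product((delta, -delta), repeat=k):
        total += abs(sum(seq))
    return total / 2**k


def _midranks(magnitudes):
    """Midranks computed by sorted-position averaging (no scipy)."""
    order = sorted(range(len(magnitudes)), key=lambda i: magnitudes[i])
    ranks = [0.0] * len(magnitudes)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and magnitudes[order[j + 1]] == magnitudes[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = mid
        i = j + 1
    return ranks


def brute_force_wilcoxon(diffs, sidedness="two_sided"):
    """Exact signed-rank p by enumerating every sign assignment."""
    nonzero = [d for d in diffs if d != 0]
    m = len(nonzero)
    if m == 0:
        return {"t_plus": 0.0, "p": 1.0}
    ranks = _midranks([abs(d) for d in nonzero])
    t_plus = sum(r for d, r in zip(nonzero, ranks) if d > 0)
    all_t = [
        sum(r for bit, r in zip(bits, ranks) if bit)
        for bits in itertools.product((0, 1), repeat=m)
    ]
    n = len(all_t)
    p_le = sum(t <= t_plus + 1e-9 for t in all_t) / n
    p_ge = sum(t >= t_plus - 1e-9 for t in all_t) / n
    p = p_ge if sidedness == "one_sided_greater" else min(1.0, 2 * min(p_le, p_ge))
    return {"t_plus": t_plus, "p": p}


# -- binomial ----------------------------------------------------------------


class TestBinomTwoSided:
    @pytest.mark.parametrize(
        "k, n, exact_p",
        [
            (2, 12, Fraction(79, 2048)),    # prints as 0.038
            (6, 12, Fraction(1)),           # prints as 1
            (1, 12, Fraction(13, 2048)),    # prints as 0.006
            (7, 12, Fraction(793, 1024)),   # prints as 0.77
            (0, 1, Fraction(1)),            # doubling a 0.5 tail caps at 1
        ],
    )
    def test_frozen_exact_values(self, k, n, exact_p):
        result = binom_two_sided(k, n, 0.5)
        assert result.p_value == pytest.approx(float(exact_p), abs=1e-12)
        assert result.statistic == k and result.n_effective == n

    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_symmetry_at_half(self, n):
        for k in range(n + 1):
            assert binom_two_sided(k, n, 0.5).p_value == pytest.approx(
                binom_two_sided(n - k, n, 0.5).p_value, abs=1e-12
            )

    def test_asymmetric_null_is_tail_doubling(self):
        # oracle: doubled smaller tail computed directly from the pmf
        k, n, p0 = 3, 10, 0.3
        pmf = [
            float(Fraction(math.comb(n, i)) * Fraction(3, 10) ** i * Fraction(7, 10) ** (n - i))
            for i in range(n + 1)
        ]
        expected = min(1.0, 2 * min(sum(pmf[: k + 1]), sum(pmf[k:])))
        assert binom_two_sided(k, n, p0).p_value == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("k, n, p0", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0), (2, 5, 1.0)])
    def test_domain_errors(self, k, n, p0):
        with pytest.raises(ValueError):
            binom_two_sided(k, n, p0)


# -- Wilcoxon ----------------------------------------------------------------


class TestWilcoxonExact:
    def test_all_zero_is_degenerate(self):
        r = wilcoxon_exact([0, 0, 0])
        assert r.degenerate and r.p_value == 1.0
        assert r.ties_dropped == 3 and r.n_effective == 0

    def test_two_positive_differences(self):
        r = wilcoxon_exact([1, 2])
        assert r.t_plus == 3.0 and r.p_value == 0.5

    def test_three_positive_differences(self):
        r = wilcoxon_exact([1, 2, 3])
        assert r.t_plus == 6.0 and r.p_value == 0.25

    def test_tie_accounting(self):
        r = wilcoxon_exact([0, 5, -3, 0, 2])
        assert r.n_effective == 3 and r.ties_dropped == 2
        assert r.n_effective + r.ties_dropped == 5

    @pytest.mark.parametrize(
        "diffs",
        [
            [1, 2, 3, -4],
            [2, 2, -2, 5],          # tied magnitudes -> midranks
            [0, 1, -1, 3, 0, 2],    # zeros and ties together
            [-1, -2, -3],
            [4.5, -1.5, 2.5, 2.5],
        ],
    )
    def test_matches_enumeration_oracle(self, diffs):
        ours = wilcoxon_exact(diffs)
        oracle = brute_force_wilcoxon(diffs)
        assert ours.t_plus == pytest.approx(oracle["t_plus"], abs=1e-12)
        assert ours.p_value == pytest.approx(oracle["p"], abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        # tie-free magnitudes: scipy's exact mode is an independent cross-check
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(3, 9))
            mags = rng.permutation(np.arange(1, m + 1)).astype(float)
            signs = rng.choice([-1.0, 1.0], size=m)
            diffs = mags * signs
            ours = wilcoxon_exact(diffs)
            ref = stats.wilcoxon(diffs, mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_one_sided_greater(self):
        r = wilcoxon_exact([1, 2, 3], sidedness="one_sided_greater")
        assert r.p_value == 0.125  # P(T+ >= 6) = 1/8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([])


# -- expected absolute difference --------------------------------------------


class TestExpectedAbsDiff:
    @pytest.mark.parametrize(
        "k, delta, expected",
        [
            (2, 2, Fraction(2)),    # (4+4+0+0)/4: the four role sequences
            (0, 7, Fraction(0)),
            (3, 2, Fraction(3)),
            (2, 5, Fraction(5)),
            (4, 2, Fraction(3)),
        ],
    )
    def test_frozen_values(self, k, delta, expected):
        assert expected_abs_diff(k, delta) == expected

    @pytest.mark.parametrize("delta", [2, 5])
    def test_closed_form_equals_enumeration(self, delta):
        for k in range(0, 13):
            assert expected_abs_diff(k, delta) == brute_force_expected_abs_diff(k, delta)

    def test_linear_in_delta_monotone_in_k(self):
        for k in range(1, 10):
            assert expected_abs_diff(k, 6) == 3 * expected_abs_diff(k, 2)
            assert expected_abs_diff(k + 1, 2) >= expected_abs_diff(k, 2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_abs_diff(-1, 2)
        with pytest.raises(ValueError):
            expected_abs_diff(2, -1)


# -- observed vs expected -----------------------------------------------------


class TestObservedVsExpected:
    def test_all_equal_dyads_degenerate(self):
        ds = build_dataset([["E"] * 4, ["E"] * 4])
        r = observed_vs_expected_test(ds)
        assert r.degenerate and r.p_value == 1.0

    def test_monopolist_dyad_difference(self):
        ds = build_dataset([["UA"] * 4])
        r = observed_vs_expected_test(ds)
        row = r.detail.iloc[0]
        assert row["observed_abs_diff"] == 8
        assert row["expected_abs_diff"] == 3.0  # expected_abs_diff(4, 2)
        assert row["difference"] == 5.0

    def test_perfect_alternators_show_less_inequality_than_chance(self):
        ds = build_dataset([["UA", "UB", "UA", "UB"]] * 5)
        r = observed_vs_expected_test(ds)
        assert (r.detail["difference"] < 0).all()
        one_sided = observed_vs_expected_test(ds, sidedness="one_sided_greater")
        assert one_sided.p_value > 0.5  # evidence points the other way

    def test_exp2_uses_its_own_delta(self):
        ds = build_dataset([["UA", "UB", "E", "E"]], design=EXP2_DESIGN)
        row = observed_vs_expected_test(ds).detail.iloc[0]
        assert row["expected_abs_diff"] == 5.0  # expected_abs_diff(2, 5)

    def test_no_eligible_dyads_raises(self):
        ds = build_dataset([["N"] * 4])
        with pytest.raises(ValueError, match="successful"):
            observed_vs_expected_test(ds)
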