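"""Kendall correlation, shift counting, the exact sign test, and the suite."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c3c4niche import contrast_tests as ct
from c3c4niche.niche_summary import GroupNiche


def brute_force_tau_b(x, y):
    """Independent oracle: concordant/discordant enumeration with tie terms."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    n0 = n * (n - 1) / 2
    n1 = sum(c * (c - 1) / 2 for c in pd.Series(x).value_counts() if c > 1)
    n2 = sum(c * (c - 1) / 2 for c in pd.Series(y).value_counts() if c > 1)
    return s / math.sqrt((n0 - n1) * (n0 - n2))


def gn(lineage, type_, **values):
    return GroupNiche(lineage=lineage, type=type_, values=values)


class TestBuildContrasts:
    def _niches(self):
        """20 lineages: 19 with C3 sisters, 5 of those without C4, plus one
        lineage with a C4 sister but no identified C3 sister."""
        out = []
        for i in range(19):
            lineage = f"L{i:02d}"
            out.append(gn(lineage, "C3", x=float(i)))
            out.append(gn(lineage, "C3-C4", x=float(i) + 0.5))
            if i >= 5:
                out.append(gn(lineage, "C4", x=float(i) + 1.0))
        out.append(gn("L19", "C3-C4", x=3.0))
        out.append(gn("L19", "C4", x=4.0))
        return out

    def test_eligibility_counts_by_comparison(self):
        niches = self._niches()
        assert len(ct.build_contrasts(niches, "C3C4_vs_C3_all", "x")) == 19
        assert len(ct.build_contrasts(niches, "C3C4_vs_C3_withC4", "x")) == 14
        assert len(ct.build_contrasts(niches, "C4_vs_C3C4", "x")) == 15

    def test_single_lineage(self):
        niches = [gn("L", "C3", x=1.0), gn("L", "C3-C4", x=2.0)]
        pairs = ct.build_contrasts(niches, "C3C4_vs_C3_all", "x")
        assert len(pairs) == 1
        assert pairs[0].focal == 2.0 and pairs[0].reference == 1.0

    def test_missing_variable_excludes_lineage(self):
        niches = [
            gn("L1", "C3", x=1.0), gn("L1", "C3-C4", x=2.0),
            gn("L2", "C3", y=1.0), gn("L2", "C3-C4", x=2.0),
        ]
        assert len(ct.build_contrasts(niches, "C3C4_vs_C3_all", "x")) == 1

    def test_zero_eligible_lineages_is_error(self):
        with pytest.raises(ValueError, match="no eligible"):
            ct.build_contrasts([gn("L", "C3-C4", x=1.0)], "C4_vs_C3C4", "x")

    def test_unknown_comparison(self):
        with pytest.raises(ValueError, match="unknown comparison"):
            ct.build_contrasts([], "C4_vs_C3", "x")


class TestKendallTau:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        tau, _ = ct.kendall_tau(x, x)
        assert tau == pytest.approx(1.0)
        tau, _ = ct.kendall_tau(x, [-v for v in x])
        assert tau == pytest.approx(-1.0)

    def test_single_swap_example(self):
        tau, _ = ct.kendall_tau([1, 2, 3, 4], [1, 2, 4, 3])
        assert tau == pytest.approx((5 - 1) / 6)

    def test_matches_brute_force_up_to_n8(self):
        rng = np.random.default_rng(51)
        for n in range(3, 9):
            for _ in range(20):
                x = rng.integers(0, 5, n).astype(float)  # ties likely
                y = rng.integers(0, 5, n).astype(float)
                if np.unique(x).size == 1 or np.unique(y).size == 1:
                    continue
                tau, _ = ct.kendall_tau(x, y)
                assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_exact_p_small_n_matches_permutation_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        tau_obs, p = ct.kendall_tau(x, y)
        taus = [
            brute_force_tau_b(x, list(perm))
            for perm in itertools.permutations(y)
        ]
        p_oracle = np.mean([abs(t) >= abs(tau_obs) - 1e-12 for t in taus])
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_p_uses_continuity_corrected_normal(self):
        rng = np.random.default_rng(53)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        tau, p = ct.kendall_tau(x, y)
        # oracle: recompute z from S with continuity correction, no ties
        n = 30
        s = tau * n * (n - 1) / 2
        var_s = n * (n - 1) * (2 * n + 5) / 18
        p_oracle = 2 * stats.norm.sf((abs(s) - 1) / math.sqrt(var_s))
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ct.kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            ct.kendall_tau([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            ct.kendall_tau([1, 2], [1, 2])


class TestCountShifts:
    def test_two_of_three_higher(self):
        pairs = [
            ct.ContrastPair("a", "x", 2.0, 1.0),
            ct.ContrastPair("b", "x", 3.0, 1.0),
            ct.ContrastPair("c", "x", 0.0, 1.0),
        ]
        sc = ct.count_shifts(pairs)
        assert (sc.k, sc.n, sc.ties) == (2, 3, 0)

    def test_all_tied(self):
        pairs = [ct.ContrastPair("a", "x", 1.0, 1.0)] * 3
        sc = ct.count_shifts(pairs)
        assert (sc.k, sc.n, sc.ties) == (0, 0, 3)
        with pytest.raises(ValueError):
            ct.sign_test(sc.k, sc.n)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(57)
        vals = rng.integers(0, 4, size=(30, 2)).astype(float)
        pairs = [ct.ContrastPair(str(i), "x", a, b) for i, (a, b) in enumerate(vals)]
        sc = ct.count_shifts(pairs)
        k = sum(1 for a, b in vals if a > b)
        ties = sum(1 for a, b in vals if a == b)
        assert (sc.k, sc.n, sc.ties) == (k, 30 - ties, ties)


class TestSignTest:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (13, 14, 2 * Fraction(1, 16384)),
            (12, 14, 2 * Fraction(15, 16384)),
            (7, 15, Fraction(1)),
        ],
    )
    def test_exact_values(self, k, n, expected):
        assert ct.sign_test(k, n) == float(expected)

    def test_symmetric_method_differs_for_asymmetric_counts(self):
        # symmetric two-tailed p for 12/14 is 2*P(X>=12) = 212/16384
        assert ct.sign_test(12, 14, method="symmetric") == pytest.approx(
            212 / 16384
        )
        assert ct.sign_test(12, 14, method="paper") == pytest.approx(30 / 16384)

    def test_half_split_even_n(self):
        """The symmetric convention yields p = 1 at an exact half split; the
        table-pinned asymmetric convention tops out below 1 for even n."""
        for n in (2, 8, 14, 20):
            assert ct.sign_test(n // 2, n, method="symmetric") == 1.0
            f = stats.binom.cdf(n // 2, n, 0.5)
            assert ct.sign_test(n // 2, n) == pytest.approx(2 * (1 - f), abs=1e-12)

    def test_half_split_odd_n_gives_one(self):
        for n in (7, 15, 19):
            assert ct.sign_test(n // 2, n) == 1.0

    def test_agrees_with_floating_binomial_path(self):
        for n in range(1, 31):
            for k in range(n + 1):
                f = stats.binom.cdf(k, n, 0.5)
                upper = 1 - f if k < n else 0.5**n
                expected = min(1.0, 2 * min(f, upper))
                assert ct.sign_test(k, n) == pytest.approx(expected, abs=1e-12)

    def test_p_in_unit_interval(self):
        for n in (1, 5, 19):
            for k in range(n + 1):
                assert 0.0 < ct.sign_test(k, n) <= 1.0

    @pytest.mark.parametrize("k,n", [(0, 0), (-1, 5), (6, 5)])
    def test_invalid_counts(self, k, n):
        with pytest.raises(ValueError):
            ct.sign_test(k, n)

    def test_non_integer_rejected(self):
        with pytest.raises(TypeError):
            ct.sign_test(1.5, 10)


class TestCorrectedThreshold:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 8, 0.00625), (0.05, 1, 0.05), (0.04, 5, 0.008)]
    )
    def test_values(self, alpha, m, expected):
        assert ct.corrected_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ct.corrected_threshold(0.0, 8)
        with pytest.raises(ValueError):
            ct.corrected_threshold(0.05, 0)


class TestRunContrastSuite:
    def _conserved_niches(self, n=14, jitter=0.0, shift=None):
        rng = np.random.default_rng(61)
        shift = shift or {}
        out = []
        for i in range(n):
            lineage = f"L{i:02d}"
            base = {"growing_season_temperature": 10.0 + 2.0 * i, "TEB": 5.0 + i}
            for type_ in ("C3", "C3-C4", "C4"):
                vals = {
                    v: base[v]
                    + (shift.get(v, 0.0) if type_ == "C3-C4" else 0.0)
                    + jitter * rng.standard_normal()
                    for v in base
                }
                out.append(GroupNiche(lineage, type_, vals))
        return out

    def test_conserved_niches_give_tau_one_and_balanced_counts(self):
        niches = self._conserved_niches(jitter=1e-9)
        suite = ct.run_contrast_suite(
            niches, variables=("growing_season_temperature", "TEB")
        )
        kend = suite[suite.test == "kendall"]
        assert (kend.statistic > 0.99).all()
        sign = suite[suite.test == "sign"]
        assert ((sign.k - sign.n / 2).abs() <= sign.n / 2 * 0.75).all()
        assert not sign.significant.any()

    def test_planted_uniform_shift_flags_only_that_variable(self):
        niches = self._conserved_niches(
            jitter=1e-6, shift={"growing_season_temperature": 5.0}
        )
        suite = ct.run_contrast_suite(
            niches, variables=("growing_season_temperature", "TEB"), m=8
        )
        sub = suite[(suite.test == "sign") & (suite.comparison == "C3C4_vs_C3_all")]
        sub = sub.set_index("variable")
        assert sub.loc["growing_season_temperature", "k"] == 14
        assert sub.loc["growing_season_temperature", "p"] == pytest.approx(
            2 * (0.5) ** 14
        )
        assert bool(sub.loc["growing_season_temperature", "significant"])
        assert not bool(sub.loc["TEB", "significant"])

    def test_report_shape_and_threshold_column(self):
        suite = ct.run_contrast_suite(
            self._conserved_niches(jitter=0.01),
            variables=("growing_season_temperature", "TEB"),
        )
        assert set(suite.columns) == {
            "variable", "comparison", "test", "statistic", "k", "n", "p", "significant"
        }
        # 2 variables x (2 kendall + 3 sign comparisons)
        assert len(suite) == 10
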