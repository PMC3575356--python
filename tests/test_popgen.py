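"""Diversity and differentiation estimators against algebraic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from mhcdiv import (
    fst_weir_cockerham,
    gst_prime_and_jost_d,
    heterozygosity,
    hwe_test,
    kst,
    observed_heterozygosity,
)
from mhcdiv.popgen import regional_aggregate

import pandas as pd


class TestHeterozygosity:
    def test_nca_unit_value(self):
        he, _ = heterozygosity([8, 5, 1, 2, 2, 2, 1, 1, 1, 1])
        assert round(he, 2) == 0.85

    def test_gai_unit_value(self):
        he, _ = heterozygosity({"a": 29, "b": 2, "c": 2, "d": 9})
        assert round(he, 2) == 0.48

    def test_single_allele(self):
        assert heterozygosity([10])[0] == 0.0

    def test_two_singletons_closed_form(self):
        # counts {1,1}: He = (2/1) * (1 - 0.5) = 1.0
        assert heterozygosity([1, 1])[0] == pytest.approx(1.0)

    def test_zero_alleles_is_error(self):
        with pytest.raises(ValueError):
            heterozygosity([])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8).filter(lambda c: sum(c) >= 2))
    @settings(max_examples=50, derandomize=True)
    def test_relabeling_invariance(self, counts):
        he1, _ = heterozygosity(counts)
        he2, _ = heterozygosity(sorted(counts, reverse=True))
        assert he1 == pytest.approx(he2)
        assert 0 <= he1 <= 1

    def test_monotone_in_dominant_frequency(self):
        # fixed k, pushing mass onto the top allele lowers He
        values = [heterozygosity([big, 10, 10])[0] for big in (10, 20, 40, 80)]
        assert values == sorted(values, reverse=True)

    def test_bootstrap_se_reported(self):
        he, se = heterozygosity([8, 5, 1, 2], bootstrap_reps=200, seed=1)
        assert 0 < se < 0.2


class TestObservedHeterozygosity:
    def test_fraction(self):
        assert observed_heterozygosity([("a", "a"), ("a", "b")]) == 0.5


class TestHwe:
    def test_perfect_proportions_not_rejected(self):
        g = [("A", "A")] * 25 + [("A", "a")] * 50 + [("a", "a")] * 25
        r = hwe_test(g)
        assert r.method == "enumeration"
        assert r.p_exact > 0.9
        assert r.p_deficit > 0.4

    def test_complete_heterozygote_deficit(self):
        g = [("A", "A")] * 50 + [("a", "a")] * 50
        r = hwe_test(g)
        assert r.p_deficit < 1e-3
        assert r.p_exact < 1e-3

    def test_undefined_for_tiny_samples(self):
        r = hwe_test([("A", "a")])
        assert not r.defined

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(5)
        p = np.array([0.5, 0.3, 0.2])
        g = [tuple(rng.choice(list("ABC"), 2, p=p)) for _ in range(30)]
        exact = hwe_test(g)
        mc = hwe_test(g, mc_reps=20000, seed=7, max_enumeration_alleles=0)
        assert mc.method == "monte_carlo"
        assert mc.p_exact == pytest.approx(exact.p_exact, abs=0.02)
        assert mc.p_deficit == pytest.approx(exact.p_deficit, abs=0.02)

    def test_null_calibration(self):
        # under random mating the deficit p-value rejects at roughly alpha
        rng = np.random.default_rng(11)
        alleles = list("AB")
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            pool = rng.choice(alleles, size=2 * 30, p=[0.6, 0.4])
            g = list(zip(pool[::2], pool[1::2]))
            if hwe_test(g).p_deficit < 0.05:
                rejections += 1
        rate = rejections / n_rep
        # exact tests are conservative on discrete tables: rate <= ~alpha
        assert rate < 0.08


class TestKst:
    def test_identical_composition(self):
        pops = [["AAAA", "AAAC"], ["AAAA", "AAAC"]]
        obs, p = kst(pops, permutations=200, seed=3)
        assert abs(obs) < 1e-9 or obs <= 0
        assert p > 0.05

    def test_hand_enumerated_toy(self):
        # pop1 = {s1, s1}, pop2 = {s2, s2}, one difference: K_S = 0,
        # K_T = 4 differing pairs * 1 / 6 pairs, so K_ST = 1
        s1, s2 = "A" * 10, "A" * 9 + "C"
        obs, _ = kst([[s1, s1], [s2, s2]], permutations=10, seed=0)
        assert obs == pytest.approx(1.0)

    def test_all_identical_degenerate(self):
        obs, p = kst([["AAA", "AAA"], ["AAA", "AAA"]], permutations=10, seed=0)
        assert (obs, p) == (0.0, 1.0)

    def test_null_p_uniform(self):
        # sequences drawn from one pool: permutation p approximately uniform
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(120):
            seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10)]
            obs, p = kst([seqs[:5], seqs[5:]], permutations=99, seed=int(rng.integers(2**31)))
            pvals.append(p)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.15


class TestFst:
    def test_reciprocal_fixation(self):
        theta, _ = fst_weir_cockerham([[("A", "A")] * 10, [("B", "B")] * 10])
        assert theta == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self):
        pops = [[("A", "B")] * 10 + [("A", "A")] * 5] * 2
        theta, _ = fst_weir_cockerham(pops)
        assert abs(theta) < 0.05

    def test_algebraic_oracle_value(self):
        # hand-evaluated theta for 3 AA + 1 AB + 1 BB vs 1 AA + 1 AB + 3 BB
        pops = [
            [("A", "A")] * 3 + [("A", "B")] + [("B", "B")],
            [("A", "A")] + [("A", "B")] + [("B", "B")] * 3,
        ]
        theta, _ = fst_weir_cockerham(pops)
        assert theta == pytest.approx(4 / 29)

    def test_monomorphic_undefined(self):
        theta, p = fst_weir_cockerham([[("A", "A")] * 4, [("A", "A")] * 4])
        assert math.isnan(theta)

    def test_permutation_p_detects_structure(self):
        pops = [[("A", "A")] * 12, [("B", "B")] * 12]
        theta, p = fst_weir_cockerham(pops, permutations=199, seed=5)
        assert p < 0.05


class TestGstPrimeJostD:
    def test_identical_pops_near_zero(self):
        est = gst_prime_and_jost_d([{"A": 8, "B": 2}, {"A": 8, "B": 2}])
        assert est.jost_d <= 0.001
        assert est.g_st_prime <= 0.001

    def test_reciprocal_fixation_both_one(self):
        est = gst_prime_and_jost_d([{"A": 10}, {"B": 10}])
        assert est.g_st_prime == pytest.approx(1.0)
        assert est.jost_d == pytest.approx(1.0)

    def test_algebraic_oracle_values(self):
        # hand-evaluated SMOGD-style estimators for {A:8,B:2} vs {A:2,B:8}
        est = gst_prime_and_jost_d([{"A": 8, "B": 2}, {"A": 2, "B": 8}])
        assert est.h_s == pytest.approx(0.35555555555555557)
        assert est.h_t == pytest.approx(0.5177777777777778)
        assert est.g_st == pytest.approx(0.3133047210300429)
        assert est.g_st_prime == pytest.approx(0.6590202752700903)
        assert est.jost_d == pytest.approx(0.503448275862069)

    def test_hs_one_flagged_undefined(self):
        # every individual a distinct heterozygote pair: Hs_est can hit 1
        est = gst_prime_and_jost_d([{"A": 1, "B": 1}, {"C": 1, "D": 1}])
        assert not est.defined
        assert math.isnan(est.g_st_prime)


class TestRegionalAggregate:
    def _pairs(self):
        return pd.DataFrame(
            [
                {"unit1": "E1", "unit2": "E2", "kst": 0.02},
                {"unit1": "W1", "unit2": "W2", "kst": 0.10},
                {"unit1": "E1", "unit2": "W1", "kst": 0.50},
            ]
        )

    def test_single_pair_per_region(self):
        region = {"E1": "east", "E2": "east", "W1": "west", "W2": "west"}
        out = regional_aggregate(self._pairs(), region, ["kst"])
        assert out.loc["east", "kst"] == pytest.approx(0.02)
        assert out.loc["west", "kst"] == pytest.approx(0.10)

    def test_pair_order_invariance(self):
        region = {"E1": "east", "E2": "east", "W1": "west", "W2": "west"}
        df = self._pairs().iloc[::-1].reset_index(drop=True)
        out = regional_aggregate(df, region, ["kst"])
        assert out.loc["east", "kst"] == pytest.approx(0.02)

    def test_region_with_single_unit_is_nan(self):
        region = {"E1": "east", "E2": "east", "W1": "lonely"}
        out = regional_aggregate(self._pairs(), region, ["kst"])
        assert math.isnan(out.loc["lonely", "kst"])
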