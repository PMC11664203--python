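"""Power definitions, their orderings, and the sample-size searches."""

import numpy as np
import pytest

from platformtrial import (BoundarySet, PowerRequest, conjunctive_power,
                           disjunctive_power, find_n, find_n_fixed_addition,
                           make_standard_layout, pairwise_power, power_table)

THP = -np.log(0.69)
NEG_INF = -np.inf


def test_power_request_validation():
    with pytest.raises(ValueError):
        PowerRequest(type="marginal", target=0.8)
    with pytest.raises(ValueError):
        PowerRequest(type="pairwise", target=1.2)


class TestPairwisePower:
    def test_symmetric_single_stage(self):
        # u = 1.96 and mean shift exactly at the bound: power one half
        lay = make_standard_layout(1, 1, 16, n_add=[0], theta_prime=0.5)
        b = BoundarySet(shape="custom", a=1.0, U=[(1.96,)], L=[(1.96,)])
        info = 1 / (1 / 16 + 1 / 16)
        theta = 1.96 / np.sqrt(info)
        assert pairwise_power(lay, b, 1, theta) == pytest.approx(0.5, abs=1e-9)

    def test_independent_of_other_arms(self, pairwise_design):
        layout, bounds = pairwise_design
        # the other arm's effect never appears in the computation; both arms
        # share geometry here so their pairwise powers coincide
        assert pairwise_power(layout, bounds, 1, THP) == pytest.approx(
            pairwise_power(layout, bounds, 2, THP), abs=1e-9)

    def test_minus_infinity_never_wins(self, small_design):
        layout, bounds = small_design
        assert pairwise_power(layout, bounds, 1, NEG_INF) == 0.0

    def test_invalid_arm(self, small_design):
        layout, bounds = small_design
        with pytest.raises(ValueError):
            pairwise_power(layout, bounds, 3, 0.2)


class TestPowerIdentities:
    """Structural identities among the three powers (single cheap design)."""

    @pytest.mark.parametrize("theta", [
        (0.5, 0.5), (0.5, 0.0), (0.0, 0.0), (0.9, 0.2), (0.5, NEG_INF),
    ])
    def test_ordering(self, small_design, theta):
        layout, bounds = small_design
        pw = [pairwise_power(layout, bounds, k, theta[k - 1]) for k in (1, 2)]
        pc = conjunctive_power(layout, bounds, theta)
        pd = disjunctive_power(layout, bounds, theta)
        # conjunctive is bounded by the weakest arm it actually has to find
        relevant = [pw[k] for k in (0, 1) if theta[k] >= layout.theta_prime]
        if relevant:
            assert pc <= min(relevant) + 1e-9
        assert max(pw) <= pd + 1e-9
        assert 0.0 <= pc <= 1.0 and 0.0 <= pd <= 1.0

    def test_one_relevant_arm_collapses_to_pairwise(self, small_design):
        layout, bounds = small_design
        theta = (layout.theta_prime, 0.0)
        pc = conjunctive_power(layout, bounds, theta)
        assert pc == pytest.approx(pairwise_power(layout, bounds, 1,
                                                  layout.theta_prime), abs=1e-9)

    def test_no_relevant_arm_is_certain(self, small_design):
        layout, bounds = small_design
        assert conjunctive_power(layout, bounds, (0.0, 0.0)) == 1.0

    def test_lone_survivor_equalises_all_powers(self, small_design):
        layout, bounds = small_design
        theta = (layout.theta_prime, NEG_INF)
        pw = pairwise_power(layout, bounds, 1, layout.theta_prime)
        assert conjunctive_power(layout, bounds, theta) == pytest.approx(pw, abs=1e-9)
        assert disjunctive_power(layout, bounds, theta) == pytest.approx(pw, abs=1e-9)

    def test_disjunctive_reduces_to_fwer_at_null(self, small_design):
        layout, bounds = small_design
        assert disjunctive_power(layout, bounds, (0.0, 0.0)) == pytest.approx(
            0.05, abs=1e-6)

    def test_power_table_is_consistent(self, small_design):
        layout, bounds = small_design
        tab = power_table(layout, bounds, (0.5, 0.2))
        assert tab["pairwise_1"] == pytest.approx(
            pairwise_power(layout, bounds, 1, 0.5), abs=1e-12)
        assert set(tab) == {"pairwise_1", "pairwise_2", "conjunctive",
                            "disjunctive"}


class TestConjunctiveMinimality:
    """The sizing guarantee: over arms at or above the clinically relevant
    effect, conjunctive power is smallest when they sit exactly at it."""

    def test_monotone_on_effect_grid(self, small_design):
        layout, bounds = small_design
        thp = layout.theta_prime
        base = conjunctive_power(layout, bounds, (thp, thp))
        grid = [(a * thp, b * thp) for a in (1.0, 1.5, 3.0)
                for b in (1.0, 1.5, 3.0)]
        for theta in grid:
            assert conjunctive_power(layout, bounds, theta) >= base - 1e-9

    def test_decreasing_in_number_of_relevant_arms(self, small_design):
        layout, bounds = small_design
        thp = layout.theta_prime
        both = conjunctive_power(layout, bounds, (thp, thp))
        one = conjunctive_power(layout, bounds, (thp, 0.0))
        assert both <= one + 1e-9


class TestFindN:
    def test_scan_and_bisect_agree(self):
        req = PowerRequest(type="pairwise", target=0.8)
        kw = dict(sigma=1.0, theta_prime=0.7, binding=True)
        scan, _ = find_n(2, 1, [0, 0.5], "triangular", 0.05, req,
                         method="scan", **kw)
        bis, _ = find_n(2, 1, [0, 0.5], "triangular", 0.05, req,
                        method="bisect", **kw)
        assert scan.n1 == bis.n1

    def test_power_met_minimally(self):
        req = PowerRequest(type="pairwise", target=0.8)
        layout, bounds = find_n(1, 2, [0.0], "triangular", 0.025, req,
                                theta_prime=THP)
        n = int(layout.n1)
        assert pairwise_power(layout, bounds, 1, THP) >= 0.8
        smaller = make_standard_layout(1, 2, n - 1, n_add=[0], theta_prime=THP)
        assert pairwise_power(smaller, bounds, 1, THP) < 0.8

    def test_unreachable_target_raises(self):
        req = PowerRequest(type="pairwise", target=0.8)
        with pytest.raises(RuntimeError):
            find_n(1, 1, [0.0], "triangular", 0.025, req, theta_prime=0.01,
                   n_cap=50)


class TestFindNFixedAddition:
    def test_zero_addition_reduces_to_ratio_search(self):
        req = PowerRequest(type="pairwise", target=0.8)
        kw = dict(sigma=1.0, theta_prime=0.7, binding=True)
        prop, _ = find_n(2, 1, [0, 0], "triangular", 0.05, req, **kw)
        fixed, _ = find_n_fixed_addition(2, 1, [0, 0], "triangular", 0.05,
                                         req, **kw)
        assert fixed.n1 == prop.n1

    def test_required_n_monotone_in_addition_count(self):
        req = PowerRequest(type="pairwise", target=0.8)
        kw = dict(sigma=1.0, theta_prime=0.7, binding=True)
        sizes = [
            find_n_fixed_addition(2, 1, [0, g], "triangular", 0.05, req,
                                  **kw)[0].n1
            for g in (0, 10, 25, 40)
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_warm_start_does_not_change_answer(self):
        req = PowerRequest(type="pairwise", target=0.8)
        kw = dict(sigma=1.0, theta_prime=0.7, binding=True)
        cold, _ = find_n_fixed_addition(2, 1, [0, 25], "triangular", 0.05,
                                        req, **kw)
        warm, _ = find_n_fixed_addition(2, 1, [0, 25], "triangular", 0.05,
                                        req, n_start=5, **kw)
        assert warm.n1 == cold.n1
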