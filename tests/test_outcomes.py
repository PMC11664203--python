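"""Outcome enumeration, sample-size distributions and expected sizes."""

import numpy as np
import pytest

from platformtrial import (BoundarySet, StopProfile, enumerate_outcomes,
                           expected_N, make_standard_layout,
                           outcome_probability, paused_N,
                           sample_size_distribution, simulate_trial)

NEG_INF = -np.inf


def test_stop_profile_validation():
    with pytest.raises(ValueError):
        StopProfile(j=(1, 2), q=(0,))
    with pytest.raises(ValueError):
        StopProfile(j=(1,), q=(2,))


def test_single_stage_outcomes_partition(small_design):
    layout, bounds = small_design
    lay1 = make_standard_layout(1, 1, 20, n_add=[0], theta_prime=0.5)
    b1 = BoundarySet(shape="custom", a=1.0, U=[(1.7,)], L=[(1.7,)])
    q_fut = outcome_probability(lay1, b1, StopProfile(j=(1,), q=(0,)), [0.3])
    q_eff = outcome_probability(lay1, b1, StopProfile(j=(1,), q=(1,)), [0.3])
    assert q_fut + q_eff == pytest.approx(1.0, abs=1e-9)


def test_invalid_profile_rejected(small_design):
    layout, bounds = small_design
    with pytest.raises(ValueError):
        outcome_probability(layout, bounds, StopProfile(j=(2, 1), q=(0, 0)),
                            [0.1, 0.1])


class TestEnumeration:
    def test_probabilities_partition_unity(self, pairwise_design, theta_prime):
        layout, bounds = pairwise_design
        tab = enumerate_outcomes(layout, bounds, [theta_prime, theta_prime])
        assert tab.total_probability == pytest.approx(1.0, abs=1e-5)
        assert len(tab.table) == 16

    def test_support_of_total_sample_size(self, pairwise_design, theta_prime):
        layout, bounds = pairwise_design
        dist = sample_size_distribution(layout, bounds,
                                        [theta_prime, theta_prime])
        assert set(dist["N"]) <= {304.0, 380.0, 456.0, 532.0}
        assert dist["probability"].sum() == pytest.approx(1.0, abs=1e-5)
        assert (dist["N"] <= layout.max_N).all()

    def test_efficacy_profiles_sum_to_conjunctive(self, pairwise_design,
                                                  theta_prime):
        # grouping the enumeration by exit directions recovers the
        # closed-form conjunctive and disjunctive powers
        from platformtrial import conjunctive_power, disjunctive_power
        layout, bounds = pairwise_design
        theta = [theta_prime, theta_prime]
        tab = enumerate_outcomes(layout, bounds, theta).table
        all_eff = sum(row["Q"] for _, row in tab.iterrows()
                      if row["profile"].q == (1, 1))
        any_eff = sum(row["Q"] for _, row in tab.iterrows()
                      if 1 in row["profile"].q)
        assert all_eff == pytest.approx(
            conjunctive_power(layout, bounds, theta), abs=1e-6)
        assert any_eff == pytest.approx(
            disjunctive_power(layout, bounds, theta), abs=1e-6)

    def test_hopeless_arms_concentrate_on_first_stage(self, pairwise_design):
        layout, bounds = pairwise_design
        tab = enumerate_outcomes(layout, bounds, [NEG_INF, NEG_INF])
        assert len(tab.table) == 1
        row = tab.table.iloc[0]
        assert row["profile"].j == (1, 1) and row["Q"] == pytest.approx(1.0)
        assert row["N"] == 304.0

    def test_arm_marginal_distributions(self, pairwise_design, theta_prime):
        layout, bounds = pairwise_design
        tab = enumerate_outcomes(layout, bounds, [theta_prime, theta_prime])
        arm1 = tab.arm_sample_size_distribution(1)
        assert set(arm1["n"]) == {76.0, 152.0}
        assert arm1["probability"].sum() == pytest.approx(1.0, abs=1e-5)
        ctrl = tab.arm_sample_size_distribution(0)
        assert ctrl["probability"].sum() == pytest.approx(1.0, abs=1e-5)


class TestExpectedN:
    def test_forced_full_trial_reaches_maximum(self, pairwise_design):
        layout, _ = pairwise_design
        # interim bounds wide open: every arm reaches its final analysis
        open_bounds = BoundarySet(shape="custom", a=1.0,
                                  U=[(np.inf, 0.0)] * 2, L=[(-np.inf, 0.0)] * 2)
        assert expected_N(layout, open_bounds, [0.0, 0.0]) == pytest.approx(
            layout.max_N, abs=1e-6)

    def test_matches_direct_sum(self, small_design):
        layout, bounds = small_design
        theta = [0.4, 0.2]
        tab = enumerate_outcomes(layout, bounds, theta).table
        direct = (tab["Q"] * tab["N"]).sum()
        assert expected_N(layout, bounds, theta) == pytest.approx(direct)


class TestPausedRecruitment:
    def test_single_gap_arithmetic(self):
        # arm 1 stops at its only analysis with 10 controls accrued; arm 2
        # joins at 20, so 10 control patients are never recruited
        lay = make_standard_layout(2, 1, 10, n_add=[0, 20], theta_prime=0.5)
        assert paused_N(lay, (1, 1)) == lay.max_N - 10 == 40.0

    def test_no_gap_when_additions_overlap(self, pairwise_design):
        # second arm joins at the first interim, before arm 1 can have
        # stopped, so pausing never has an effect
        layout, bounds = pairwise_design
        tab = enumerate_outcomes(layout, bounds, [0.0, 0.0]).table
        assert (tab["N_paused"] == tab["N"]).all()

    def test_paused_never_exceeds_continuous(self):
        lay = make_standard_layout(2, 2, 10, n_add=[0, 25], theta_prime=0.5)
        for j1 in (1, 2):
            for j2 in (1, 2):
                assert paused_N(lay, (j1, j2)) <= lay.max_N
                assert paused_N(lay, (j1, j2)) <= float(
                    lay.treatment_count(1, j1) + lay.treatment_count(2, j2)
                    + max(lay.control_count(1, j1), lay.control_count(2, j2)))

    def test_simulator_agrees_with_paused_accounting(self):
        from platformtrial import calibrate
        # arm 2 joins only after arm 1 could finish, so real pauses occur
        # whose length depends on where arm 1 stops
        lay = make_standard_layout(2, 2, 15, n_add=[0, 45], theta_prime=0.5)
        bounds = calibrate(lay, "triangular", 0.05)
        res = simulate_trial(lay, bounds, [0.0, 0.0], reps=40_000, seed=7)
        analytic = expected_N(lay, bounds, [0.0, 0.0], paused=True)
        assert res.expected_N_se(paused=True) > 0
        assert abs(res.expected_N(paused=True) - analytic) < \
            4 * res.expected_N_se(paused=True)
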