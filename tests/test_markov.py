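"""Markov engine: transforms, transition structure, cohort recursion, payoffs."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asthmacea.markov import (
    HealthState,
    InfeasibleParameterError,
    accumulate_outcomes,
    apply_odds_ratio,
    apply_relative_risk,
    build_transition_matrix,
    drug_cost_per_cycle,
    prob_to_rate,
    rate_to_prob,
    run_cohort,
    run_strategy,
)
from asthmacea.parameters import RangedValue, Strategy, base_case_parameters
from asthmacea.synthetic import reference_trace
from tests.conftest import with_settings

PROB_GRID = np.linspace(0.01, 0.99, 99)


class TestProbabilityTransforms:
    def test_prob_to_rate_examples(self):
        assert prob_to_rate(0.0, 1) == 0.0
        assert prob_to_rate(0.11, 1) == pytest.approx(-math.log(0.89), rel=1e-12)

    def test_prob_rate_round_trip_on_grid(self):
        for p in PROB_GRID:
            assert rate_to_prob(prob_to_rate(p)) == pytest.approx(p, abs=1e-12)

    def test_prob_one_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            prob_to_rate(1.0)

    def test_relative_risk_closed_form_on_grid(self):
        for p in PROB_GRID:
            for rr in (0.5, 0.85, 1.0, 1.5):
                assert apply_relative_risk(p, rr) == pytest.approx(
                    1.0 - (1.0 - p) ** rr, abs=1e-12)

    def test_relative_risk_null_and_zero(self):
        assert apply_relative_risk(0.11, 1.0) == pytest.approx(0.11, abs=1e-15)
        assert apply_relative_risk(0.0, 0.3) == 0.0
        assert apply_relative_risk(0.11, 0.85) < 0.11

    def test_odds_ratio_closed_form_on_grid(self):
        for p in PROB_GRID:
            for o in (0.5, 0.65, 1.0, 2.0):
                odds = o * p / (1 - p)
                assert apply_odds_ratio(p, o) == pytest.approx(
                    odds / (1 + odds), abs=1e-12)

    def test_odds_ratio_examples(self):
        assert apply_odds_ratio(0.02, 1.0) == pytest.approx(0.02, abs=1e-15)
        assert apply_odds_ratio(0.5, 0.65) == pytest.approx(0.65 / 1.65, abs=1e-12)

    @given(p=st.floats(0, 0.99), ratio=st.floats(0.01, 10))
    @settings(max_examples=100, deadline=None)
    def test_transforms_stay_in_unit_interval(self, p, ratio):
        # closed interval: a huge hazard multiple rounds to 1.0 in floats
        assert 0.0 <= apply_relative_risk(p, ratio) <= 1.0
        assert 0.0 <= apply_odds_ratio(p, ratio) < 1.0


class TestTransitionMatrix:
    def test_maintenance_controlled_row_zero_mortality(
            self, base_params, no_mortality_table):
        m = build_transition_matrix(
            base_params, no_mortality_table, 30, Strategy.MAINTENANCE_ICS)
        np.testing.assert_allclose(
            m[HealthState.CONTROLLED], [0.89, 0.11, 0, 0, 0, 0], atol=1e-12)

    def test_as_needed_entry_probability_scaled(
            self, base_params, no_mortality_table):
        m = build_transition_matrix(
            base_params, no_mortality_table, 30, Strategy.AS_NEEDED_ICS_FORMOTEROL)
        assert m[HealthState.CONTROLLED, HealthState.OCS_BURST] == pytest.approx(
            1.0 - 0.89 ** 0.85, abs=1e-12)

    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_rows_sum_to_one_and_death_rows_identity(
            self, base_params, life_table, strategy):
        m = build_transition_matrix(base_params, life_table, 60, strategy)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0) and np.all(m <= 1)
        for dead in (HealthState.ASTHMA_DEATH, HealthState.OTHER_DEATH):
            expected = np.zeros(6)
            expected[dead] = 1.0
            np.testing.assert_array_equal(m[dead], expected)

    def test_asthma_death_only_from_hospitalization(
            self, base_params, life_table):
        m = build_transition_matrix(
            base_params, life_table, 60, Strategy.MAINTENANCE_ICS)
        col = m[:, HealthState.ASTHMA_DEATH]
        assert col[HealthState.HOSPITALIZATION] > 0
        alive_others = [HealthState.CONTROLLED, HealthState.OCS_BURST,
                        HealthState.ED_VISIT]
        assert all(col[s] == 0 for s in alive_others)

    def test_ed_risk_scale_switch(self, base_params, no_mortality_table):
        risk_params = with_settings(base_params, ed_effect_scale="risk")
        m = build_transition_matrix(
            risk_params, no_mortality_table, 30, Strategy.AS_NEEDED_ICS_FORMOTEROL)
        assert m[HealthState.OCS_BURST, HealthState.ED_VISIT] == pytest.approx(
            1.0 - 0.98 ** 0.65, abs=1e-12)


class TestCohortRecursion:
    def test_absorbing_identity_with_no_transitions(
            self, base_params, no_mortality_table):
        frozen = dataclasses.replace(
            base_params,
            transitions=dataclasses.replace(
                base_params.transitions,
                p_controlled_to_ocs_burst=RangedValue(0, 0, 0.14)),
            settings=dataclasses.replace(
                base_params.settings, horizon_age_years=35))
        trace = run_cohort(frozen, no_mortality_table, Strategy.MAINTENANCE_ICS)
        # stays (1, 0, ..., 0) until the absorbing terminal year empties it
        alive_cycles = trace.cycle_death_prob < 1.0
        np.testing.assert_array_equal(
            trace.occupancy[:-1][alive_cycles, HealthState.CONTROLLED],
            np.ones(alive_cycles.sum()))

    def test_conservation_and_death_monotone(self, base_params, life_table):
        for strategy in Strategy:
            trace = run_cohort(base_params, life_table, strategy)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = trace.occupancy[:, 4:].sum(axis=1)
            assert np.all(np.diff(dead) >= -1e-15)

    def test_engine_matches_independent_oracle_20_cycles(
            self, base_params, life_table):
        for strategy in Strategy:
            trace = run_cohort(base_params, life_table, strategy)
            oracle = np.array(reference_trace(base_params, life_table, strategy, 20))
            np.testing.assert_allclose(
                trace.occupancy[:21], oracle, rtol=0, atol=1e-12)

    def test_three_cycle_trace_matches_hand_matrix_powers(
            self, base_params, no_mortality_table):
        # explicit hand multiplication with the base maintenance probabilities
        p1, p2, p3, p4 = 0.11, 0.02, 0.0117, 2e-6
        m = np.array([
            [1 - p1, p1, 0, 0, 0, 0],
            [1 - p2, 0, p2, 0, 0, 0],
            [1 - p3, 0, 0, p3, 0, 0],
            [1 - p4, 0, 0, 0, p4, 0],
            [0, 0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0, 1],
        ])
        start = np.array([1.0, 0, 0, 0, 0, 0])
        expected = [start, start @ m, start @ m @ m, start @ m @ m @ m]
        trace = run_cohort(base_params, no_mortality_table, Strategy.MAINTENANCE_ICS)
        np.testing.assert_allclose(
            trace.occupancy[:4], np.array(expected), atol=1e-14)

    def test_cohort_fully_dead_at_horizon(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, Strategy.MAINTENANCE_ICS)
        assert trace.occupancy[-1, 4:].sum() == pytest.approx(1.0, abs=1e-10)

    def test_trace_frame_layout(self, short_params, life_table):
        df = run_cohort(short_params, life_table, Strategy.MAINTENANCE_ICS).to_frame()
        assert list(df.columns) == [
            "cycle", "age", "controlled", "ocs_burst", "ed_visit",
            "hospitalization", "asthma_death", "other_death"]
        assert df["age"].iloc[0] == 30


class TestPayoffs:
    def test_drug_cost_examples(self, base_params):
        assert drug_cost_per_cycle(
            base_params, Strategy.AS_NEEDED_ICS_FORMOTEROL) == pytest.approx(
            (53 / 120) * 0.52 * 0.68 * 28, rel=1e-12)
        assert drug_cost_per_cycle(
            base_params, Strategy.MAINTENANCE_ICS) == pytest.approx(
            (53 / 120) * 2 * 0.62 * 28, rel=1e-12)

    def test_zero_adherence_zero_drug_cost(self, base_params):
        zeroed = dataclasses.replace(
            base_params,
            effects=dataclasses.replace(
                base_params.effects,
                adherence_as_needed=RangedValue(0, 0, 0.85)))
        assert drug_cost_per_cycle(zeroed, Strategy.AS_NEEDED_ICS_FORMOTEROL) == 0.0

    def test_undiscounted_qalys_equal_years_when_utility_one(
            self, base_params, no_mortality_table):
        ones = {f.name: RangedValue(1.0, 0.5, 1.0)
                for f in dataclasses.fields(base_params.utilities)}
        params = dataclasses.replace(
            base_params,
            utilities=dataclasses.replace(base_params.utilities, **ones),
            settings=dataclasses.replace(
                base_params.settings, horizon_age_years=40,
                annual_discount_rate=RangedValue(0, 0, 0.06)))
        trace = run_cohort(params, no_mortality_table, Strategy.MAINTENANCE_ICS)
        out = accumulate_outcomes(trace, params)
        # nobody dies before the absorbing year, utility is 1 everywhere:
        # QALYs == person-years == simulated cycles x cycle length, up to the
        # final absorbing cycle handled by the trapezoid
        assert out.total_discounted_qalys == pytest.approx(
            out.person_years_alive, abs=1e-10)

    def test_discounting_strictly_reduces_totals(self, short_params, life_table):
        trace = run_cohort(short_params, life_table, Strategy.MAINTENANCE_ICS)
        discounted = accumulate_outcomes(trace, short_params)
        undisc_params = with_settings(
            short_params, annual_discount_rate=RangedValue(0, 0, 0.06))
        undiscounted = accumulate_outcomes(trace, undisc_params)
        assert discounted.total_discounted_cost < undiscounted.total_discounted_cost
        assert discounted.total_discounted_qalys < undiscounted.total_discounted_qalys

    def test_zero_discount_equals_plain_sums(self, base_params, no_mortality_table):
        params = with_settings(
            base_params, horizon_age_years=35,
            annual_discount_rate=RangedValue(0, 0, 0.06),
            half_cycle_correction=False)
        trace = run_cohort(params, no_mortality_table, Strategy.MAINTENANCE_ICS)
        out = accumulate_outcomes(trace, params)
        # independent plain sum of the cost stream
        occ = trace.occupancy
        cyc_years = 28 / 365.25
        alive = occ[:, :4].sum(axis=1)
        cost = (alive * (drug_cost_per_cycle(params, Strategy.MAINTENANCE_ICS)
                         + 416 * cyc_years)
                + occ[:, 1] * 94 + occ[:, 2] * 191 + occ[:, 3] * 386)
        assert out.total_discounted_cost == pytest.approx(
            cost[:-1].sum(), rel=1e-12)

    def test_trapezoid_on_two_point_trace_is_endpoint_mean(
            self, base_params, no_mortality_table):
        params = with_settings(
            base_params, horizon_age_years=31,
            annual_discount_rate=RangedValue(0, 0, 0.06))
        trace = run_cohort(params, no_mortality_table, Strategy.MAINTENANCE_ICS)
        two_point = dataclasses.replace(
            trace,
            occupancy=trace.occupancy[:2],
            cycle_ages=trace.cycle_ages[:2],
            cycle_death_prob=trace.cycle_death_prob[:1])
        out = accumulate_outcomes(two_point, params)
        u = params.utilities
        w = np.array([u.u_controlled.base, u.u_ocs_burst.base,
                      u.u_ed_visit.base, u.u_hospitalization.base, 0, 0])
        payoffs = two_point.occupancy @ w * (28 / 365.25)
        assert out.total_discounted_qalys == pytest.approx(
            payoffs.mean(), rel=1e-12)

    def test_wrong_state_count_rejected(self, short_params, life_table):
        trace = run_cohort(short_params, life_table, Strategy.MAINTENANCE_ICS)
        bad = dataclasses.replace(trace, occupancy=trace.occupancy[:, :5])
        with pytest.raises(ValueError, match="states"):
            accumulate_outcomes(bad, short_params)


class TestStrategyComparisons:
    def test_null_effect_and_equal_dosing_gives_identical_outcomes(
            self, base_params, life_table):
        params = dataclasses.replace(
            base_params,
            effects=dataclasses.replace(
                base_params.effects,
                rr_exacerbation=RangedValue(1.0, 0.72, 1.0),
                or_ed_visit=RangedValue(1.0, 0.43, 1.0),
                adherence_as_needed=RangedValue(0.62, 0.51, 0.85),
                as_needed_doses_per_day=RangedValue(2.0, 0.39, 2.0)),
            settings=dataclasses.replace(
                base_params.settings, horizon_age_years=60))
        _, an = run_strategy(params, life_table, Strategy.AS_NEEDED_ICS_FORMOTEROL)
        _, maint = run_strategy(params, life_table, Strategy.MAINTENANCE_ICS)
        assert an.total_discounted_cost == pytest.approx(
            maint.total_discounted_cost, abs=1e-12)
        assert an.total_discounted_qalys == pytest.approx(
            maint.total_discounted_qalys, abs=1e-12)
        assert an.exacerbation_free_survival == pytest.approx(
            maint.exacerbation_free_survival, abs=1e-15)

    def test_protective_effects_never_hurt_quality_outcomes(
            self, base_params, life_table):
        """rr < 1 and or < 1 must give the as-needed arm >= QALYs and
        >= exacerbation-free survival across random parameter draws."""
        rng = np.random.default_rng(20210)
        for _ in range(100):
            params = dataclasses.replace(
                base_params,
                transitions=dataclasses.replace(
                    base_params.transitions,
                    p_controlled_to_ocs_burst=RangedValue(
                        rng.uniform(0.01, 0.4), 0.0, 0.5),
                    p_ocs_burst_to_ed=RangedValue(
                        rng.uniform(0.005, 0.2), 0.0, 0.3)),
                effects=dataclasses.replace(
                    base_params.effects,
                    rr_exacerbation=RangedValue(rng.uniform(0.4, 1.0), 0.3, 1.0),
                    or_ed_visit=RangedValue(rng.uniform(0.3, 1.0), 0.2, 1.0)),
                settings=dataclasses.replace(
                    base_params.settings, horizon_age_years=45))
            _, an = run_strategy(params, life_table,
                                 Strategy.AS_NEEDED_ICS_FORMOTEROL)
            _, maint = run_strategy(params, life_table, Strategy.MAINTENANCE_ICS)
            assert an.total_discounted_qalys >= maint.total_discounted_qalys - 1e-12
            assert (an.exacerbation_free_survival
                    >= maint.exacerbation_free_survival - 1e-12)

    def test_landmark_survival_composition(self, base_params, life_table):
        """First-passage survival at one year equals the closed-form product."""
        _, summary = run_strategy(base_params, life_table,
                                  Strategy.MAINTENANCE_ICS)
        trace = run_cohort(base_params, life_table, Strategy.MAINTENANCE_ICS)
        expected = np.prod(1 - trace.cycle_death_prob[:13]) * 0.89 ** 13
        assert summary.exacerbation_free_survival == pytest.approx(
            expected, rel=1e-12)
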