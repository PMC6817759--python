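"""Cohort engine: transition matrices, traces, accrual, and an independent
individual-level microsimulation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from menocea import (
    ParameterSet,
    ValidationError,
    accrue,
    discount_factor,
    run_cohort,
    run_strategy,
    transition_matrix,
)
from menocea.markov import DEAD, MS, RED, REC1, N_STATES
from menocea.parameters import mortality_schedule, per_cycle_probability


def _no_risk_params(params):
    """Fixture variant with recurrence and mortality switched off."""
    p = params.copy()
    p.transitions.p_to_recurrence = 0.0
    p.transitions.p_rec_death = 0.0
    p.transitions.background_mortality = [0.0, 0.0]
    return p


class TestTransitionMatrix:
    def test_rows_are_stochastic(self, params):
        for strategy in ("guided", "self_managed", "waitlist"):
            for cycle in (1, 5, 10):
                T = transition_matrix(params, strategy, cycle)
                assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
                assert (T >= 0).all()

    def test_first_cycle_response_entry(self, params):
        p_rec = per_cycle_probability(0.01, 0.5)
        m1 = mortality_schedule(params.transitions, 10, 0.5)[0]
        T = transition_matrix(params, "guided", 1)
        assert T[MS, RED] == pytest.approx(0.44 * (1 - p_rec - m1), rel=1e-12)

    def test_no_response_after_first_cycle(self, params):
        for cycle in (2, 3, 10):
            assert transition_matrix(params, "waitlist", cycle)[MS, RED] == 0.0

    def test_dead_row_is_identity(self, params):
        T = transition_matrix(params, "guided", 3)
        expected = np.zeros(N_STATES)
        expected[DEAD] = 1.0
        assert np.array_equal(T[DEAD], expected)

    def test_cycle_out_of_range(self, params):
        with pytest.raises(ValueError):
            transition_matrix(params, "guided", 0)
        with pytest.raises(ValueError):
            transition_matrix(params, "guided", 11)

    def test_inconsistent_probabilities_rejected(self, params):
        bad = params.copy()
        bad.transitions.p_to_recurrence = 0.9
        bad.transitions.probs_are_annual = False
        bad.transitions.background_mortality = [0.4, 0.4]
        bad.transitions.mortality_is_per_cycle = True
        with pytest.raises(ValueError):
            transition_matrix(bad, "guided", 1)


class TestRunCohort:
    def test_initial_condition(self, params):
        trace = run_cohort(params, "waitlist")
        expected = np.zeros(N_STATES)
        expected[MS] = 1.0
        assert np.array_equal(trace.occupancy[0], expected)
        assert trace.occupancy.shape == (11, N_STATES)

    def test_degenerate_dynamics_hold_responders(self, params):
        trace = run_cohort(_no_risk_params(params), "guided")
        assert np.allclose(trace.occupancy[1:, RED], 0.44, atol=1e-12)
        assert np.allclose(trace.occupancy[1:, MS], 0.56, atol=1e-12)

    def test_death_occupancy_monotone(self, params):
        trace = run_cohort(params, "waitlist")
        assert (np.diff(trace.occupancy[:, DEAD]) >= 0).all()
        # strictly increasing once recurrence is populated
        assert (np.diff(trace.occupancy[1:, DEAD]) > 0).all()

    def test_effect_expiry_reverts_responders(self, params):
        p = _no_risk_params(params)
        p.effect_duration_cycles = 6
        trace = run_cohort(p, "guided")
        assert trace.occupancy[6, RED] == pytest.approx(0.44)
        assert np.allclose(trace.occupancy[7:, RED], 0.0, atol=1e-12)
        assert np.allclose(trace.occupancy[7:, MS], 1.0, atol=1e-12)

    @given(
        p_resp=st.floats(0.0, 1.0),
        p_rec=st.floats(0.0, 0.5),
        p_rd=st.floats(0.0, 0.8),
        bg_lo=st.floats(0.0, 0.05),
        bg_step=st.floats(0.0, 0.05),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_over_random_parameters(self, params, p_resp, p_rec,
                                                 p_rd, bg_lo, bg_step):
        p = params.copy()
        p.transitions.p_response = {k: p_resp for k in p.transitions.p_response}
        p.transitions.p_to_recurrence = p_rec
        p.transitions.p_rec_death = p_rd
        p.transitions.background_mortality = [bg_lo, bg_lo + bg_step]
        p.validate()
        trace = run_cohort(p, "guided")
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (trace.occupancy >= -1e-12).all()


class TestDiscountFactor:
    @pytest.mark.parametrize("rate,time,expected", [
        (0.04, 1.0, 1 / 1.04),
        (0.015, 5.0, 1.015 ** -5),
        (0.0, 7.3, 1.0),
    ])
    def test_values(self, rate, time, expected):
        assert discount_factor(rate, time) == pytest.approx(expected, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)
        with pytest.raises(ValueError):
            discount_factor(0.04, -1.0)


class TestAccrue:
    def test_zero_utilities_zero_qalys(self, params):
        p = params.copy()
        p.utilities.u_ms = p.utilities.u_red = p.utilities.u_rec = 0.0
        res = run_strategy(p, "waitlist")
        assert res.total_qaly == 0.0

    def test_single_cycle_hand_computed(self, params):
        p = _no_risk_params(params)
        p.n_cycles = 1
        p.discount_effects = 0.0
        p.discount_costs = 0.0
        p.utilities.u_ms = 0.8
        p.transitions.p_response = {k: 0.0 for k in p.transitions.p_response}
        res = run_strategy(p, "waitlist")
        assert res.total_qaly == pytest.approx(0.40, abs=1e-12)
        assert res.total_cost == pytest.approx(p.costs.state_cost_ms, rel=1e-12)

    def test_intervention_perspective_costs(self, params):
        assert run_strategy(params, "guided", "intervention").total_cost == 226.09
        assert run_strategy(params, "waitlist", "intervention").total_cost == 0.0

    def test_unknown_perspective(self, params):
        with pytest.raises(ValueError):
            run_strategy(params, "guided", "societal")

    def test_qaly_bounded_by_horizon(self, params):
        res = run_strategy(params, "guided")
        assert 0 < res.total_qaly <= params.n_cycles * params.cycle_length * 0.85

    def test_cost_monotone_in_state_cost(self, params):
        from menocea.sensitivity import set_parameter
        base = run_strategy(params, "waitlist").total_cost
        up = set_parameter(params, "costs.state_cost_ms", 700.0)
        assert run_strategy(up, "waitlist").total_cost > base

    def test_qaly_monotone_in_utility(self, params):
        from menocea.sensitivity import set_parameter
        base = run_strategy(params, "waitlist").total_qaly
        up = set_parameter(params, "utilities.u_ms", 0.9)
        assert run_strategy(up, "waitlist").total_qaly > base

    def test_accrual_modes_bracket_half_cycle(self, params):
        totals = {}
        for mode in ("begin", "end", "half_cycle"):
            p = params.copy()
            p.accrual = mode
            totals[mode] = run_strategy(p, "waitlist").total_qaly
        assert totals["end"] < totals["half_cycle"] < totals["begin"]

    def test_closed_form_static_cohort(self, params):
        # no transitions at all, zero rates: totals are plain sums
        p = _no_risk_params(params)
        p.transitions.p_response = {k: 0.0 for k in p.transitions.p_response}
        p.discount_effects = p.discount_costs = 0.0
        res = run_strategy(p, "waitlist")
        assert res.total_qaly == pytest.approx(10 * 0.5 * 0.83, rel=1e-12)
        assert res.total_cost == pytest.approx(10 * p.costs.state_cost_ms, rel=1e-12)


class TestMicrosimulationOracle:
    """Monte-Carlo agreement between the deterministic cohort trace and an
    independent per-individual simulation through the same matrices."""

    N = 100_000

    def _microsimulate(self, params, strategy, n, seed):
        rng = np.random.default_rng(seed)
        states = np.zeros(n, dtype=np.int64)
        occ = np.zeros((params.n_cycles + 1, N_STATES))
        occ[0] = np.bincount(states, minlength=N_STATES) / n
        expiry = params.effect_duration_cycles
        for c in range(1, params.n_cycles + 1):
            if expiry is not None and c == expiry + 1:
                states[states == RED] = MS
            T = transition_matrix(params, strategy, c)
            cum = T.cumsum(axis=1)
            u = rng.random(n)
            states = (u[:, None] > cum[states]).sum(axis=1)
            occ[c] = np.bincount(states, minlength=N_STATES) / n
        return occ

    @pytest.mark.parametrize("strategy", ["guided", "waitlist"])
    def test_trace_within_three_mc_standard_errors(self, params, strategy):
        trace = run_cohort(params, strategy)
        sim = self._microsimulate(params, strategy, self.N, seed=42)
        p = trace.occupancy
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / self.N)
        # allow a tiny absolute floor for near-degenerate occupancies
        assert (np.abs(sim - p) <= 3 * se + 5e-6).all()
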