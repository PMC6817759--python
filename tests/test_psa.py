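"""Distribution fitting, parameter sampling, and PSA summaries."""

import numpy as np
import pytest

from menocea import (
    PsaConfig,
    ValidationError,
    beta_from_mean_se,
    ceac,
    dirichlet_counts,
    draw_parameter_set,
    gamma_from_mean_se,
    ne_quadrant_fraction,
    quadrant_fractions,
    run_psa,
    run_strategy,
)
from menocea.psa import PsaResult, default_wtp_grid


class TestBetaFromMeanSe:
    def test_utility_shape_parameters(self):
        a, b = beta_from_mean_se(0.83, 0.013)
        assert a == pytest.approx(692.15, abs=0.01)
        assert b == pytest.approx(141.77, abs=0.01)

    def test_moments_recovered(self):
        a, b = beta_from_mean_se(0.73, 0.020)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.73, abs=1e-9)
        assert var ** 0.5 == pytest.approx(0.020, abs=1e-9)

    def test_tiny_se_concentrates(self, rng):
        a, b = beta_from_mean_se(0.5, 1e-5)
        draws = rng.beta(a, b, 1000)
        assert np.allclose(draws, 0.5, atol=1e-3)

    def test_sampling_mean(self, rng):
        a, b = beta_from_mean_se(0.73, 0.020)
        assert rng.beta(a, b, 10**6).mean() == pytest.approx(0.730, abs=0.001)

    def test_infeasible_se(self):
        with pytest.raises(ValueError):
            beta_from_mean_se(0.83, 0.5)


class TestGammaFromMeanSe:
    @pytest.mark.parametrize("mean", [226.09, 580.64, 47.92])
    def test_twenty_percent_rule_gives_shape_25(self, mean):
        shape, scale = gamma_from_mean_se(mean, 0.2 * mean)
        assert shape == pytest.approx(25.0, rel=1e-12)
        assert shape * scale == pytest.approx(mean, rel=1e-12)

    def test_explicit_values(self):
        shape, scale = gamma_from_mean_se(226.09, 45.218)
        assert shape == pytest.approx(25.0)
        assert scale == pytest.approx(9.0436)

    def test_moment_round_trip(self):
        shape, scale = gamma_from_mean_se(123.4, 56.7)
        assert shape * scale == pytest.approx(123.4, rel=1e-12)
        assert (shape * scale ** 2) ** 0.5 == pytest.approx(56.7, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            gamma_from_mean_se(-1.0, 1.0)


class TestDirichletCounts:
    def test_multiplication(self):
        conc = dirichlet_counts([0.44, 0.56], 85)
        assert conc == pytest.approx([37.4, 47.6])

    def test_degenerate_component_floored(self):
        conc = dirichlet_counts([1.0, 0.0], 85)
        assert conc[0] == pytest.approx(85.0)
        assert 0 < conc[1] <= 1e-9

    def test_sampling_mean(self, rng):
        conc = dirichlet_counts([0.44, 0.56], 85)
        draws = rng.dirichlet(conc, 10**5)[:, 0]
        assert draws.mean() == pytest.approx(0.44, abs=0.005)

    def test_not_normalized_rejected(self):
        with pytest.raises(ValidationError):
            dirichlet_counts([0.5, 0.6], 85)


class TestDrawParameterSet:
    def test_all_fixed_is_identity(self, params, rng):
        p = params.copy()
        p.psa_specs = {k: type(v)("fixed", v.mean) for k, v in p.psa_specs.items()}
        p.cost_se_fraction = 0.0
        draw = draw_parameter_set(p, rng)
        assert draw.to_dict() == p.to_dict()

    def test_draws_validate_and_stay_in_support(self, params, rng):
        for _ in range(50):
            d = draw_parameter_set(params, rng)
            d.validate()
            for u in (d.utilities.u_ms, d.utilities.u_red, d.utilities.u_rec):
                assert 0.0 <= u <= 1.0
            assert all(0 <= v <= 1 for v in d.transitions.p_response.values())
            assert d.costs.state_cost_ms > 0

    def test_recurrence_probs_fixed_by_default(self, params, rng):
        d = draw_parameter_set(params, rng)
        assert d.transitions.p_to_recurrence == 0.01
        assert d.transitions.p_rec_death == 0.04

    def test_sampling_moments_match_specs(self, params):
        rng = np.random.default_rng(7)
        n = 5000
        u_ms = np.empty(n)
        cost_g = np.empty(n)
        for i in range(n):
            d = draw_parameter_set(params, rng)
            u_ms[i] = d.utilities.u_ms
            cost_g[i] = d.costs.intervention_cost["guided"]
        # empirical mean within 4 standard errors of the spec
        assert abs(u_ms.mean() - 0.83) < 4 * 0.013 / n**0.5
        assert abs(u_ms.std(ddof=1) - 0.013) < 4 * 0.013 / (2 * n) ** 0.5
        se_g = 0.2 * 226.09
        assert abs(cost_g.mean() - 226.09) < 4 * se_g / n**0.5


class TestRunPsa:
    def test_seed_reproducibility(self, params):
        cfg = PsaConfig(n_draws=25, seed=99)
        a = run_psa(params, cfg)
        b = run_psa(params, cfg)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_different_seeds_differ(self, params):
        a = run_psa(params, PsaConfig(n_draws=10, seed=1))
        b = run_psa(params, PsaConfig(n_draws=10, seed=2))
        assert not np.array_equal(a.costs, b.costs)

    def test_degenerate_psa_equals_deterministic(self, params):
        p = params.copy()
        p.psa_specs = {k: type(v)("fixed", v.mean) for k, v in p.psa_specs.items()}
        p.cost_se_fraction = 0.0
        psa = run_psa(p, PsaConfig(n_draws=1, seed=0))
        for j, s in enumerate(psa.strategies):
            det = run_strategy(p, s)
            assert psa.costs[0, j] == pytest.approx(det.total_cost, rel=1e-12)
            assert psa.qalys[0, j] == pytest.approx(det.total_qaly, rel=1e-12)

    def test_psa_mean_near_point_estimate(self, params):
        """The PSA mean incremental QALY (guided vs waitlist) agrees with the
        deterministic value within Monte-Carlo error."""
        n = 1000
        psa = run_psa(params, PsaConfig(n_draws=n, seed=5))
        g = psa.strategies.index("guided")
        w = psa.strategies.index("waitlist")
        dq = psa.qalys[:, g] - psa.qalys[:, w]
        det = (run_strategy(params, "guided").total_qaly
               - run_strategy(params, "waitlist").total_qaly)
        assert abs(dq.mean() - det) < 3 * dq.std(ddof=1) / n**0.5


@pytest.fixture(scope="module")
def small_psa(params):
    return run_psa(params, PsaConfig(n_draws=400, seed=11))


class TestCeac:

    def test_wtp_zero_is_probability_cheaper(self, small_psa):
        cfg = PsaConfig(n_draws=400, seed=11, wtp_grid=[0.0])
        curve = ceac(small_psa, cfg)
        j = curve.strategies.index("guided")
        w = curve.strategies.index("waitlist")
        frac_cheaper = np.mean(small_psa.costs[:, j] < small_psa.costs[:, w])
        assert curve.probability[0, j] == pytest.approx(frac_cheaper, abs=1e-12)

    def test_multiway_partition(self, small_psa):
        cfg = PsaConfig(n_draws=400, seed=11, comparison_mode="multiway")
        curve = ceac(small_psa, cfg)
        assert np.allclose(curve.probability.sum(axis=1), 1.0, atol=1e-9)
        assert (curve.probability >= 0).all()

    def test_empty_grid_rejected(self, small_psa, params):
        with pytest.raises(ValidationError):
            ceac(small_psa, PsaConfig(n_draws=1, wtp_grid=[]))

    def test_monotone_for_costlier_more_effective(self, params):
        """With positive mean incremental cost and QALY, the pairwise CEAC
        rises with willingness to pay (checked on the built-in set)."""
        psa = run_psa(params, PsaConfig(n_draws=600, seed=3))
        cfg = PsaConfig(n_draws=600, seed=3,
                        wtp_grid=[0, 10_000, 30_000, 60_000, 120_000])
        curve = ceac(psa, cfg)
        j = curve.strategies.index("guided")
        probs = curve.probability[:, j]
        assert (np.diff(probs) >= -0.02).all()  # small MC wiggle allowed
        assert probs[-1] > probs[0]

    def test_default_grid_contains_threshold(self):
        assert 30_000.0 in default_wtp_grid()


class TestCePlane:
    def test_quadrants_partition(self, params):
        psa = run_psa(params, PsaConfig(n_draws=300, seed=21))
        q = quadrant_fractions(psa, "guided")
        assert sum(q.values()) == pytest.approx(1.0, abs=1e-12)
        assert q["NE"] == ne_quadrant_fraction(psa, "guided")

    def test_dominated_draws_give_zero(self):
        psa = PsaResult(strategies=["a", "waitlist"],
                        costs=np.array([[5.0, 1.0], [6.0, 2.0]]),
                        qalys=np.array([[1.0, 2.0], [1.0, 3.0]]),
                        seed=0, perspective="healthcare")
        assert ne_quadrant_fraction(psa, "a") == 0.0
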