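"""Damage engine: Weibull pit field, damage kinetics, removal/inheritance,
mass accounting and the time integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from pitcorr.model import (
    EXPOSED,
    INTERIOR,
    REMOVED,
    MassLossCurve,
    NonTerminationError,
    PitParams,
    compute_mass_loss,
    damage_increment,
    init_state,
    remove_and_inherit,
    sample_lambda,
    simulate,
    weibull_interval_prob,
    weibull_pdf,
)

from conftest import make_box_mesh

OPT_GAMMA, OPT_PSI = 2.74898, 2.60477

shapes = st.floats(min_value=0.2, max_value=8.0, allow_nan=False)


class TestPitParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gamma=0.0, psi=1, beta=1, Ku=0.1),
            dict(gamma=1, psi=-1, beta=1, Ku=0.1),
            dict(gamma=1, psi=1, beta=-0.1, Ku=0.1),
            dict(gamma=1, psi=1, beta=1, Ku=-0.1),
            dict(gamma=1, psi=1, beta=1, Ku=0.1, delta_u=0.0),
            dict(gamma=1, psi=1, beta=1, Ku=0.1, mode="melting"),
        ],
    )
    def test_constructor_validates(self, kwargs):
        with pytest.raises(ValueError):
            PitParams(**kwargs)

    def test_default_rate_reduces_to_ku_lambda(self):
        p = PitParams(gamma=1, psi=1, beta=1, Ku=0.25)
        assert p.damage_rate(2.0) == pytest.approx(0.5)

    def test_delta_u_scales_rate(self):
        p = PitParams(gamma=1, psi=1, beta=1, Ku=0.2, delta_u=0.1, Le=0.5)
        assert p.damage_rate(1.0) == pytest.approx(0.04)


class TestWeibull:
    @pytest.mark.parametrize(
        "gamma,psi", [(1.0, 1.0), (2.0, 0.5), (OPT_GAMMA, OPT_PSI), (0.7, 3.0)]
    )
    def test_pdf_matches_reference_distribution(self, gamma, psi):
        x = np.linspace(0.01, 10, 50)
        np.testing.assert_allclose(
            weibull_pdf(x, gamma, psi),
            stats.weibull_min.pdf(x, c=gamma, scale=psi),
            rtol=1e-12,
        )

    def test_pdf_zero_below_origin_and_exponential_at_origin(self):
        assert weibull_pdf(-1.0, 2.0, 1.0) == 0.0
        assert weibull_pdf(0.0, 1.0, 1.0) == 1.0

    def test_pdf_integrates_to_one_at_calibrated_shapes(self):
        val, err = integrate.quad(lambda x: weibull_pdf(x, OPT_GAMMA, OPT_PSI), 0, 50)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_interval_prob_total_and_degenerate(self):
        assert weibull_interval_prob(0, np.inf, 2.0, 1.5) == pytest.approx(1.0)
        assert weibull_interval_prob(1.3, 1.3, 2.0, 1.5) == 0.0

    def test_interval_prob_closed_form_example(self):
        # quadrature of the density agrees with the survival-function difference
        expected = np.exp(-1.0) - np.exp(-4.0)
        assert weibull_interval_prob(1, 2, 2.0, 1.0) == pytest.approx(expected)
        quad, _ = integrate.quad(lambda x: weibull_pdf(x, 2.0, 1.0), 1, 2)
        assert quad == pytest.approx(expected, abs=1e-10)

    def test_interval_prob_rejects_reversed_bounds(self):
        with pytest.raises(ValueError):
            weibull_interval_prob(2, 1, 2.0, 1.0)
        with pytest.raises(ValueError):
            weibull_interval_prob(0, 1, -1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-5, 10), b=st.floats(-5, 10), gamma=shapes, psi=shapes)
    def test_interval_prob_is_a_probability(self, a, b, gamma, psi):
        lo, hi = min(a, b), max(a, b)
        p = weibull_interval_prob(lo, hi, gamma, psi)
        assert 0.0 <= p <= 1.0
        # monotone in the upper bound
        assert weibull_interval_prob(lo, hi + 1.0, gamma, psi) >= p - 1e-15


class TestSampleLambda:
    def test_zero_draws(self):
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1)
        assert sample_lambda(0, p, np.random.default_rng(0)).size == 0

    def test_exponential_mean(self):
        p = PitParams(gamma=1.0, psi=1.0, beta=1, Ku=0.1)
        x = sample_lambda(100_000, p, np.random.default_rng(1))
        se = 1.0 / np.sqrt(x.size)  # exponential(1): sd = mean = 1
        assert abs(x.mean() - 1.0) < 3 * se

    def test_ks_against_closed_form_cdf(self):
        p = PitParams(gamma=OPT_GAMMA, psi=OPT_PSI, beta=1, Ku=0.1)
        x = sample_lambda(100_000, p, np.random.default_rng(2))
        assert np.all(x >= 0)
        res = stats.kstest(x, stats.weibull_min(c=OPT_GAMMA, scale=OPT_PSI).cdf)
        assert res.pvalue > 0.01

    def test_reproducible_under_seed(self):
        p = PitParams(gamma=2, psi=2, beta=1, Ku=0.1)
        a = sample_lambda(100, p, np.random.default_rng(7))
        b = sample_lambda(100, p, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestInitState:
    def test_single_element_mesh(self):
        mesh = make_box_mesh(1, 1, 1)
        st_ = init_state(mesh, PitParams(gamma=2, psi=1, beta=1, Ku=0.1, seed=5))
        assert st_.status[0] == EXPOSED and st_.lambda_p[0] > 0 and st_.dP[0] == 0

    def test_uniform_mode_pins_lambda_to_one(self):
        mesh = make_box_mesh(4, 4, 4)
        st_ = init_state(mesh, PitParams(gamma=2, psi=1, beta=1, Ku=0.1, mode="uniform"))
        exp = st_.status == EXPOSED
        assert np.all(st_.lambda_p[exp] == 1.0)
        assert np.all(np.isnan(st_.lambda_p[~exp]))

    def test_interior_untouched_and_seed_reproducible(self, coupon_3600):
        p = PitParams(gamma=OPT_GAMMA, psi=OPT_PSI, beta=5.1, Ku=0.1005, seed=11)
        a = init_state(coupon_3600, p)
        b = init_state(coupon_3600, p)
        np.testing.assert_array_equal(a.lambda_p, b.lambda_p)
        assert np.all(a.status[~coupon_3600.boundary] == INTERIOR)
        assert np.all(np.isnan(a.lambda_p[~coupon_3600.boundary]))
        assert np.all(a.dP == 0)


class TestDamageIncrement:
    def test_direct_rate_evaluation(self):
        mesh = make_box_mesh(1, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1005, mode="uniform").bind(mesh)
        st_ = init_state(mesh, p)
        out = damage_increment(st_, p, dt=1.0)
        assert out.dP[0] == pytest.approx(0.1005)
        assert out.time == pytest.approx(1.0)
        assert st_.dP[0] == 0.0  # input untouched

    def test_zero_lambda_never_corrodes(self):
        mesh = make_box_mesh(1, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.5).bind(mesh)
        st_ = init_state(mesh, p)
        st_.lambda_p[0] = 0.0
        out = damage_increment(st_, p, dt=1000.0)
        assert out.dP[0] == 0.0

    def test_damage_caps_at_one_and_only_exposed_evolve(self):
        mesh = make_box_mesh(3, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1, mode="uniform").bind(mesh)
        st_ = init_state(mesh, p, exposed=np.array([0]))
        out = damage_increment(st_, p, dt=1e4)
        assert out.dP[0] == 1.0 and np.all(out.dP[1:] == 0.0)

    def test_rejects_nonpositive_dt(self):
        mesh = make_box_mesh(1, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1).bind(mesh)
        with pytest.raises(ValueError):
            damage_increment(init_state(mesh, p), p, dt=0.0)


class TestRemoveAndInherit:
    def _bar(self, beta, lam0=1.0, mode="pitting"):
        mesh = make_box_mesh(3, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=beta, Ku=0.1, mode=mode).bind(mesh)
        st_ = init_state(mesh, p, exposed=np.array([0]))
        st_.lambda_p[0] = lam0
        return mesh, p, st_

    def test_inheritance_scales_by_beta(self):
        mesh, p, st_ = self._bar(beta=5.1, lam0=0.5)
        st_.dP[0] = 1.0
        out = remove_and_inherit(st_, mesh, p)
        assert out.status[0] == REMOVED
        assert out.lambda_p[1] == pytest.approx(5.1 * 0.5)
        assert out.status[1] == EXPOSED and out.status[2] == INTERIOR

    def test_identity_inheritance_with_unit_beta(self):
        mesh, p, st_ = self._bar(beta=1.0, lam0=0.73)
        st_.dP[0] = 1.0
        out = remove_and_inherit(st_, mesh, p)
        assert out.lambda_p[1] == pytest.approx(0.73)

    def test_geometric_acceleration_along_a_bar(self):
        mesh, p, st_ = self._bar(beta=2.0, lam0=1.0)
        st_.dP[0] = 1.0
        st_ = remove_and_inherit(st_, mesh, p)
        assert st_.lambda_p[1] == pytest.approx(2.0)
        st_.dP[1] = 1.0
        st_ = remove_and_inherit(st_, mesh, p)
        assert st_.lambda_p[2] == pytest.approx(4.0)
        assert list(st_.status) == [REMOVED, REMOVED, EXPOSED]

    def test_competing_donors_take_the_max(self):
        mesh = make_box_mesh(3, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=2.0, Ku=0.1).bind(mesh)
        st_ = init_state(mesh, p, exposed=np.array([0, 2]))
        st_.lambda_p[0], st_.lambda_p[2] = 0.3, 0.9
        st_.dP[[0, 2]] = 1.0
        out = remove_and_inherit(st_, mesh, p)
        assert out.lambda_p[1] == pytest.approx(2.0 * 0.9)

    def test_existing_lambda_is_never_lowered(self):
        mesh, p, st_ = self._bar(beta=0.5, lam0=1.0)
        st_.lambda_p[1] = 3.0
        st_.status[1] = EXPOSED
        st_.dP[0] = 1.0
        out = remove_and_inherit(st_, mesh, p)
        assert out.lambda_p[1] == 3.0

    def test_uniform_mode_inherits_unity(self):
        mesh, p, st_ = self._bar(beta=5.1, mode="uniform")
        st_.dP[0] = 1.0
        out = remove_and_inherit(st_, mesh, p)
        assert out.lambda_p[1] == 1.0


class TestMassLoss:
    def test_fresh_zero_and_all_removed_hundred(self):
        mesh = make_box_mesh(2, 2, 2)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1).bind(mesh)
        st_ = init_state(mesh, p)
        assert compute_mass_loss(st_, mesh) == 0.0
        st_.status[:] = REMOVED
        st_.dP[:] = 1.0
        for acct in ("partial", "removed_only"):
            assert compute_mass_loss(st_, mesh, acct) == 100.0

    def test_three_of_ten_removed_is_thirty_percent(self):
        mesh = make_box_mesh(10, 1, 1)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1).bind(mesh)
        st_ = init_state(mesh, p)
        st_.status[:3] = REMOVED
        st_.dP[:3] = 1.0
        assert compute_mass_loss(st_, mesh, "removed_only") == pytest.approx(30.0)
        assert compute_mass_loss(st_, mesh, "partial") == pytest.approx(30.0)


class TestSimulate:
    def test_uniform_front_speed_on_masked_bar(self):
        # one end face exposed: the recession front eats one element per
        # Le/(delta_u*Ku) hours, so N elements take N/Ku hours (delta_u=Le)
        N, Ku = 8, 0.05
        mesh = make_box_mesh(1, 1, N)
        p = PitParams(gamma=2, psi=1, beta=1.0, Ku=Ku, mode="uniform")
        curve = simulate(mesh, p, mass_loss_target=100.0, exposed=np.array([0]))
        expected = N / Ku
        dt_step = 0.1 / Ku
        assert curve.times_h[-1] == pytest.approx(expected, abs=dt_step + 1e-9)
        # front consumes element k at ~ (k+1)/Ku hours
        t_half = curve.final_time_for(50.0)
        assert t_half == pytest.approx(expected / 2, abs=dt_step + 1e-9)

    def test_uniform_mode_synchronous_surface_death(self):
        mesh = make_box_mesh(4, 4, 2)
        p = PitParams(gamma=2, psi=1, beta=1.0, Ku=0.2, mode="uniform")
        curve = simulate(mesh, p, mass_loss_target=100.0)
        # every element is boundary-exposed here: all die at t = 1/Ku
        assert curve.times_h[-1] == pytest.approx(1 / 0.2, abs=0.1 / 0.2 + 1e-9)

    def test_curve_contract_monotone_and_reaches_target(self, coupon_3600):
        p = PitParams(gamma=2.6, psi=2.6, beta=5.1, Ku=0.1005, seed=4)
        curve = simulate(coupon_3600, p, mass_loss_target=89.27)
        assert np.all(np.diff(curve.mass_loss_pct) >= 0)
        assert curve.mass_loss_pct[-1] >= 89.27
        assert curve.mass_loss_pct[0] == 0.0 and curve.times_h[0] == 0.0

    def test_trajectory_reproducible_under_seed(self):
        mesh = make_box_mesh(5, 5, 3)
        p = PitParams(gamma=2.0, psi=1.5, beta=2.0, Ku=0.1, seed=9)
        c1 = simulate(mesh, p, mass_loss_target=90.0)
        c2 = simulate(mesh, p, mass_loss_target=90.0)
        np.testing.assert_array_equal(c1.times_h, c2.times_h)
        np.testing.assert_array_equal(c1.mass_loss_pct, c2.mass_loss_pct)

    @pytest.mark.parametrize("mode", ["uniform", "pitting"])
    def test_doubling_ku_halves_time_to_target(self, mode):
        mesh = make_box_mesh(5, 5, 3)
        times = {}
        for ku in (0.05, 0.1):
            p = PitParams(gamma=2.0, psi=1.5, beta=2.0, Ku=ku, seed=3, mode=mode)
            times[ku] = simulate(mesh, p, mass_loss_target=80.0).final_time_for(80.0)
        assert times[0.05] / times[0.1] == pytest.approx(2.0, rel=0.02)

    def test_zero_rate_target_raises_up_front(self):
        mesh = make_box_mesh(2, 2, 2)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.0)
        with pytest.raises(NonTerminationError):
            simulate(mesh, p, mass_loss_target=50.0)

    def test_beta_zero_stall_raises_mid_run(self):
        # the exposed shell corrodes, but inherited lambda = 0 freezes the rest
        mesh = make_box_mesh(1, 1, 5)
        p = PitParams(gamma=2, psi=1, beta=0.0, Ku=0.1, seed=2)
        with pytest.raises(NonTerminationError):
            simulate(mesh, p, mass_loss_target=99.0, exposed=np.array([0]))

    def test_t_end_run_records_requested_times(self):
        mesh = make_box_mesh(3, 3, 2)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.01, seed=1)
        rec = [0.0, 12.0, 24.0]
        curve = simulate(mesh, p, t_end=24.0, record_times=rec)
        for t in rec:
            assert np.any(np.isclose(curve.times_h, t))

    def test_exactly_one_stop_rule(self):
        mesh = make_box_mesh(2, 2, 2)
        p = PitParams(gamma=2, psi=1, beta=1, Ku=0.1)
        with pytest.raises(ValueError):
            simulate(mesh, p)
        with pytest.raises(ValueError):
            simulate(mesh, p, t_end=1.0, mass_loss_target=50.0)


class TestMassLossCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MassLossCurve(np.array([0.0, 1.0]), np.array([5.0, 1.0]))
        with pytest.raises(ValueError):
            MassLossCurve(np.array([0.0, 1.0]), np.array([0.0, 150.0]))

    def test_final_time_interpolates(self):
        c = MassLossCurve(np.array([0.0, 2.0, 4.0]), np.array([0.0, 50.0, 100.0]))
        assert c.final_time_for(75.0) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            c.final_time_for(101.0)
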