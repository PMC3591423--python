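"""Core steady-state survival mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

import platekin as pk
from platekin.models import age_grid, mean_realized_lifespan


def ls_curve_closed_form(law: pk.LognormalLaw, t):
    """Analytic survival curve for the pure lognormal-senescent case (r = 0).

    Uses the truncated-mean identity int_t^inf SF(u) du
    = mu Phi((m + s^2 - ln t)/s) - t Phi((m - ln t)/s).
    """
    t = np.asarray(t, dtype=float)
    m, s = law.m, law.s
    mu = law.mean
    with np.errstate(divide="ignore"):
        lt = np.log(np.where(t > 0, t, 1.0))
    upper = mu * stats.norm.cdf((m + s**2 - lt) / s) - t * stats.norm.cdf((m - lt) / s)
    return np.where(t > 0, upper / mu, 1.0)


class TestLognormalLaw:
    def test_moment_round_trip_exact_pairs(self):
        for mu, sigma in [(89.5, 28.2), (100.0, 25.0), (53.3, 11.3)]:
            law = pk.lognormal_from_moments(mu, sigma)
            mu2, sigma2 = pk.lognormal_to_moments(law)
            assert mu2 == pytest.approx(mu, abs=1e-10)
            assert sigma2 == pytest.approx(sigma, abs=1e-10)

    def test_log_params_match_published_moments(self):
        # (m, s) = (4.45, 0.307) corresponds to mean ~89.5 hr, s.d. ~28.2 hr
        law = pk.LognormalLaw(4.45, 0.307)
        mu, sigma = pk.lognormal_to_moments(law)
        assert mu == pytest.approx(89.5, rel=0.005)
        assert sigma == pytest.approx(28.2, rel=0.005)

    def test_degenerate_limit(self):
        law = pk.lognormal_from_moments(1.0, 1e-8)
        assert law.mean == pytest.approx(1.0, rel=1e-6)
        assert law.sd == pytest.approx(0.0, abs=1e-6)

    @given(mu=st.floats(10.0, 300.0), cv=st.floats(0.05, 0.6))
    @settings(max_examples=30, deadline=None)
    def test_moment_round_trip_property(self, mu, cv):
        law = pk.lognormal_from_moments(mu, cv * mu)
        mu2, sigma2 = pk.lognormal_to_moments(law)
        assert mu2 == pytest.approx(mu, rel=1e-10)
        assert sigma2 == pytest.approx(cv * mu, rel=1e-10)

    def test_pdf_normalized_on_standard_range(self):
        law = pk.LognormalLaw(4.45, 0.307)
        total, _ = quad(law.pdf, 0.0, math.exp(law.m + 6 * law.s))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pk.LognormalLaw(4.0, 0.0)
        with pytest.raises(ValueError):
            pk.lognormal_from_moments(-1.0, 10.0)
        with pytest.raises(ValueError):
            pk.DeltaLaw(0.0)


class TestSurvivalToAge:
    def test_no_death_at_age_zero(self, wt_dls_model):
        assert pk.survival_to_age(wt_dls_model, 0.0) == pytest.approx(1.0)

    def test_delta_closed_form(self):
        model = pk.LifespanModel(pk.DeltaLaw(100.0), 0.01)
        assert pk.survival_to_age(model, 50.0) == pytest.approx(math.exp(-0.5))
        assert pk.survival_to_age(model, 150.0) == 0.0

    def test_lognormal_median_without_random_loss(self):
        law = pk.LognormalLaw(4.5, 0.3)
        model = pk.LifespanModel(law, 0.0)
        assert pk.survival_to_age(model, math.exp(4.5)) == pytest.approx(0.5)

    def test_negative_age_rejected(self, wt_dls_model):
        with pytest.raises(ValueError):
            pk.survival_to_age(wt_dls_model, -1.0)

    @given(r=st.floats(0.0, 0.02))
    @settings(max_examples=20, deadline=None)
    def test_nonincreasing_and_bounded(self, r):
        model = pk.LifespanModel(pk.LognormalLaw(4.6, 0.25), r)
        ages = np.linspace(0.0, 400.0, 200)
        P = pk.survival_to_age(model, ages)
        assert np.all((0.0 <= P) & (P <= 1.0))
        assert np.all(np.diff(P) <= 1e-12)


class TestSteadyAgeDensity:
    def test_normalization(self, wt_dls_model):
        grid = age_grid(wt_dls_model)
        dens = pk.steady_age_density(wt_dls_model, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)

    def test_delta_no_loss_is_uniform(self):
        model = pk.LifespanModel(pk.DeltaLaw(120.0), 0.0)
        dens = pk.steady_age_density(model, np.array([10.0, 60.0, 110.0]))
        assert dens == pytest.approx(np.full(3, 1.0 / 120.0), rel=1e-3)

    def test_normalizer_is_f_over_r(self, wt_dls_model):
        # wild-type-like parameters: f ~ 0.31, r = 0.0038 -> normalizer ~ 82 hr
        f = pk.random_loss_fraction(wt_dls_model)
        assert f == pytest.approx(0.31, abs=0.005)
        theta = mean_realized_lifespan(wt_dls_model)
        assert theta == pytest.approx(f / wt_dls_model.r, rel=1e-12)
        # and it matches the quadrature of P
        grid = age_grid(wt_dls_model)
        P = pk.survival_to_age(wt_dls_model, grid)
        assert np.trapezoid(P, grid) == pytest.approx(theta, rel=1e-3)


class TestPopulationSurvivalCurve:
    def test_starts_at_one_and_vanishes(self, wt_dls_model):
        assert pk.population_survival_curve(wt_dls_model, 0.0) == pytest.approx(1.0)
        assert pk.population_survival_curve(wt_dls_model, 1e4) == 0.0

    def test_delta_limits(self):
        model = pk.LifespanModel(pk.DeltaLaw(100.0), 0.0)
        assert pk.population_survival_curve(model, 40.0) == pytest.approx(0.6)
        model_r = pk.LifespanModel(pk.DeltaLaw(100.0), 0.01)
        t = 40.0
        expected = (math.exp(-0.01 * t) - math.exp(-1.0)) / (1 - math.exp(-1.0))
        assert pk.population_survival_curve(model_r, t) == pytest.approx(expected)

    def test_monotone_nonincreasing(self, wt_dls_model):
        t = np.linspace(0.0, 300.0, 400)
        D = pk.population_survival_curve(wt_dls_model, t)
        assert np.all(np.diff(D) <= 1e-12)

    def test_ls_curve_matches_closed_form(self):
        """Trapezoid route vs the analytic truncated-mean formula (r = 0)."""
        law = pk.LognormalLaw(4.45, 0.307)
        model = pk.LifespanModel(law, 0.0)
        t = np.linspace(0.0, 250.0, 60)
        numeric = pk.population_survival_curve(model, t, grid_points=4000)
        analytic = ls_curve_closed_form(law, t)
        assert np.max(np.abs(numeric - analytic)) < 5e-5

    def test_dls_r0_reduces_to_ls(self):
        law = pk.LognormalLaw(4.6, 0.26)
        t = np.linspace(0.0, 300.0, 100)
        dls = pk.population_survival_curve(pk.LifespanModel(law, 0.0), t)
        ls = ls_curve_closed_form(law, t)
        assert np.max(np.abs(dls - ls)) < 1e-4

    def test_dls_small_s_approaches_dornhorst(self):
        T, r = 100.0, 0.005
        law = pk.LognormalLaw(math.log(T), 1e-4 * math.log(T))
        t = np.linspace(0.0, 140.0, 300)
        dls = pk.population_survival_curve(pk.LifespanModel(law, r), t,
                                           grid_points=4000)
        dorn = pk.population_survival_curve(pk.LifespanModel(pk.DeltaLaw(T), r), t)
        assert np.max(np.abs(dls - dorn)) < 1e-3


class TestRandomLossFraction:
    def test_zero_iff_no_random_loss(self, study_law):
        assert pk.random_loss_fraction(pk.LifespanModel(study_law, 0.0)) == 0.0
        assert pk.random_loss_fraction(pk.LifespanModel(pk.DeltaLaw(100.0), 0.0)) == 0.0

    def test_dornhorst_published_values(self):
        wt = pk.LifespanModel(pk.DeltaLaw(109.4), 0.0072)
        assert round(pk.random_loss_fraction(wt), 2) == 0.55
        bclx = pk.LifespanModel(pk.DeltaLaw(55.8), 0.0029)
        assert round(pk.random_loss_fraction(bclx), 2) == 0.15

    def test_dls_published_value_and_quad_crosscheck(self, wt_dls_model):
        f = pk.random_loss_fraction(wt_dls_model)
        assert round(f, 2) == 0.31
        law, r = wt_dls_model.law, wt_dls_model.r
        f_quad = 1.0 - quad(lambda l: math.exp(-r * l) * law.pdf(l),
                            0.0, math.exp(law.m + 8 * law.s))[0]
        assert f == pytest.approx(f_quad, abs=1e-4)

    def test_delta_general_quadrature_equals_closed_form(self):
        # E[e^{-rL}] for a point mass at T is e^{-rT} exactly
        for T, r in [(109.4, 0.0072), (55.8, 0.0029), (201.3, 0.0035)]:
            model = pk.LifespanModel(pk.DeltaLaw(T), r)
            assert pk.random_loss_fraction(model) == pytest.approx(
                1.0 - math.exp(-r * T), abs=1e-9)

    @given(r=st.floats(1e-4, 0.03))
    @settings(max_examples=20, deadline=None)
    def test_strictly_increasing_in_r(self, r, study_law):
        f1 = pk.random_loss_fraction(pk.LifespanModel(study_law, r))
        f2 = pk.random_loss_fraction(pk.LifespanModel(study_law, r * 1.5))
        assert 0.0 < f1 < f2 < 1.0


class TestSteadyState:
    def test_ls_wild_type_production_rate(self):
        model = pk.LifespanModel(pk.lognormal_from_moments(89.5, 28.2), 0.0)
        ss = pk.steady_state(model, 1183.0)
        assert ss.S == pytest.approx(13.2, abs=0.05)

    def test_dornhorst_bclx_loss_rate(self):
        model = pk.LifespanModel(pk.DeltaLaw(55.8), 0.0029)
        ss = pk.steady_state(model, 847.0)
        assert ss.R == pytest.approx(59.0, abs=0.5)

    def test_dls_wild_type_loss_rate(self, wt_dls_model):
        ss = pk.steady_state(wt_dls_model, 1183.0)
        assert ss.R == pytest.approx(108.0, abs=0.5)

    @given(r=st.floats(1e-4, 0.02), N=st.floats(500.0, 2000.0))
    @settings(max_examples=25, deadline=None)
    def test_conservation_identities(self, r, N, study_law):
        ss = pk.steady_state(pk.LifespanModel(study_law, r), N)
        # f = R/S with both per day; N = S * mean realized lifespan
        assert ss.f == pytest.approx(ss.R / (ss.S * 24.0), abs=1e-9)
        assert N == pytest.approx(ss.S * ss.mean_realized_lifespan, abs=1e-9)

    def test_r_zero_uses_mean_lifespan_limit(self, study_law):
        ss = pk.steady_state(pk.LifespanModel(study_law, 0.0), 1000.0)
        assert ss.mean_realized_lifespan == pytest.approx(100.0)
        assert ss.f == 0.0 and ss.R == 0.0

    def test_invalid_count(self, wt_dls_model):
        with pytest.raises(ValueError):
            pk.steady_state(wt_dls_model, 0.0)


class TestModelDescriptor:
    @pytest.mark.parametrize("model", [
        pk.LifespanModel(pk.LognormalLaw(4.45, 0.307), 0.0),
        pk.LifespanModel(pk.DeltaLaw(109.4), 0.0072),
        pk.LifespanModel(pk.LognormalLaw(4.57, 0.258), 0.0038),
    ])
    def test_json_round_trip(self, model):
        again = pk.model_from_json(pk.model_to_json(model))
        assert again == model
        assert again.kind == model.kind

    def test_moment_parameterization_accepted(self):
        model = pk.model_from_dict({"model": "DLS", "mu": 99.5, "sigma": 26.1,
                                    "r": 0.0038})
        assert model.law.mean == pytest.approx(99.5)

    def test_kind_is_derivable(self, study_law):
        assert pk.LifespanModel(study_law, 0.0).kind == "LS"
        assert pk.LifespanModel(study_law, 0.001).kind == "DLS"
        assert pk.LifespanModel(pk.DeltaLaw(100.0), 0.001).kind == "DORNHORST"

    def test_bad_descriptors_rejected(self):
        with pytest.raises(ValueError):
            pk.model_from_dict({"model": "GAMMA", "mu": 100, "sigma": 25})
        with pytest.raises(ValueError):
            pk.model_from_dict({"model": "LS", "mu": 100, "sigma": 25, "r": 0.01})
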