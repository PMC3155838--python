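"""Closed-form concentration models against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.integrate import quad

from popkdesign import (
    AS_TO_DHA,
    BATEMAN,
    BatemanParams,
    CovariateProfile,
    DostParams,
    ScalingConfig,
    bateman_concentration,
    dost_concentration,
    maturation_multiplier,
    scale_parameters,
)
from popkdesign.structural import (
    bateman_concentration_grad_arr,
    bateman_concentration_arr,
    dost_concentration_grad_arr,
)

ADULT = dict(ka=0.82, cl_f=47.5, v_f=32.1, tlag=0.21)
DOSE = 200.0 * AS_TO_DHA


def ode_oracle(p: BatemanParams, dose, t_eval):
    """Numerically integrate the absorption/disposition ODE system."""
    k = p.cl_f / p.v_f

    def rhs(t, z):
        return [-p.ka * z[0], p.ka * z[0] - k * z[1]]

    sol = solve_ivp(rhs, (p.tlag, max(t_eval) + 1.0), [dose, 0.0],
                    t_eval=t_eval, rtol=1e-12, atol=1e-14)
    return sol.y[1] / p.v_f


class TestBateman:
    def test_zero_dose_gives_zero(self):
        p = BatemanParams(**ADULT)
        assert bateman_concentration(p, 0.0, 2.0) == 0.0

    def test_pre_lag_is_zero(self):
        p = BatemanParams(**ADULT)
        assert bateman_concentration(p, DOSE, 0.1) == 0.0

    def test_matches_ode_integration(self):
        p = BatemanParams(**ADULT)
        t = np.array([0.5, 1.0, 2.0, 6.0])
        c = bateman_concentration(p, DOSE, t)
        ref = ode_oracle(p, DOSE, t)
        assert np.allclose(c, ref, rtol=1e-8)

    @pytest.mark.parametrize("ka,cl,v", [
        (0.76, 44.6, 24.6), (0.87, 50.4, 39.6), (0.82, 47.5, 32.1),
        (1.19, 88.5, 232.0),
    ])
    def test_ode_agreement_across_ci_grid(self, ka, cl, v):
        p = BatemanParams(ka=ka, cl_f=cl, v_f=v, tlag=0.21)
        t = np.linspace(0.3, 12.0, 25)
        assert np.allclose(bateman_concentration(p, DOSE, t),
                           ode_oracle(p, DOSE, t), rtol=1e-8)

    def test_linear_in_dose(self):
        p = BatemanParams(**ADULT)
        t = np.linspace(0.25, 10, 40)
        assert np.allclose(bateman_concentration(p, 2 * DOSE, t),
                           2 * bateman_concentration(p, DOSE, t), rtol=1e-12)

    def test_auc_equals_dose_over_clearance(self):
        p = BatemanParams(**ADULT)
        auc, err = quad(lambda t: float(bateman_concentration(p, DOSE, t)),
                        0, np.inf, limit=200)
        assert auc == pytest.approx(DOSE / p.cl_f, rel=1e-8)

    def test_converges_to_dost_as_rates_merge(self):
        k = 0.99
        v = 46.3
        pb = BatemanParams(ka=k * (1 + 1e-7), cl_f=k * v, v_f=v, tlag=0.21)
        pd = DostParams(k=k, v_f=v, tlag=0.21)
        t = np.linspace(0.3, 10, 30)
        cb = bateman_concentration(pb, DOSE, t)
        cd = dost_concentration(pd, DOSE, t)
        assert np.allclose(cb, cd, rtol=1e-5)

    def test_analytic_gradient_matches_finite_differences(self):
        th = [0.82, 47.5, 32.1, 0.21]
        t = np.array([0.3, 0.6, 1.5, 3.0, 6.0, 12.0])
        _, g = bateman_concentration_grad_arr(*th, DOSE, t)
        for j in range(4):
            h = 1e-6 * th[j]
            up = list(th); up[j] += h
            dn = list(th); dn[j] -= h
            fd = (bateman_concentration_arr(*up, DOSE, t)
                  - bateman_concentration_arr(*dn, DOSE, t)) / (2 * h)
            assert np.allclose(g[:, j], fd, rtol=1e-6, atol=1e-12)


class TestDost:
    def test_peak_at_lag_plus_inverse_rate(self):
        p = DostParams(k=0.99, v_f=46.3, tlag=0.21)
        t = np.linspace(0, 6, 60001)
        c = dost_concentration(p, 200.0, t)
        assert t[np.argmax(c)] == pytest.approx(0.21 + 1 / 0.99, abs=2e-4)

    def test_boundary_zero_at_lag(self):
        p = DostParams(k=0.99, v_f=46.3, tlag=0.21)
        assert dost_concentration(p, 200.0, 0.21) == 0.0

    def test_gradient_matches_finite_differences(self):
        th = [0.99, 46.3, 0.21]
        t = np.array([0.3, 1.0, 2.5, 7.0])
        _, g = dost_concentration_grad_arr(*th, 200.0, t)
        from popkdesign.structural import dost_concentration_arr
        for j in range(3):
            h = 1e-6 * th[j]
            up = list(th); up[j] += h
            dn = list(th); dn[j] -= h
            fd = (dost_concentration_arr(*up, 200.0, t)
                  - dost_concentration_arr(*dn, 200.0, t)) / (2 * h)
            assert np.allclose(g[:, j], fd, rtol=1e-6, atol=1e-12)


class TestScaling:
    def test_identity_at_reference(self):
        adult = BatemanParams(**ADULT)
        cov = CovariateProfile(weight=50.0, age=30.0)
        out = scale_parameters(adult, cov, ScalingConfig(w_ref=50.0))
        assert out.cl_f == pytest.approx(adult.cl_f, rel=1e-12)
        assert out.v_f == pytest.approx(adult.v_f, rel=1e-12)

    def test_allometric_formula_at_70kg(self):
        adult = BatemanParams(**ADULT)
        cov = CovariateProfile(weight=70.0, age=30.0)
        out = scale_parameters(adult, cov, ScalingConfig(w_ref=50.0))
        assert out.cl_f == pytest.approx(47.5 * (70 / 50) ** 0.75, rel=1e-12)
        assert out.v_f == pytest.approx(32.1 * (70 / 50), rel=1e-12)
        assert out.ka == adult.ka and out.tlag == adult.tlag

    @pytest.mark.parametrize("form", ["exponential", "hill"])
    def test_maturation_monotone_and_bounded(self, form):
        cfg = ScalingConfig(maturation_form=form)
        ages = np.linspace(0.0, 40.0, 400)
        mf = maturation_multiplier(ages, cfg)
        assert np.all(np.diff(mf) >= -1e-15)
        assert np.all(mf <= 1.0) and mf[-1] > 0.99

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            CovariateProfile(weight=0.0)


@settings(max_examples=30, deadline=None)
@given(
    ka=st.floats(0.3, 2.0), cl=st.floats(20.0, 120.0), v=st.floats(15.0, 300.0),
    tlag=st.floats(0.0, 0.6), t=st.floats(0.0, 24.0),
)
def test_concentration_nonnegative_and_finite(ka, cl, v, tlag, t):
    p = BatemanParams(ka=ka, cl_f=cl, v_f=v, tlag=tlag)
    c = float(bateman_concentration(p, DOSE, t))
    assert np.isfinite(c) and c >= 0.0
    if t <= tlag:
        assert c == 0.0
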