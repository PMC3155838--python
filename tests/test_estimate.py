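"""Mixed-effects estimator: exact-likelihood oracles and %RSE arithmetic."""

import numpy as np
import pytest
from dataclasses import replace

from popkdesign import (
    DOST,
    Design,
    DesignConstraints,
    Group,
    build_population_model,
    empirical_rse,
    fit,
    simulate_trial,
)
from popkdesign.estimate import perturbed_init


class TestEmpiricalRSE:
    def test_hand_arithmetic(self):
        assert empirical_rse([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_constant_vector_is_zero(self):
        assert empirical_rse([5.0] * 20) == 0.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(1.0, 0.3, 100)
        # spreadsheet-style recomputation
        n = len(v)
        mean = sum(v) / n
        sd = (sum((x - mean) ** 2 for x in v) / (n - 1)) ** 0.5
        med = sorted(v)[49:51]
        med = (med[0] + med[1]) / 2
        assert empirical_rse(v) == pytest.approx(100 * sd / med, rel=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            empirical_rse([1.0])

    def test_zero_median_flagged_as_nan(self):
        assert np.isnan(empirical_rse([-1.0, 0.0, 1.0]))


def _single_eta_model(sig_prop=0.15, sig_add=0.02, bsv=25.0):
    """Dost model, one random effect on V/F — small enough for an exact
    quadrature oracle of the marginal likelihood."""
    return build_population_model(
        DOST, theta={"k": 1.0, "v_f": 40.0, "tlag": 0.0},
        bsv_cv={"v_f": bsv}, sigma_prop=sig_prop, sigma_add=sig_add,
        fixed_theta=("tlag",), label="oneeta",
    )


def _gh_m2ll(pm, ds, n_nodes=80):
    """Exact marginal -2LL by Gauss-Hermite quadrature over the single eta."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    j = pm.param_names.index("v_f")
    omega = np.sqrt(pm.omega[j, j])
    total = 0.0
    for _, ids, times, y, dose, wt, age in ds.subject_blocks():
        for i in range(len(ids)):
            th = np.tile(pm.theta, (n_nodes, 1))
            th[:, j] *= np.exp(nodes * omega)
            f = pm.structural.conc(th[:, None, :], dose[i], times[None, :])
            rv = pm.sigma_add**2 + pm.sigma_prop**2 * f**2
            ll = -0.5 * np.sum((y[i] - f) ** 2 / rv + np.log(2 * np.pi * rv),
                               axis=1)
            m = ll.max()
            total += -2.0 * (m + np.log(np.sum(weights * np.exp(ll - m))
                                        / np.sqrt(2 * np.pi)))
    return total


class TestObjectiveOracles:
    @pytest.mark.parametrize("theta_mult", [1.0, 1.2, 0.85])
    def test_laplace_objective_tracks_exact_quadrature(self, theta_mult):
        # moderate variability: Laplace error is a fraction of a -2LL unit
        # per subject, far below any structural mistake (a lost 2*pi term
        # alone would shift ~1.8 per subject)
        pm = _single_eta_model()
        design = Design(groups=[Group(20, np.array([0.5, 1.5, 4.0, 8.0]))],
                        constraints=DesignConstraints())
        ds = simulate_trial(pm, design, seed=21)
        pm_at = pm.with_theta(pm.theta * np.array([theta_mult, theta_mult, 1.0]))
        fr = fit(ds, pm_at, maxiter=0)          # objective at the given point
        exact = _gh_m2ll(pm_at, ds)
        assert fr.objective == pytest.approx(exact, abs=0.3 * 20)

    def test_laplace_tight_at_small_variability(self):
        pm = _single_eta_model(sig_prop=0.05, sig_add=0.01, bsv=8.0)
        design = Design(groups=[Group(20, np.array([0.5, 1.5, 4.0, 8.0]))])
        ds = simulate_trial(pm, design, seed=22)
        fr = fit(ds, pm, maxiter=0)
        assert fr.objective == pytest.approx(_gh_m2ll(pm, ds), abs=1.0)

    def test_noise_free_rich_data_recovers_theta_exactly(self):
        pm = _single_eta_model(sig_prop=1e-6, sig_add=0.0, bsv=25.0)
        pm0 = replace(pm)
        pm0.omega = np.zeros((3, 3))
        pm0.est_om_diag = np.zeros(3, bool)
        design = Design(groups=[Group(12, np.linspace(0.5, 12, 12))])
        ds = simulate_trial(pm0, design, seed=5)
        init = replace(pm0)
        init.theta = pm0.theta * np.array([1.15, 0.9, 1.0])
        init.est_sigma_prop = False
        fr = fit(ds, init)
        assert fr.estimates["k"] == pytest.approx(1.0, rel=1e-3)
        assert fr.estimates["v_f"] == pytest.approx(40.0, rel=1e-3)

    def test_recovery_within_sampling_error_at_moderate_noise(self):
        pm = _single_eta_model(sig_prop=0.15, sig_add=0.02, bsv=30.0)
        design = Design(groups=[Group(40, np.array([0.5, 1.0, 2.5, 6.0, 10.0]))])
        ds = simulate_trial(pm, design, seed=17)
        fr = fit(ds, perturbed_init(pm))
        assert fr.converged
        assert fr.estimates["k"] == pytest.approx(1.0, rel=0.1)
        assert fr.estimates["v_f"] == pytest.approx(40.0, rel=0.1)
        assert fr.estimates["om2_v_f"] == pytest.approx(0.09, rel=0.6)

    def test_zero_bsv_data_gives_near_zero_variance_estimate(self):
        pm = _single_eta_model(sig_prop=0.1, sig_add=0.01, bsv=20.0)
        design = Design(groups=[Group(30, np.array([0.5, 1.5, 4.0, 8.0]))])
        ds = simulate_trial(pm, design, seed=9, omega_scale=0.0)
        fr = fit(ds, perturbed_init(pm))
        # estimated variance collapses toward the boundary
        assert fr.estimates["om2_v_f"] < 0.005

    def test_foce_and_laplace_objectives_agree_for_small_variability(self):
        """Both marginal approximations coincide (and match the exact
        quadrature) when variability is small; evaluated at fixed points so
        the check is independent of either optimiser's path."""
        pm = _single_eta_model(sig_prop=0.05, sig_add=0.01, bsv=8.0)
        design = Design(groups=[Group(25, np.array([0.5, 1.5, 4.0, 8.0]))])
        ds = simulate_trial(pm, design, seed=13)
        # at the generating parameters all three agree closely
        a = fit(ds, pm, maxiter=0, method="laplace").objective
        b = fit(ds, pm, maxiter=0, method="foce").objective
        exact = _gh_m2ll(pm, ds)
        assert a == pytest.approx(exact, abs=2.0)
        assert b == pytest.approx(exact, abs=2.0)
        # far from the data (inflated start) the Laplace form still tracks
        # the exact marginal; the linearised form degrades there
        init = perturbed_init(pm)
        a = fit(ds, init, maxiter=0, method="laplace").objective
        b = fit(ds, init, maxiter=0, method="foce").objective
        exact = _gh_m2ll(init, ds)
        assert a == pytest.approx(exact, abs=5.0)
        assert b == pytest.approx(exact, rel=0.05)

    def test_nonconvergence_never_raises(self):
        pm = _single_eta_model()
        design = Design(groups=[Group(4, np.array([0.5, 1.5]))])
        ds = simulate_trial(pm, design, seed=2)
        fr = fit(ds, perturbed_init(pm), maxiter=1)
        assert isinstance(fr.converged, bool)


class TestSimEstReporting:
    def test_single_replicate_flags_insufficient_data(self, adult_model,
                                                      adult_design):
        from popkdesign import sim_est

        pm = _single_eta_model()
        design = Design(groups=[Group(8, np.array([0.5, 1.5, 4.0, 8.0]))])
        rep = sim_est(pm, design, n_replicates=1, seed=3)
        assert rep.n_converged <= 1
        assert rep.table.empty
        assert "insufficient" in rep.message
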