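"""Population Fisher information: closed-form oracles and design metrics."""

import numpy as np
import pytest

from popkdesign import (
    CovariateProfile,
    Design,
    DesignConstraints,
    FIMResult,
    Group,
    PopulationModel,
    compound_objective,
    d_criterion,
    efficiency,
    individual_fim,
    population_fim,
)
from popkdesign.fim import fim_batch
from popkdesign.population import build_competing_set
from popkdesign.structural import StructuralModel


class LinearModel(StructuralModel):
    """f(t) = theta1 + theta2*t — classical linear-regression special case."""

    param_names = ("a", "b")
    name = "linear"

    def conc(self, theta, dose, t):
        a = np.asarray(theta, float)[..., 0]
        b = np.asarray(theta, float)[..., 1]
        return a + b * np.asarray(t, float)

    def conc_grad(self, theta, dose, t):
        t = np.asarray(t, float)
        f = self.conc(theta, dose, t)
        g = np.stack([np.ones_like(t), t], axis=-1)
        return f, np.broadcast_to(g, f.shape + (2,)).copy()

    def scale_factors(self, weight, age, cfg):
        one = np.ones(np.broadcast_shapes(np.shape(weight), np.shape(age)))
        return np.stack([one, one], axis=-1)


def _linear_pm(sigma=0.5):
    return PopulationModel(
        structural=LinearModel(), theta=np.array([1.0, 2.0]),
        omega=np.zeros((2, 2)), sigma_prop=0.0, sigma_add=sigma,
        est_om_diag=np.zeros(2, bool), est_sigma_prop=False,
        est_sigma_add=False,
    )


class TestLinearOracle:
    def test_fim_equals_xtx_over_sigma2(self):
        sigma = 0.5
        times = np.array([1.0, 2.0, 4.0, 8.0])
        pm = _linear_pm(sigma)
        fr = individual_fim(pm, CovariateProfile(weight=50), dose=1.0, times=times)
        X = np.column_stack([np.ones_like(times), times])
        assert np.allclose(fr.matrix, X.T @ X / sigma**2, rtol=1e-8)

    def test_classical_nonlinear_regression_limit(self, adult_model):
        """With no random effects and additive error only, the population
        FIM reduces to the weighted sensitivity cross-product."""
        from dataclasses import replace

        pm = replace(adult_model, sigma_prop=1e-12, sigma_add=0.1)
        pm.omega = np.zeros((4, 4))
        pm.est_om_diag = np.zeros(4, bool)
        pm.est_om_offdiag = ()
        pm.est_sigma_prop = False
        times = np.array([0.5, 1.0, 3.0, 6.0])
        fr = individual_fim(pm, CovariateProfile(weight=50), 147.9, times)
        _, G = pm.structural.conc_grad(pm.theta, 147.9, times)
        J = G[:, :3]  # free thetas (lag fixed)
        assert np.allclose(fr.matrix, J.T @ J / 0.1**2, rtol=1e-6)


class TestFIMStructure:
    def test_symmetry_and_near_psd(self, adult_model, adult_design):
        fr = population_fim(adult_model, adult_design)
        assert np.allclose(fr.matrix, fr.matrix.T, atol=1e-12)
        assert np.linalg.eigvalsh(fr.matrix).min() >= -1e-10 * np.abs(
            np.linalg.eigvalsh(fr.matrix)).max()

    def test_doubling_subjects_doubles_information(self, adult_model, adult_design):
        fr1 = population_fim(adult_model, adult_design)
        d2 = Design(groups=[Group(n_subjects=120, times=adult_design.groups[0].times)])
        fr2 = population_fim(adult_model, d2)
        assert np.allclose(fr2.matrix, 2 * fr1.matrix, rtol=1e-12)
        assert np.allclose(fr2.expected_se, fr1.expected_se / np.sqrt(2), rtol=1e-9)

    def test_group_order_is_irrelevant(self, adult_model):
        g1 = Group(n_subjects=20, times=np.array([0.5, 2.0, 6.0]))
        g2 = Group(n_subjects=40, times=np.array([0.75, 3.0, 8.0]))
        a = population_fim(adult_model, Design(groups=[g1, g2]))
        b = population_fim(adult_model, Design(groups=[g2, g1]))
        assert np.array_equal(a.matrix, b.matrix)

    def test_extra_sampling_time_never_reduces_logdet(self, adult_model):
        base = np.array([0.5, 2.0, 6.0])
        fr0 = population_fim(adult_model, Design(groups=[Group(60, base)]))
        for extra in (1.0, 4.0, 9.0):
            t = np.sort(np.append(base, extra))
            fr1 = population_fim(adult_model, Design(groups=[Group(60, t)]))
            assert fr1.logdet >= fr0.logdet - 1e-9

    def test_sensitivities_match_finite_differences(self, adult_model):
        times = np.atleast_2d(np.array([0.5, 1.5, 4.0, 8.0]))
        pm = adult_model
        f0, g = pm.structural.conc_grad(pm.theta, 147.9, times)
        for j in range(4):
            h = 1e-6 * pm.theta[j]
            up = pm.theta.copy(); up[j] += h
            dn = pm.theta.copy(); dn[j] -= h
            fd = (pm.structural.conc(up, 147.9, times)
                  - pm.structural.conc(dn, 147.9, times)) / (2 * h)
            assert np.allclose(g[..., j], fd, rtol=1e-6, atol=1e-12)


class TestCriteria:
    def test_identity_matrix_has_zero_log_determinant(self):
        fr = FIMResult(matrix=np.eye(5), param_labels=list("abcde"),
                       param_values=np.ones(5))
        assert d_criterion(fr) == pytest.approx(0.0)

    def test_scaling_shifts_logdet_by_p_log_c(self, adult_model, adult_design):
        fr = population_fim(adult_model, adult_design)
        scaled = FIMResult(matrix=3.0 * fr.matrix, param_labels=fr.param_labels,
                           param_values=fr.param_values)
        assert scaled.logdet == pytest.approx(fr.logdet + fr.p * np.log(3.0), rel=1e-10)

    def test_two_by_two_matches_direct_formula(self):
        m = np.array([[4.0, 1.0], [1.0, 3.0]])
        fr = FIMResult(matrix=m, param_labels=["a", "b"], param_values=np.ones(2))
        assert fr.logdet == pytest.approx(np.log(4 * 3 - 1))

    def test_efficiency_identities(self, adult_model, adult_design):
        fr = population_fim(adult_model, adult_design)
        assert efficiency(fr, fr) == pytest.approx(1.0)
        d2 = Design(groups=[Group(120, adult_design.groups[0].times)])
        fr2 = population_fim(adult_model, d2)
        assert efficiency(fr2, fr) == pytest.approx(2.0, rel=1e-9)

    def test_efficiency_is_multiplicative(self, adult_model):
        designs = [Design(groups=[Group(60, np.array(ts))]) for ts in
                   ([0.5, 2.0, 6.0], [0.4, 1.0, 3.0], [0.6, 2.5, 8.0])]
        a, b, c = (population_fim(adult_model, d) for d in designs)
        assert efficiency(a, b) * efficiency(b, c) == pytest.approx(
            efficiency(a, c), rel=1e-10)

    def test_mismatched_parameterisations_rejected(self, adult_model, dost_model,
                                                   adult_design):
        fa = population_fim(adult_model, adult_design)
        fd = population_fim(dost_model, adult_design)
        with pytest.raises(ValueError):
            efficiency(fa, fd)


class TestCompoundObjective:
    def test_single_member_equals_normalised_logdet(self, adult_model, adult_ci,
                                                    adult_design):
        cs = build_competing_set([(adult_model, adult_ci)], central_weight=1.0)
        fr = population_fim(adult_model, adult_design)
        assert compound_objective(cs, adult_design) == pytest.approx(
            fr.logdet / fr.p, rel=1e-12)

    def test_invariant_to_duplicated_member_with_split_weights(
            self, adult_model, adult_ci, adult_design):
        from popkdesign.population import CompetingModelSet

        cs1 = CompetingModelSet(members=[(adult_model, 1.0)])
        cs2 = CompetingModelSet(members=[(adult_model, 0.4), (adult_model, 0.6)])
        assert compound_objective(cs1, adult_design) == pytest.approx(
            compound_objective(cs2, adult_design), rel=1e-12)

    def test_objective_between_member_extremes(self, adult_model, dost_model,
                                               adult_design):
        from popkdesign.population import CompetingModelSet

        cs = CompetingModelSet(members=[(adult_model, 0.5), (dost_model, 0.5)])
        obj = compound_objective(cs, adult_design)
        fa = population_fim(adult_model, adult_design)
        fd = population_fim(dost_model, adult_design)
        lo = min(fa.logdet / fa.p, fd.logdet / fd.p)
        hi = max(fa.logdet / fa.p, fd.logdet / fd.p)
        assert lo - 1e-9 <= obj <= hi + 1e-9
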