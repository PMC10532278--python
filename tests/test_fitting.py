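import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import localsem as ls
from localsem.fitting import CompiledModel, ParameterMapping, fit_groups
from localsem.modelspec import parse_model_syntax

from conftest import random_pd


class TestImpliedCovariance:
    def test_one_factor_unit_loadings(self):
        spec = parse_model_syntax("F =~ 1*X1 + 1*X2 + 1*X3\n"
                                  "X1~~1*X1\nX2~~1*X2\nX3~~1*X3\nF~~1*F")
        Sigma = ls.implied_covariance(spec, {})
        assert np.allclose(Sigma, np.ones((3, 3)) + np.eye(3))

    def test_zero_loadings_give_psi(self):
        spec = parse_model_syntax("F =~ 0*X1 + 0*X2\nF ~~ 1*F")
        Sigma = ls.implied_covariance(spec, {"X1~~X1": 0.3, "X2~~X2": 0.7})
        assert np.allclose(Sigma, np.diag([0.3, 0.7]))

    def test_structural_zero_reduces_to_cfa(self, two_factor_syntax):
        cfa = parse_model_syntax(two_factor_syntax)
        sem = parse_model_syntax(two_factor_syntax + "\nFY ~ 0*FX")
        th_cfa = {l: 0.8 for l in cfa.free_labels}
        th_cfa["FX~~FY"] = 0.4
        th_sem = {l: th_cfa[l] for l in sem.free_labels if l in th_cfa}
        S1 = ls.implied_covariance(cfa, th_cfa)
        # with B = 0 and cov(FX, zeta_Y) = 0, Eq-5-style and CFA structure agree
        # apart from the factor covariance block, so compare a model with the
        # covariance fixed at 0 in both
        th_cfa0 = dict(th_cfa, **{"FX~~FY": 0.0})
        S1 = ls.implied_covariance(cfa, th_cfa0)
        S2 = ls.implied_covariance(sem, th_sem)
        assert np.allclose(S1, S2)

    def test_symmetry(self, two_factor_syntax):
        spec = parse_model_syntax(two_factor_syntax + "\nFY ~ FX")
        theta = {l: 0.5 for l in spec.free_labels}
        S = ls.implied_covariance(spec, theta)
        assert np.allclose(S, S.T)


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert ls.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_scaled_identity(self):
        val = ls.ml_discrepancy(np.eye(2), 2 * np.eye(2))
        assert val == pytest.approx(2 * math.log(2) - 1, abs=1e-12)

    def test_closed_form_diagonal(self):
        val = ls.ml_discrepancy(np.diag([2.0, 1.0]), np.eye(2))
        assert val == pytest.approx(1 - math.log(2), abs=1e-12)

    def test_rejects_non_pd(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ls.ml_discrepancy(bad, np.eye(2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 5))
    def test_nonnegative_on_random_pd_pairs(self, seed, n):
        rng = np.random.default_rng(seed)
        S, Sig = random_pd(rng, n), random_pd(rng, n)
        assert ls.ml_discrepancy(S, Sig) >= 0.0

    def test_congruence_invariance(self):
        rng = np.random.default_rng(5)
        S, Sig = random_pd(rng, 3), random_pd(rng, 3)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        d1 = ls.ml_discrepancy(S, Sig)
        d2 = ls.ml_discrepancy(A @ S @ A.T, A @ Sig @ A.T)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestFitGroups:
    def test_saturated_model_zero_discrepancy(self):
        # just-identified one-factor, three-indicator model reproduces S
        rng = np.random.default_rng(1)
        lam = np.array([1.0, 0.8, 1.2])
        S = np.outer(lam, lam) * 0.9 + np.diag([0.5, 0.6, 0.4])
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        fit = fit_groups(spec, [(S, 100.0)])
        assert fit.converged
        assert fit.discrepancy < 1e-8
        assert np.allclose(fit.implied()[0], S, atol=1e-5)

    def test_just_identified_closed_form(self):
        # algebraic solution: phi = s12 s13 / s23, lam2 = s23/s13, lam3 = s23/s12
        lam = np.array([1.0, 0.7, 1.3])
        phi = 0.8
        S = phi * np.outer(lam, lam) + np.diag([0.4, 0.5, 0.3])
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        fit = fit_groups(spec, [(S, 500.0)])
        th = fit.theta_dict()
        s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
        assert th["F~~F"] == pytest.approx(s12 * s13 / s23, abs=1e-5)
        assert th["F=~X2"] == pytest.approx(s23 / s13, abs=1e-5)
        assert th["F=~X3"] == pytest.approx(s23 / s12, abs=1e-5)

    def test_two_identical_groups_pool_to_single_fit(self):
        lam = np.array([1.0, 0.9, 1.1])
        S = 0.7 * np.outer(lam, lam) + np.diag([0.5, 0.5, 0.5])
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        f1 = fit_groups(spec, [(S, 80.0)])
        f2 = fit_groups(spec, [(S, 40.0), (S, 40.0)],
                        par_invariant=spec.free_labels)
        assert np.allclose(f2.theta[0], f2.theta[1])
        assert np.allclose(f1.theta[0], f2.theta[0], atol=1e-6)

    def test_objective_not_above_start(self):
        rng = np.random.default_rng(7)
        spec = parse_model_syntax("F =~ X1 + X2 + X3 + X4")
        S = random_pd(rng, 4, jitter=1.0)
        fit = fit_groups(spec, [(S, 50.0)])
        cm = CompiledModel(spec)
        from localsem.fitting import _start_values
        theta0 = np.broadcast_to(_start_values(cm, S[None]), (1, cm.P))
        sign, logdetS = np.linalg.slogdet(S[None])
        D0 = cm.discrepancies(theta0, S[None], logdetS)
        assert fit.discrepancy <= 50.0 * D0[0] + 1e-12

    def test_indicator_reordering_permutes_estimates(self):
        rng = np.random.default_rng(3)
        lam = np.array([1.0, 0.7, 1.3])
        S = 0.8 * np.outer(lam, lam) + np.diag([0.4, 0.5, 0.3])
        spec_a = parse_model_syntax("F =~ 1*X1 + X2 + X3")
        perm = [0, 2, 1]
        spec_b = parse_model_syntax("F =~ 1*X1 + X3 + X2")
        fa = fit_groups(spec_a, [(S, 100.0)]).theta_dict()
        fb = fit_groups(spec_b, [(S[np.ix_(perm, perm)], 100.0)]).theta_dict()
        for lab in ("F=~X2", "F=~X3", "F~~F", "X2~~X2", "X3~~X3"):
            assert fa[lab] == pytest.approx(fb[lab], abs=1e-6)

    def test_rejects_non_pd_group(self):
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        bad = np.array([[1.0, 1.2, 0.0], [1.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            fit_groups(spec, [(bad, 10.0)])


class TestParameterMapping:
    def test_invariant_and_focal_classes(self):
        mp = ParameterMapping.build(["a", "b"], 4, par_invariant=["a"])
        u = np.array([2.0, 1.0, 2.0, 3.0, 4.0])
        Theta = mp.theta(u)
        assert np.allclose(Theta[:, 0], 2.0)
        assert np.allclose(Theta[:, 1], [1, 2, 3, 4])

    def test_linear_class_has_two_coefficients(self):
        mp = ParameterMapping.build(["a"], 5, par_linear=["a"])
        assert mp.n_free == 2
        Theta = mp.theta(np.array([1.0, 2.0]))
        assert np.allclose(np.diff(Theta[:, 0], 2), 0.0)   # constant first diffs

    def test_quadratic_class_constant_second_differences(self):
        mp = ParameterMapping.build(["a"], 6, par_quadratic=["a"])
        assert mp.n_free == 3
        Theta = mp.theta(np.array([0.5, 1.0, 2.0]))
        assert np.allclose(np.diff(Theta[:, 0], 3), 0.0)

    def test_label_in_two_classes_rejected(self):
        with pytest.raises(ValueError):
            ParameterMapping.build(["a"], 3, par_invariant=["a"], par_linear=["a"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ParameterMapping.build(["a"], 3, par_invariant=["zzz"])


class TestFitStatistics:
    def test_saturated_perfect_fit(self):
        lam = np.array([1.0, 0.8, 1.2])
        S = 0.9 * np.outer(lam, lam) + np.diag([0.5, 0.6, 0.4])
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        st_ = fit_groups(spec, [(S, 100.0)]).fit_statistics()
        assert st_["srmr"] == pytest.approx(0.0, abs=1e-6)
        assert st_["rmsea"] == pytest.approx(0.0, abs=1e-6)
        assert st_["cfi"] == pytest.approx(1.0)
        assert st_["gfi"] == pytest.approx(1.0, abs=1e-6)

    def test_srmr_hand_computed(self):
        # Sigma(theta) = [[1, .3], [.3, 1]] vs S = [[1, .5], [.5, 1]]:
        # correlation residuals (0, 0, .2) over the lower triangle
        from localsem.fitting import FitResult, fit_statistics
        spec = parse_model_syntax("F =~ 1*V1 + 1*V2\n"
                                  "F ~~ 0.3*F\nV1 ~~ 0.7*V1\nV2 ~~ 0.7*V2")
        cm = CompiledModel(spec)
        assert cm.P == 0
        S = np.array([[[1.0, 0.5], [0.5, 1.0]]])
        mp = ParameterMapping.build([], 1)
        fit = FitResult(spec=spec, labels=[], theta=np.zeros((1, 0)),
                        u=np.zeros(0), mapping=mp, discrepancy=0.0,
                        group_discrepancies=np.zeros(1),
                        weights=np.array([50.0]), converged=True, n_iter=0,
                        grad_norm=0.0, S=S)
        st_ = fit_statistics(fit)
        assert st_["srmr"] == pytest.approx(math.sqrt(0.04 / 3), abs=1e-10)


class TestStandardize:
    def test_factor_correlation(self, two_factor_syntax):
        spec = parse_model_syntax(two_factor_syntax)
        theta = {l: 0.8 for l in spec.free_labels}
        theta.update({"FX~~FX": 4.0, "FY~~FY": 4.0, "FX~~FY": 2.0})
        cm = CompiledModel(spec)
        vec = np.array([theta[l] for l in cm.free_labels])
        std = ls.standardize_solution(spec, vec[None, :])[0]
        j = cm.free_labels.index("FX~~FY")
        assert std[j] == pytest.approx(0.5)

    def test_unit_factor_variances_leave_correlation(self, two_factor_syntax):
        spec = parse_model_syntax(two_factor_syntax)
        theta = {l: 0.8 for l in spec.free_labels}
        theta.update({"FX~~FX": 1.0, "FY~~FY": 1.0, "FX~~FY": 0.45})
        cm = CompiledModel(spec)
        vec = np.array([theta[l] for l in cm.free_labels])
        std = ls.standardize_solution(spec, vec[None, :])[0]
        assert std[cm.free_labels.index("FX~~FY")] == pytest.approx(0.45)

    def test_residual_sign_preserved(self):
        spec = parse_model_syntax("F =~ X1 + X2 + X3\nX1 ~~ X2")
        cm = CompiledModel(spec)
        theta = {l: 0.7 for l in cm.free_labels}
        theta["X1~~X2"] = -0.1
        vec = np.array([theta[l] for l in cm.free_labels])
        std = ls.standardize_solution(spec, vec[None, :])[0]
        assert std[cm.free_labels.index("X1~~X2")] < 0
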