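import warnings

import numpy as np
import pytest

import localsem as ls
from localsem import LocalSEM
from localsem.fitting import fit_groups
from localsem.modelspec import parse_model_syntax


@pytest.fixture(scope="module")
def grid_sample(dgm3_pop_small):
    """N=2000 sample whose moderator takes exactly the 13 grid values."""
    dgm, pop = dgm3_pop_small
    return dgm, ls.draw_sample(pop, 2000, seed=11)


def _lsem(dgm, sample, **kw):
    kw.setdefault("wt_floor", 0.0)
    kw.setdefault("grid", dgm.grid)
    return LocalSEM(sample, dgm.model_syntax(), dgm.moderator, **kw)


class TestPointwise:
    def test_single_focal_point_equals_single_group_fit(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample, grid=[12.0], kernel="uniform", bw=100.0,
                      residualize=False)
        res = model.fit(mode="pointwise")
        X = sample[dgm.indicators].to_numpy()
        E = X - X.mean(axis=0)
        S = E.T @ E / len(X)
        ref = fit_groups(parse_model_syntax(dgm.model_syntax()), [(S, float(len(X)))])
        assert np.allclose(res.theta[0], ref.theta[0], atol=1e-6)

    def test_exact_population_recovery(self, dgm1_pop_small):
        # uniform kernel with bw = spacing/2 on the exact-moment population:
        # conditional covariances equal the targets, curves are recovered
        dgm, pop = dgm1_pop_small
        model = _lsem(dgm, pop, kernel="uniform", bw=0.5)
        res = model.fit(mode="pointwise")
        true = dgm.marker_curves()
        for lab in res.labels:
            assert np.allclose(res.curve(lab), true[lab], atol=1e-4), lab

    def test_constraints_require_joint(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample, par_invariant=["FX=~X2"])
        with pytest.raises(ValueError):
            model.fit(mode="pointwise")


class TestJoint:
    def test_empty_constraints_match_pointwise(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample, kernel="gaussian", h=2.0)
        pw = model.fit(mode="pointwise")
        jt = model.fit(mode="joint", est_dif=False)
        assert np.allclose(jt.theta, pw.theta, atol=1e-5)

    def test_constrained_objective_not_below_unconstrained(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample)
        free = model.fit(mode="joint", est_dif=False)
        constr = _lsem(dgm, sample,
                       par_invariant=["FX=~X2", "FX=~X3"]).fit(
                           mode="joint", est_dif=False)
        assert constr.fit.discrepancy >= free.fit.discrepancy - 1e-8
        # the weighted sum of pointwise optima is a lower bound for any
        # constrained joint objective
        pw = model.fit(mode="pointwise")
        pw_sum = sum(float(f.discrepancy) for f in pw.pointwise_fits)
        assert pw_sum <= constr.fit.discrepancy + 1e-8

    def test_invariant_curves_are_flat(self, grid_sample):
        dgm, sample = grid_sample
        res = _lsem(dgm, sample, par_invariant=["FX=~X2", "FX=~X3"]).fit()
        assert np.ptp(res.curve("FX=~X2")) == 0.0
        assert np.ptp(res.curve("FX=~X3")) == 0.0

    def test_all_invariant_identical_matrices_is_single_group_fit(self):
        spec = parse_model_syntax("F =~ X1 + X2 + X3")
        lam = np.array([1.0, 0.8, 1.2])
        S = 0.9 * np.outer(lam, lam) + np.diag([0.5, 0.6, 0.4])
        joint = fit_groups(spec, [(S, 30.0)] * 5, par_invariant=spec.free_labels)
        single = fit_groups(spec, [(S, 150.0)])
        assert np.allclose(joint.theta[0], single.theta[0], atol=1e-6)

    def test_quadratic_constraint_recovers_quadratic_curve(self, dgm2_pop_two_factor):
        # the factor-variance curve of the preset is linear in age, a special
        # case of the quadratic constraint: constrained joint estimation on
        # the exact population must reproduce it
        dgm, pop = dgm2_pop_two_factor
        model = _lsem(dgm, pop, kernel="uniform", bw=0.5,
                      par_invariant=dgm.invariant_loading_labels(),
                      par_quadratic=["FX~~FX"])
        res = model.fit(est_dif=False)
        true = dgm.marker_curves()
        assert np.allclose(res.curve("FX~~FX"), true["FX~~FX"], atol=1e-3)

    def test_standardized_correlation_within_bounds(self, dgm2_pop_two_factor):
        dgm, pop = dgm2_pop_two_factor
        sample = ls.draw_sample(pop, 1500, seed=21)
        res = _lsem(dgm, sample,
                    par_invariant=dgm.invariant_loading_labels()).fit(est_dif=False)
        rho = res.curve("FX~~FY", standardized=True)
        assert np.all(np.abs(rho) <= 1.0)


class TestMGM:
    def test_mgm_equals_uniform_kernel_lsem_on_grid_data(self, grid_sample):
        dgm, sample = grid_sample
        lsem = _lsem(dgm, sample, kernel="uniform", bw=0.5)
        pw = lsem.fit(mode="pointwise")
        mgm = _lsem(dgm, sample).fit(mode="mgm")
        assert mgm.grid.T == 13
        assert np.allclose(mgm.theta, pw.theta, atol=1e-5)

    def test_single_group(self, grid_sample):
        dgm, sample = grid_sample
        res = _lsem(dgm, sample).fit(mode="mgm", n_groups=1)
        assert res.theta.shape[0] == 1

    def test_invariance_constraints_match_joint_mode(self, grid_sample):
        dgm, sample = grid_sample
        inv = ["FX=~X2", "FX=~X3"]
        mgm = _lsem(dgm, sample, par_invariant=inv).fit(mode="mgm")
        jt = _lsem(dgm, sample, kernel="uniform", bw=0.5,
                   par_invariant=inv).fit(mode="joint", est_dif=False)
        assert np.allclose(mgm.theta, jt.theta, atol=1e-5)


class TestDIF:
    def test_requires_invariant_parameters(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample)
        with pytest.raises(ValueError):
            model.fit(mode="joint", est_dif=True, dif_labels=[])

    def test_single_focal_point_dif_equals_free_estimate(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample, grid=[12.0], kernel="uniform", bw=100.0,
                      residualize=False, par_invariant=["FX=~X2"])
        res = model.fit(mode="joint", dif_labels=["FX=~X2"])
        free = _lsem(dgm, sample, grid=[12.0], kernel="uniform", bw=100.0,
                     residualize=False).fit(mode="pointwise")
        # with T = 1 there is no pooling: freeing the parameter with all
        # others held at their (identical) estimates returns the free value
        assert res.curve("FX=~X2", dif=True)[0] == pytest.approx(
            free.curve("FX=~X2")[0], abs=1e-4)

    def test_invariant_population_gives_flat_dif_curves(self, dgm3_pop_small):
        dgm, pop = dgm3_pop_small
        model = _lsem(dgm, pop, kernel="uniform", bw=0.5,
                      par_invariant=dgm.invariant_loading_labels())
        res = model.fit()
        true = dgm.marker_curves()
        for lab in res.dif.columns:
            curve = res.curve(lab, dif=True)
            assert np.ptp(curve) < 1e-4
            assert np.allclose(curve, true[lab], atol=1e-4)

    def test_default_dif_set_includes_fixed_anchor(self, grid_sample):
        dgm, sample = grid_sample
        model = _lsem(dgm, sample, par_invariant=["FX=~X2", "FX=~X3"])
        assert set(model.default_dif_labels()) == {"FX=~X1", "FX=~X2", "FX=~X3"}


class TestMissingData:
    def test_pairwise_deletion_end_to_end(self, dgm3_pop_small):
        # estimates from data with 10% missingness stay close to the
        # complete-data estimates (pairwise-deleted moments, PD repair on)
        dgm, pop = dgm3_pop_small
        sample = ls.draw_sample(pop, 2000, seed=61)
        rng = np.random.default_rng(62)
        holey = sample.copy()
        for col in dgm.indicators:
            holey.loc[rng.random(len(holey)) < 0.10, col] = np.nan
        full = _lsem(dgm, sample).fit(est_dif=False)
        miss = _lsem(dgm, holey).fit(est_dif=False)
        assert np.allclose(miss.theta, full.theta, atol=0.15)
        assert miss.fit.converged


class TestResultsSurface:
    def test_curves_table_layout(self, grid_sample):
        dgm, sample = grid_sample
        res = _lsem(dgm, sample, par_invariant=["FX=~X2", "FX=~X3"]).fit()
        df = res.curves
        assert list(df.columns) == ["parameter", "focal_index", "a_t", "estimate",
                                    "standardized", "is_invariant", "is_dif"]
        assert df[df.is_dif].parameter.nunique() == 3
        assert (df.groupby(["parameter", "is_dif"]).size() == 13).all()

    def test_summary_prints_fit_statistics(self, grid_sample):
        dgm, sample = grid_sample
        res = _lsem(dgm, sample, par_invariant=["FX=~X2"]).fit(est_dif=False)
        text = res.summary()
        assert "RMSEA" in text and "SRMR" in text
        assert "FX~~FX" in text

    def test_pointwise_fit_statistics_per_focal_point(self, grid_sample):
        dgm, sample = grid_sample
        res = _lsem(dgm, sample).fit(mode="pointwise")
        stats = res.fit_statistics()
        assert len(stats) == 13
        # just-identified model at every focal point: perfect fit
        assert all(s["srmr"] < 1e-4 for s in stats)
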