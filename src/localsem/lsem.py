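"""Locally weighted structural equation models over a continuous moderator.

The user-facing surface follows the model/results idiom: :class:`LocalSEM`
is built from a data frame plus lavaan-style model syntax, ``fit()`` returns
an :class:`LSEMResults` carrying parameter curves, fit statistics and DIF
effects, and bootstrap / permutation inference hangs off the results object.

Estimation modes
----------------
``pointwise``
    A separate SEM is fitted to the conditional covariance matrix at each
    focal point; parameters vary freely over the moderator.
``joint``
    One weighted minimization over all focal points,
    F(θ) = Σ_t W_t D(Σ̂_t, Σ_t(θ_0, θ_t)), in which selected parameters can
    be invariant (θ_0) or follow linear/quadratic trends over the grid.
``mgm``
    A classical multiple-group SEM on a discretized moderator; with the
    uniform kernel and bandwidth Δ/2 on grid-valued data this coincides with
    the locally weighted estimate under the same identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import (CompiledModel, FitResult, ParameterMapping, fit_groups,
                      fit_statistics, standardize_solution)
from .kernels import FocalGrid, KernelSpec, WeightMatrix, compute_weights, make_grid
from .modelspec import LAMBDA, ModelSpec, parse_model_syntax
from .moments import LocalMoments, compute_local_moments

__all__ = ["LocalSEM", "LSEMResults"]


class LocalSEM:
    """Local SEM: parameter curves of an SEM over a continuous moderator.

    Parameters
    ----------
    data : pandas.DataFrame
        Person-by-variable table with the indicator columns named in the
        model syntax and the moderator column.
    model : str or ModelSpec
        lavaan-style model syntax (see :mod:`localsem.modelspec`).
    moderator : str
        Name of the continuous moderator column (age in most applications).
    grid : str or sequence
        Focal points: ``"equidistant:T"``, ``"percentile:T"`` or explicit.
    kernel : {"gaussian", "epanechnikov", "uniform"}
    h, bw : float
        Bandwidth factor (bw = h N^(-1/5) σ_A; default h = 2) or the
        bandwidth itself; give at most one.
    par_invariant, par_linear, par_quadratic : sequence of str
        Parameter labels constrained equal / linear-in-grid / quadratic-in-
        grid across focal points (joint estimation).
    pw_linear, pw_quadratic : int
        Number of segments for piecewise variants of the trend constraints.
    residualize : bool
        Local quadratic removal of the conditional mean before covariances.
    cov_mode : {"weighted", "local_regression"}
        Conditional-covariance estimator.
    pd : bool
        Eigenvalue-clipping repair of indefinite conditional covariances.
    sampling_weights, cluster : str
        Optional column names for sampling weights and cluster ids.
    wt_floor : float
        Minimum kernel-weight sum per focal point; defaults to 5 * I.
    """

    def __init__(self, data: pd.DataFrame, model: str | ModelSpec, moderator: str,
                 grid="equidistant:13", kernel: str = "gaussian",
                 h: float | None = None, bw: float | None = None,
                 sampling_weights: str | None = None, cluster: str | None = None,
                 residualize: bool = True, cov_mode: str = "weighted",
                 pd: bool = True, pd_floor: float = 1e-4,
                 par_invariant: Sequence[str] = (), par_linear: Sequence[str] = (),
                 par_quadratic: Sequence[str] = (), pw_linear: int = 1,
                 pw_quadratic: int = 1, wt_floor: float | None = None,
                 gtol: float = 1e-8):
        self.spec = model if isinstance(model, ModelSpec) else parse_model_syntax(model)
        self.moderator = moderator
        if moderator not in data.columns:
            raise ValueError(f"moderator column {moderator!r} not in data")
        missing_cols = [c for c in self.spec.indicators if c not in data.columns]
        if missing_cols:
            raise ValueError(f"indicator column(s) missing from data: {missing_cols}")
        if h is not None and bw is not None:
            raise ValueError("give either h or bw, not both")

        self.data = data
        self.a = data[moderator].to_numpy(float)
        if not np.all(np.isfinite(self.a)):
            raise ValueError("moderator contains missing or non-finite values")
        if np.unique(self.a).size < 2:
            raise ValueError("moderator is constant")
        self.X = data[self.spec.indicators].to_numpy(float)
        self.N = self.X.shape[0]
        self.sampling_weights = (data[sampling_weights].to_numpy(float)
                                 if sampling_weights else None)
        self.cluster = data[cluster].to_numpy() if cluster else None

        self.grid = grid if isinstance(grid, FocalGrid) else make_grid(self.a, grid)
        sigma_A = float(np.std(self.a, ddof=1))
        self.kernel = KernelSpec(kernel, h=h, bw=bw).resolve(self.N, sigma_A)
        self.residualize = residualize
        self.cov_mode = cov_mode
        self.pd = pd
        self.pd_floor = pd_floor
        self.wt_floor = 5 * self.spec.n_indicators if wt_floor is None else wt_floor
        self.gtol = gtol

        self.par_invariant = tuple(par_invariant)
        self.par_linear = tuple(par_linear)
        self.par_quadratic = tuple(par_quadratic)
        self.pw_linear = pw_linear
        self.pw_quadratic = pw_quadratic

        self.weights: WeightMatrix = compute_weights(
            self.a, self.grid, self.kernel,
            sampling_weights=self.sampling_weights, wt_floor=self.wt_floor)
        self.grid = self.weights.grid            # after any focal-point drops
        self.moments: LocalMoments = compute_local_moments(
            self.X, self.a, self.weights, mode=cov_mode, residualize=residualize,
            pd=pd, pd_floor=pd_floor, indicator_names=self.spec.indicators)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model: str, moderator: str, **kw):
        return cls(data, model, moderator, **kw)

    def _recompute_moments(self, X, a, sampling_weights=None) -> LocalMoments:
        """Moments for resampled/permuted rows with the frozen grid, kernel
        and bandwidth of this model (used by bootstrap and permutation)."""
        wm = compute_weights(a, self.grid, self.kernel,
                             sampling_weights=sampling_weights, wt_floor=None)
        if np.any(wm.W <= 0):
            raise ValueError("replicate has empty focal point")
        return compute_local_moments(X, a, wm, mode=self.cov_mode,
                                     residualize=self.residualize,
                                     pd=self.pd, pd_floor=self.pd_floor)

    def default_dif_labels(self) -> list[str]:
        """Invariant labels plus fixed (anchor) loadings — the parameters for
        which DIF curves are reported by default."""
        labels = list(self.par_invariant)
        for p in self.spec.parameters:
            if p.matrix == LAMBDA and not p.free:
                labels.append(p.label)
        return labels

    # ------------------------------------------------------------------
    def fit(self, mode: str = "joint", est_dif: bool | None = None,
            dif_labels: Sequence[str] | None = None, n_groups: int | None = None,
            start: np.ndarray | None = None,
            moments: LocalMoments | None = None,
            gtol: float | None = None) -> "LSEMResults":
        """Estimate the model.

        ``est_dif`` defaults to True in joint mode whenever invariance
        constraints are present.  ``moments``/``start`` are used internally
        by resampling loops.
        """
        gtol = self.gtol if gtol is None else gtol
        if mode == "mgm":
            return self._fit_mgm(n_groups)
        mom = moments if moments is not None else self.moments
        if mode == "pointwise":
            if self.par_invariant or self.par_linear or self.par_quadratic:
                raise ValueError("cross-focal-point constraints require mode='joint'")
            return self._fit_pointwise(mom, gtol=gtol)
        if mode != "joint":
            raise ValueError(f"unknown mode {mode!r}")

        cm = CompiledModel(self.spec)
        mapping = ParameterMapping.build(
            cm.free_labels, mom.grid.T, self.par_invariant, self.par_linear,
            self.par_quadratic, self.pw_linear, self.pw_quadratic)
        fit = fit_groups(self.spec, S=mom.cov, weights=mom.W, mapping=mapping,
                         start=start, gtol=gtol)
        res = LSEMResults(model=self, mode="joint", fit=fit, moments=mom,
                          grid=mom.grid, f_hat=mom.f_hat)
        if est_dif is None:
            est_dif = bool(self.par_invariant)
        if est_dif:
            labels = list(dif_labels) if dif_labels is not None \
                else self.default_dif_labels()
            if not labels:
                raise ValueError("DIF effects require invariant (or fixed-anchor) "
                                 "parameters")
            res.dif = estimate_dif(self.spec, fit, mom, labels, gtol=gtol)
        return res

    def _fit_pointwise(self, mom: LocalMoments,
                       gtol: float | None = None) -> "LSEMResults":
        cm = CompiledModel(self.spec)
        T = mom.grid.T
        Theta = np.empty((T, cm.P))
        fits, conv = [], np.ones(T, bool)
        for t in range(T):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    f = fit_groups(self.spec, S=mom.cov[t][None],
                                   weights=np.array([mom.W[t]]),
                                   gtol=gtol or self.gtol)
                Theta[t] = f.theta[0]
                conv[t] = f.converged
            except Exception:
                Theta[t] = np.nan
                conv[t] = False
                f = None
            fits.append(f)
        if not conv.all():
            warnings.warn(f"pointwise fit failed to converge at focal point(s) "
                          f"{np.flatnonzero(~conv).tolist()}", RuntimeWarning)
        res = LSEMResults(model=self, mode="pointwise", fit=None, moments=mom,
                          grid=mom.grid, f_hat=mom.f_hat)
        res.pointwise_fits = fits
        res.pointwise_converged = conv
        res._theta = Theta
        res._labels = cm.free_labels
        return res

    def _fit_mgm(self, n_groups: int | None) -> "LSEMResults":
        a = self.a
        distinct = np.unique(a)
        if n_groups is None or n_groups >= distinct.size:
            codes = np.searchsorted(distinct, a)
            n_groups = distinct.size
        else:
            qs = np.quantile(a, np.linspace(0, 1, n_groups + 1))
            qs[0], qs[-1] = -np.inf, np.inf
            codes = np.searchsorted(qs, a, side="right") - 1
        counts = np.bincount(codes, minlength=n_groups)
        if np.any(counts == 0):
            raise ValueError("empty moderator bin in MGM discretization")
        S = np.empty((n_groups, self.spec.n_indicators, self.spec.n_indicators))
        centers = np.empty(n_groups)
        for g in range(n_groups):
            rows = self.X[codes == g]
            centers[g] = a[codes == g].mean()
            E = rows - rows.mean(axis=0)
            S[g] = E.T @ E / rows.shape[0]          # ML (÷N) covariance
        cm = CompiledModel(self.spec)
        mapping = ParameterMapping.build(
            cm.free_labels, n_groups, self.par_invariant, self.par_linear,
            self.par_quadratic, self.pw_linear, self.pw_quadratic)
        fit = fit_groups(self.spec, S=S, weights=counts.astype(float),
                         mapping=mapping, gtol=self.gtol)
        grid = FocalGrid(centers, "explicit")
        res = LSEMResults(model=self, mode="mgm", fit=fit, moments=None,
                          grid=grid, f_hat=counts / counts.sum())
        return res


# ---------------------------------------------------------------------------
# DIF effects
# ---------------------------------------------------------------------------

def estimate_dif(spec: ModelSpec, fit: FitResult, moments: LocalMoments,
                 dif_labels: Sequence[str], gtol: float = 1e-8) -> pd.DataFrame:
    """Focal-point-specific estimates of otherwise invariant/fixed parameters.

    All fitted parameters θ̂_t are held fixed; the DIF set is freed and
    Σ_t W_t D(Σ̂_t, Σ_t(δ_t, θ̂_t)) is minimized — which decouples into a
    separate small minimization per focal point, solved here as one batched
    L-BFGS problem with the invariant estimates as warm start.
    """
    from scipy.optimize import minimize

    # spec variant in which fixed DIF parameters become free
    params = []
    for p in spec.parameters:
        if not p.free and p.label in dif_labels:
            params.append(type(p)(p.label, p.matrix, p.row, p.col, True))
        else:
            params.append(p)
    dspec = ModelSpec(spec.indicators, spec.factors, params)
    cm = CompiledModel(dspec)
    T = moments.grid.T
    labels = cm.free_labels
    dif_idx = np.array([labels.index(l) for l in dif_labels])
    other_idx = np.array([j for j in range(cm.P) if j not in set(dif_idx)])

    Theta = np.zeros((T, cm.P))
    fitted = dict(zip(fit.labels, fit.theta.T))    # label -> (T,) curve
    fixed_vals = {p.label: p.value for p in spec.parameters if not p.free}
    for j, lab in enumerate(labels):
        if lab in fitted:
            Theta[:, j] = fitted[lab]
        else:
            Theta[:, j] = fixed_vals[lab]

    S = moments.cov
    sign, logdetS = np.linalg.slogdet(S)
    w = moments.W / moments.W.sum()
    x0 = Theta[:, dif_idx].ravel()

    def fun(x):
        Th = Theta.copy()
        Th[:, dif_idx] = x.reshape(T, dif_idx.size)
        F, Gmat = cm.value_and_grad(Th, S, logdetS, w)
        if F is None:
            return 1e10 * (1 + x @ x), np.zeros_like(x)
        return F, Gmat[:, dif_idx].ravel()

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12})
    delta = res.x.reshape(T, dif_idx.size)
    return pd.DataFrame(delta, columns=list(dif_labels),
                        index=pd.Index(moments.grid.points, name="a_t"))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class LSEMResults:
    """Fitted parameter curves and fit statistics of a local SEM."""

    model: LocalSEM
    mode: str
    fit: FitResult | None
    moments: LocalMoments | None
    grid: FocalGrid
    f_hat: np.ndarray
    dif: pd.DataFrame | None = None
    pointwise_fits: list = field(default_factory=list)
    pointwise_converged: np.ndarray | None = None
    _theta: np.ndarray | None = None
    _labels: list[str] | None = None

    # -- parameter access ------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return self.fit.labels if self.fit is not None else self._labels

    @property
    def theta(self) -> np.ndarray:
        """Free parameter curves, shape (T, P)."""
        return self.fit.theta if self.fit is not None else self._theta

    @property
    def standardized(self) -> np.ndarray:
        return standardize_solution(self.model.spec, self.theta)

    def curve(self, label: str, standardized: bool = False,
              dif: bool = False) -> np.ndarray:
        if dif:
            if self.dif is None or label not in self.dif.columns:
                raise KeyError(f"no DIF curve for {label!r}")
            return self.dif[label].to_numpy()
        j = self.labels.index(label)
        return (self.standardized if standardized else self.theta)[:, j]

    def invariant_labels(self) -> list[str]:
        return list(self.model.par_invariant)

    # -- curve table ------------------------------------------------------
    @property
    def curves(self) -> pd.DataFrame:
        """Long-format curve table (the ``curves.csv`` export)."""
        th, std = self.theta, self.standardized
        inv = set(self.model.par_invariant)
        rows = []
        for j, lab in enumerate(self.labels):
            for t, at in enumerate(self.grid.points):
                rows.append((lab, t, at, th[t, j], std[t, j], lab in inv, False))
        if self.dif is not None:
            for lab in self.dif.columns:
                for t, at in enumerate(self.grid.points):
                    rows.append((lab, t, at, self.dif[lab].iloc[t],
                                 np.nan, False, True))
        return pd.DataFrame(rows, columns=["parameter", "focal_index", "a_t",
                                           "estimate", "standardized",
                                           "is_invariant", "is_dif"])

    # -- fit statistics ---------------------------------------------------
    def fit_statistics(self) -> dict | list[dict]:
        """Global statistics (joint/mgm) or per-focal-point list (pointwise)."""
        if self.mode == "pointwise":
            out = []
            for f in self.pointwise_fits:
                out.append(None if f is None else fit_statistics(f))
            return out
        return fit_statistics(self.fit)

    # -- curve summaries --------------------------------------------------
    def curve_mean_sd(self, label: str, standardized: bool = False,
                      dif: bool = False) -> tuple[float, float]:
        """Density-weighted mean and SD of one parameter curve."""
        from .inference import curve_mean_sd
        return curve_mean_sd(self.curve(label, standardized, dif), self.f_hat)

    # -- inference --------------------------------------------------------
    def bootstrap(self, R: int = 200, seed: int | None = None, **kw):
        from .inference import bootstrap
        return bootstrap(self, R=R, seed=seed, **kw)

    def permutation_test(self, B: int = 1000, seed: int | None = None, **kw):
        from .inference import permutation_test
        return permutation_test(self, B=B, seed=seed, **kw)

    # -- display -----------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Local structural equation model",
            "=" * 55,
            f"mode: {self.mode}    N = {m.N}    focal points: {self.grid.T}",
            f"kernel: {m.kernel.kernel}   h = {m.kernel.h}   "
            f"bw = {m.kernel.bw:.4f}",
            f"invariant parameters: {list(m.par_invariant) or 'none'}",
        ]
        if self.mode != "pointwise":
            st = self.fit_statistics()
            lines.append(
                f"chi2 = {st['chi2']:.2f} (df {st['df']})  RMSEA = {st['rmsea']:.3f}"
                f"  SRMR = {st['srmr']:.3f}  CFI = {st['cfi']:.3f}"
                f"  TLI = {st['tli']:.3f}  GFI = {st['gfi']:.3f}")
        lines.append("-" * 55)
        lines.append(f"{'parameter':<18}{'M':>9}{'SD':>9}")
        for lab in self.labels:
            M, SD = self.curve_mean_sd(lab)
            lines.append(f"{lab:<18}{M:>9.3f}{SD:>9.3f}")
        if self.dif is not None:
            for lab in self.dif.columns:
                M, SD = self.curve_mean_sd(lab, dif=True)
                lines.append(f"{'dif ' + lab:<18}{M:>9.3f}{SD:>9.3f}")
        return "\n".join(lines)
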