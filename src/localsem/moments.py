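"""Kernel-weighted conditional means, residuals and conditional covariance
matrices at each focal point, with positive-definite repair.

At a focal point a_t the conditional mean of each indicator is estimated by
local quadratic regression in (a_n - a_t) (weighted least squares, closed
form).  Residuals from these fits feed the conditional covariance, either by
direct weighting,

    sigma_ij(a_t) = W_t^{-1} sum_n w_nt e_nit e_njt,

or by a second local quadratic regression of the residual products on
(a_n - a_t), whose intercept is the covariance estimate ("local_regression"
mode).  Missing values are handled by pairwise deletion with per-pair weight
renormalization; resulting indefinite matrices are repaired by eigenvalue
clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import FocalGrid, WeightMatrix

__all__ = ["LocalMoments", "local_quadratic_fit", "compute_local_moments",
           "repair_positive_definite", "grid_density"]


def local_quadratic_fit(y: np.ndarray, a: np.ndarray, a_t: float,
                        w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least-squares fit of y on (1, a-a_t, (a-a_t)^2).

    Returns the coefficient triple; the intercept is the conditional-mean
    estimate at a_t.  A singular design falls back to the linear and then the
    intercept-only fit (degenerate moderator support).
    """
    y = np.asarray(y, float)
    z = np.asarray(a, float) - a_t
    w = np.asarray(w, float)
    ok = np.isfinite(y) & (w > 0)
    coef = np.zeros(3)
    for ncol in (3, 2, 1):
        B = np.column_stack([z[ok] ** d for d in range(ncol)])
        G = (B * w[ok, None]).T @ B
        rhs = (B * w[ok, None]).T @ y[ok]
        try:
            c = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.cond(G) < 1e10:
            coef[:ncol] = c
            return tuple(coef)
    # all-zero weights or no finite data
    if not np.any(ok):
        raise ValueError("no observations with positive weight")
    coef[0] = np.average(y[ok], weights=w[ok]) if w[ok].sum() > 0 else np.nan
    return tuple(coef)


@dataclass
class LocalMoments:
    """Per-focal-point conditional moments."""

    grid: FocalGrid
    mean_coef: np.ndarray          # (T, I, 3) local quadratic coefficients
    cov: np.ndarray                # (T, I, I) conditional covariances (PD-repaired)
    cov_raw: np.ndarray            # before repair
    W: np.ndarray                  # (T,) weight sums
    pd_repaired: np.ndarray        # (T,) bool
    mode: str                      # "weighted" | "local_regression"
    residualize: bool = True
    indicator_names: list[str] = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        """Conditional mean estimates mu_i(a_t) = gamma_it0, shape (T, I)."""
        return self.mean_coef[:, :, 0]

    @property
    def f_hat(self) -> np.ndarray:
        return self.W / self.W.sum()

    def to_frame(self):
        """Long-format audit export: t, a_t, i, j, value (j == '' for means)."""
        import pandas as pd
        rows = []
        names = self.indicator_names or [f"V{i+1}" for i in range(self.cov.shape[1])]
        for t, at in enumerate(self.grid.points):
            for i, ni in enumerate(names):
                rows.append((t, at, ni, "", self.means[t, i]))
                for j, nj in enumerate(names):
                    if j >= i:
                        rows.append((t, at, ni, nj, self.cov[t, i, j]))
        return pd.DataFrame(rows, columns=["t", "a_t", "i", "j", "value"])


def _design(z: np.ndarray) -> np.ndarray:
    return np.stack([np.ones_like(z), z, z * z], axis=1)  # (N, 3)


def _wls_batched(B: np.ndarray, w: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve the 3x3 weighted normal equations for many responses at once.

    B (N,3), w (N,), Y (N,m) -> coefficients (m,3).  Falls back to lower
    polynomial order on singular designs.
    """
    for ncol in (3, 2, 1):
        Bn = B[:, :ncol]
        G = (Bn * w[:, None]).T @ Bn
        if np.linalg.cond(G) >= 1e10:
            continue
        rhs = (Bn * w[:, None]).T @ Y
        sol = np.linalg.solve(G, rhs)           # (ncol, m)
        out = np.zeros((Y.shape[1], 3))
        out[:, :ncol] = sol.T
        return out
    out = np.zeros((Y.shape[1], 3))
    out[:, 0] = (w[:, None] * Y).sum(axis=0) / w.sum()
    return out


def compute_local_moments(X: np.ndarray, a: np.ndarray, weights: WeightMatrix,
                          mode: str = "weighted", residualize: bool = True,
                          pd: bool = True, pd_floor: float = 1e-4,
                          pair_floor: int = 3,
                          indicator_names: list[str] | None = None) -> LocalMoments:
    """Conditional means, residuals and covariances at every focal point.

    Parameters
    ----------
    X : (N, I) indicator matrix, NaN for missing.
    a : (N,) moderator.
    weights : kernel weight matrix aligned with the rows of X.
    mode : "weighted" (Eq.-16-style direct weighting) or "local_regression"
        (intercept of a local quadratic fit to residual products).
    residualize : local quadratic mean removal; if False, residuals are
        deviations from the plain kernel-weighted mean.
    """
    X = np.asarray(X, float)
    a = np.asarray(a, float)
    N, I = X.shape
    if weights.w.shape[0] != N:
        raise ValueError("weight matrix not aligned with data rows")
    if mode not in ("weighted", "local_regression"):
        raise ValueError(f"unknown covariance mode {mode!r}")
    T = weights.grid.T
    has_missing = bool(np.isnan(X).any())
    miss = np.isnan(X)
    if has_missing and np.any(miss.all(axis=0)):
        raise ValueError("indicator with no observed values")

    mean_coef = np.zeros((T, I, 3))
    cov_raw = np.zeros((T, I, I))
    pd_flags = np.zeros(T, bool)

    Xf = np.where(miss, 0.0, X)
    for t in range(T):
        z = a - weights.grid.points[t]
        B = _design(z)
        wt = weights.w[:, t]
        if not has_missing:
            if residualize:
                coefs = _wls_batched(B, wt, X)               # (I, 3)
            else:
                mu = (wt[:, None] * X).sum(0) / wt.sum()
                coefs = np.zeros((I, 3))
                coefs[:, 0] = mu
            mean_coef[t] = coefs
            E = X - B @ coefs.T                               # (N, I)
            if mode == "weighted":
                cov_raw[t] = (E * wt[:, None]).T @ E / wt.sum()
            else:
                iu, ju = np.triu_indices(I)
                P = E[:, iu] * E[:, ju]                       # (N, npair)
                c = _wls_batched(B, wt, P)[:, 0]
                M = np.zeros((I, I))
                M[iu, ju] = c
                M[ju, iu] = c
                cov_raw[t] = M
        else:
            E = np.zeros((N, I))
            for i in range(I):
                ok = ~miss[:, i]
                if residualize:
                    mean_coef[t, i] = local_quadratic_fit(X[ok, i], a[ok],
                                                          weights.grid.points[t], wt[ok])
                else:
                    sw = wt[ok].sum()
                    mean_coef[t, i, 0] = (wt[ok] * X[ok, i]).sum() / sw
                E[:, i] = Xf[:, i] - B @ mean_coef[t, i]
            obs = (~miss).astype(float)
            # pairwise deletion with per-pair weight renormalization
            WW = (obs * wt[:, None]).T @ obs                  # (I, I) pair weight sums
            npair = (obs.T @ obs)
            if np.any(npair < pair_floor):
                raise ValueError("pairwise complete cases below floor for some pair")
            Em = np.where(miss, 0.0, E)
            cov_raw[t] = (Em * wt[:, None]).T @ Em / WW
            if mode == "local_regression":
                iu, ju = np.triu_indices(I)
                for i, j in zip(iu, ju):
                    ok = ~(miss[:, i] | miss[:, j])
                    c = local_quadratic_fit(E[ok, i] * E[ok, j], a[ok],
                                            weights.grid.points[t], wt[ok])
                    cov_raw[t, i, j] = cov_raw[t, j, i] = c[0]

    cov = cov_raw.copy()
    if pd:
        for t in range(T):
            repaired = repair_positive_definite(cov_raw[t], pd_floor)
            pd_flags[t] = not np.allclose(repaired, cov_raw[t])
            cov[t] = repaired

    return LocalMoments(grid=weights.grid, mean_coef=mean_coef, cov=cov,
                        cov_raw=cov_raw, W=weights.W.copy(), pd_repaired=pd_flags,
                        mode=mode, residualize=residualize,
                        indicator_names=list(indicator_names or []))


def repair_positive_definite(S: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Nearest-style positive-definite repair by eigenvalue clipping.

    Eigenvalues below ``floor * max_eigenvalue`` are raised to that level and
    the matrix is reassembled; the diagonal is then rescaled back to the
    input diagonal so variances are preserved.  Positive definite inputs
    (relative to the floor) are returned unchanged.
    """
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    vals, vecs = np.linalg.eigh(S)
    vmax = vals[-1]
    if vmax <= 0:
        return floor * np.eye(S.shape[0])
    lo = floor * vmax
    if vals[0] >= lo:
        return S.copy()
    vals = np.maximum(vals, lo)
    R = (vecs * vals) @ vecs.T
    d_old = np.diag(S)
    d_new = np.diag(R)
    scale = np.sqrt(np.where((d_old > 0) & (d_new > 0), d_old / d_new, 1.0))
    return R * scale[:, None] * scale[None, :]


def grid_density(weights: WeightMatrix) -> np.ndarray:
    """f̂(a_t) = W_t / Σ_s W_s over the retained focal points."""
    if np.any(weights.W <= 0):
        raise ValueError("focal point with nonpositive weight sum")
    return weights.f_hat
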