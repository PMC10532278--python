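"""Maximum-likelihood covariance-structure fitting.

This is the shared numerical engine behind every estimator in the package:
a single-group SEM is the one-group case, a multiple-group model is the
G-group case with group weights N_g, and joint locally weighted estimation is
the T-group case with kernel weight sums W_t as group weights.

The fitting function is the (weighted) ML discrepancy

    F(theta) = sum_g n_g * [ log|Sigma_g(theta)| + tr(S_g Sigma_g(theta)^-1)
                             - log|S_g| - I ]

minimized by L-BFGS-B with an analytic gradient.  Cross-group structure
(invariance, polynomial trends across groups, fixed values) is expressed by a
linear parameter mapping: the full per-group parameter matrix Theta (G x P)
is an affine function of the free vector u.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .modelspec import BETA, LAMBDA, PHI, PSI, ModelSpec, Parameter

__all__ = [
    "CompiledModel",
    "ParameterMapping",
    "FitResult",
    "implied_covariance",
    "ml_discrepancy",
    "fit_groups",
    "fit_statistics",
    "standardize_solution",
    "ConvergenceError",
]

_PENALTY = 1e10


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# compiled covariance structure
# ---------------------------------------------------------------------------

class CompiledModel:
    """A :class:`ModelSpec` compiled to fast batched matrix operations.

    All public methods accept a parameter matrix ``Theta`` of shape (G, P)
    where P is the number of free parameters (in ``spec.free_labels`` order)
    and G the number of groups, and operate on stacked (G, ., .) arrays.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.I = spec.n_indicators
        self.K = spec.n_factors
        free = spec.free_parameters
        self.free_labels = [p.label for p in free]
        self.P = len(free)

        # base matrices with fixed values filled in
        self._lam0 = np.zeros((self.I, self.K))
        self._b0 = np.zeros((self.K, self.K))
        self._phi0 = np.zeros((self.K, self.K))
        self._psi0 = np.zeros((self.I, self.I))
        for p in spec.parameters:
            if p.free:
                continue
            m = {LAMBDA: self._lam0, BETA: self._b0,
                 PHI: self._phi0, PSI: self._psi0}[p.matrix]
            m[p.row, p.col] = p.value
            if p.matrix in (PHI, PSI):
                m[p.col, p.row] = p.value

        # index arrays per matrix for free parameters
        def _idx(matrix):
            sel = [(j, p) for j, p in enumerate(free) if p.matrix == matrix]
            js = np.array([j for j, _ in sel], dtype=int)
            rs = np.array([p.row for _, p in sel], dtype=int)
            cs = np.array([p.col for _, p in sel], dtype=int)
            return js, rs, cs

        self._ilam = _idx(LAMBDA)
        self._ib = _idx(BETA)
        self._iphi = _idx(PHI)
        self._ipsi = _idx(PSI)
        self.has_beta = self._ib[0].size > 0 or np.any(self._b0 != 0)
        self.variance_mask = np.array([p.is_variance for p in free])

    # -- matrix construction -----------------------------------------------
    def matrices(self, Theta: np.ndarray):
        Theta = np.atleast_2d(Theta)
        G = Theta.shape[0]
        lam = np.broadcast_to(self._lam0, (G, self.I, self.K)).copy()
        b = np.broadcast_to(self._b0, (G, self.K, self.K)).copy()
        phi = np.broadcast_to(self._phi0, (G, self.K, self.K)).copy()
        psi = np.broadcast_to(self._psi0, (G, self.I, self.I)).copy()
        j, r, c = self._ilam
        lam[:, r, c] = Theta[:, j]
        j, r, c = self._ib
        b[:, r, c] = Theta[:, j]
        j, r, c = self._iphi
        phi[:, r, c] = Theta[:, j]
        phi[:, c, r] = Theta[:, j]
        j, r, c = self._ipsi
        psi[:, r, c] = Theta[:, j]
        psi[:, c, r] = Theta[:, j]
        return lam, b, phi, psi

    def implied(self, Theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance matrices, shape (G, I, I)."""
        Sig, *_ = self._implied_cache(Theta)
        return Sig

    def _implied_cache(self, Theta):
        lam, b, phi, psi = self.matrices(Theta)
        if self.has_beta:
            eye = np.eye(self.K)
            Gm = np.linalg.inv(eye - b)          # (I - B)^-1
            C = lam @ Gm
        else:
            Gm = None
            C = lam
        CP = C @ phi
        Sig = CP @ np.swapaxes(C, -1, -2) + psi
        return Sig, lam, phi, Gm, C, CP

    # -- objective + gradient ----------------------------------------------
    def discrepancies(self, Theta, S, logdetS):
        """Per-group ML discrepancies D(S_g, Sigma_g(Theta_g)); +inf if non-PD."""
        Sig = self.implied(Theta)
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
        Sinv = np.linalg.inv(Sig)
        tr = np.einsum("gij,gji->g", S, Sinv)
        return logdet + tr - logdetS - self.I

    def value_and_grad(self, Theta, S, logdetS, weights):
        """Weighted objective sum_g w_g D_g and its gradient dF/dTheta (G, P).

        Returns ``(None, None)`` when any implied matrix fails the Cholesky
        factorization (caller turns this into a line-search penalty).
        """
        Sig, lam, phi, Gm, C, CP = self._implied_cache(Theta)
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return None, None
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
        Sinv = np.linalg.inv(Sig)
        D = logdet + np.einsum("gij,gji->g", S, Sinv) - logdetS - self.I
        F = float(np.dot(weights, D))

        # A_g = Sigma^-1 - Sigma^-1 S Sigma^-1  (gradient kernel)
        A = Sinv - Sinv @ S @ Sinv
        Gmat = np.zeros(Theta.shape)
        j, r, c = self._ilam
        if j.size:
            if Gm is None:
                M = A @ CP
            else:
                M = A @ CP @ np.swapaxes(Gm, -1, -2)
            Gmat[:, j] = 2.0 * M[:, r, c]
        j, r, c = self._iphi
        if j.size:
            M = np.swapaxes(C, -1, -2) @ A @ C
            fac = np.where(r == c, 1.0, 2.0)
            Gmat[:, j] = fac * M[:, r, c]
        j, r, c = self._ipsi
        if j.size:
            fac = np.where(r == c, 1.0, 2.0)
            Gmat[:, j] = fac * A[:, r, c]
        j, r, c = self._ib
        if j.size:
            # d tr(A dSigma)/d b_{kl} = 2 [G Phi C^T A Lam G]_{l k}
            M = Gm @ phi @ np.swapaxes(C, -1, -2) @ A @ lam @ Gm
            Gmat[:, j] = 2.0 * M[:, c, r]
        Gmat *= weights[:, None]
        return F, Gmat


def implied_covariance(spec: ModelSpec, theta: dict[str, float] | np.ndarray) -> np.ndarray:
    """Model-implied covariance Σ(θ) for one parameter vector."""
    cm = CompiledModel(spec)
    vec = _as_vector(cm, theta)
    return cm.implied(vec[None, :])[0]


def _as_vector(cm: CompiledModel, theta) -> np.ndarray:
    if isinstance(theta, dict):
        missing = [l for l in cm.free_labels if l not in theta]
        if missing:
            raise ValueError(f"theta missing labels {missing}")
        return np.array([theta[l] for l in cm.free_labels], dtype=float)
    vec = np.asarray(theta, dtype=float)
    if vec.shape != (cm.P,):
        raise ValueError(f"expected {cm.P} parameter values, got {vec.shape}")
    return vec


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy D(S, Σ) = log|Σ| + tr(SΣ⁻¹) − log|S| − I (≥ 0)."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    I = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0 or np.any(np.linalg.eigvalsh(S) <= 0) \
            or np.any(np.linalg.eigvalsh(Sigma) <= 0):
        raise ValueError("ml_discrepancy requires positive definite inputs")
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - I)


# ---------------------------------------------------------------------------
# parameter mapping (cross-group constraint classes)
# ---------------------------------------------------------------------------

FOCAL, INVARIANT = "focal", "invariant"


def _poly_basis(G: int, degree: int, n_segments: int = 1) -> np.ndarray:
    """Polynomial / piecewise-polynomial basis over group index 1..G.

    Piecewise variants use a truncated-power spline basis with knots at
    equal-length block boundaries, which keeps the curve continuous (and,
    for the quadratic, continuously differentiable) across segments.
    """
    t = np.arange(G, dtype=float)
    if G > 1:
        t = (t - t.mean()) / (t.max() - t.min())  # scaled for conditioning
    cols = [np.ones(G)]
    for d in range(1, degree + 1):
        cols.append(t ** d)
    if n_segments > 1:
        knots = np.quantile(t, np.arange(1, n_segments) / n_segments)
        for kn in knots:
            cols.append(np.maximum(t - kn, 0.0) ** degree)
    return np.column_stack(cols)


@dataclass
class ParameterMapping:
    """Affine map u -> Theta (G x P) realizing cross-group constraints.

    Each free model parameter (column p of Theta) has a class:

    * ``focal`` — one value per group (G coordinates of u),
    * ``invariant`` — a single shared value,
    * ``linear`` / ``quadratic`` — polynomial trend over the (equidistant)
      group index, per Eq.-style first/second difference equalities,
    * piecewise variants thereof (``n_segments`` > 1).
    """

    n_groups: int
    labels: list[str]
    classes: dict[str, str]                      # label -> class
    bases: list[np.ndarray] = field(default_factory=list)   # per column
    slices: list[slice] = field(default_factory=list)
    n_free: int = 0

    @classmethod
    def build(cls, labels: list[str], n_groups: int,
              par_invariant=(), par_linear=(), par_quadratic=(),
              pw_linear: int = 1, pw_quadratic: int = 1) -> "ParameterMapping":
        par_invariant = set(par_invariant)
        par_linear = set(par_linear)
        par_quadratic = set(par_quadratic)
        overlap = (par_invariant & par_linear) | (par_invariant & par_quadratic) \
            | (par_linear & par_quadratic)
        if overlap:
            raise ValueError(f"parameters in more than one constraint class: {overlap}")
        unknown = (par_invariant | par_linear | par_quadratic) - set(labels)
        if unknown:
            raise ValueError(f"constraint on unknown parameter label(s): {sorted(unknown)}")
        classes = {}
        for lab in labels:
            if lab in par_invariant:
                classes[lab] = INVARIANT
            elif lab in par_linear:
                classes[lab] = "linear"
            elif lab in par_quadratic:
                classes[lab] = "quadratic"
            else:
                classes[lab] = FOCAL
        mp = cls(n_groups=n_groups, labels=list(labels), classes=classes)
        pos = 0
        for lab in labels:
            cl = classes[lab]
            if cl == FOCAL:
                basis = np.eye(n_groups)
            elif cl == INVARIANT:
                basis = np.ones((n_groups, 1))
            elif cl == "linear":
                basis = _poly_basis(n_groups, 1, pw_linear)
            else:
                basis = _poly_basis(n_groups, 2, pw_quadratic)
            mp.bases.append(basis)
            mp.slices.append(slice(pos, pos + basis.shape[1]))
            pos += basis.shape[1]
        mp.n_free = pos
        return mp

    def theta(self, u: np.ndarray) -> np.ndarray:
        Theta = np.empty((self.n_groups, len(self.labels)))
        for p, (basis, sl) in enumerate(zip(self.bases, self.slices)):
            Theta[:, p] = basis @ u[sl]
        return Theta

    def chain(self, Gmat: np.ndarray) -> np.ndarray:
        g = np.empty(self.n_free)
        for p, (basis, sl) in enumerate(zip(self.bases, self.slices)):
            g[sl] = basis.T @ Gmat[:, p]
        return g

    def u_from_theta(self, Theta: np.ndarray) -> np.ndarray:
        u = np.empty(self.n_free)
        for p, (basis, sl) in enumerate(zip(self.bases, self.slices)):
            u[sl] = np.linalg.lstsq(basis, Theta[:, p], rcond=None)[0]
        return u

    def bounds(self, variance_mask: np.ndarray, floor: float = 1e-8):
        """Box bounds on u: positivity floor where a coordinate maps one-to-one
        onto a variance parameter (focal/invariant classes)."""
        lb = np.full(self.n_free, -np.inf)
        for p, lab in enumerate(self.labels):
            if variance_mask[p] and self.classes[lab] in (FOCAL, INVARIANT):
                lb[self.slices[p]] = floor
        return [(l, np.inf) for l in lb]


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Minimizer of the weighted multi-group ML discrepancy."""

    spec: ModelSpec
    labels: list[str]
    theta: np.ndarray          # (G, P) per-group free parameter values
    u: np.ndarray              # reduced free vector
    mapping: ParameterMapping
    discrepancy: float         # sum_g w_g D_g at the optimum
    group_discrepancies: np.ndarray
    weights: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    S: np.ndarray              # (G, I, I) sample/conditional covariances

    @property
    def n_groups(self) -> int:
        return self.theta.shape[0]

    def theta_dict(self, g: int = 0) -> dict[str, float]:
        return dict(zip(self.labels, self.theta[g]))

    def implied(self) -> np.ndarray:
        return CompiledModel(self.spec).implied(self.theta)

    def fit_statistics(self, effective_n: float | None = None) -> dict[str, float]:
        return fit_statistics(self, effective_n)

    def standardized(self) -> np.ndarray:
        return standardize_solution(self.spec, self.theta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _start_values(cm: CompiledModel, S: np.ndarray) -> np.ndarray:
    """Standard SEM start values: loadings 0.7, variances from S diagonals,
    covariances and regressions 0."""
    Sbar = S.mean(axis=0)
    spec = cm.spec
    theta0 = np.zeros(cm.P)
    # indicator sets per factor for variance starts
    fac_ind: dict[int, list[int]] = {}
    for p in spec.parameters:
        if p.matrix == LAMBDA:
            fac_ind.setdefault(p.col, []).append(p.row)
    for j, p in enumerate(spec.free_parameters):
        if p.matrix == LAMBDA:
            theta0[j] = 0.7
        elif p.matrix == PSI and p.row == p.col:
            theta0[j] = 0.5 * Sbar[p.row, p.row]
        elif p.matrix == PHI and p.row == p.col:
            inds = fac_ind.get(p.row, [])
            theta0[j] = 0.5 * np.mean([Sbar[i, i] for i in inds]) if inds else 0.5
        else:
            theta0[j] = 0.0
    return theta0


def fit_groups(spec: ModelSpec,
               covariances: list[tuple[np.ndarray, float]] | None = None,
               *,
               S: np.ndarray | None = None,
               weights: np.ndarray | None = None,
               par_invariant=(), par_linear=(), par_quadratic=(),
               pw_linear: int = 1, pw_quadratic: int = 1,
               mapping: ParameterMapping | None = None,
               start: np.ndarray | None = None,
               gtol: float = 1e-8, ftol: float = 1e-13,
               maxiter: int = 1000, n_restarts: int = 3,
               rng: np.random.Generator | None = None) -> FitResult:
    """Minimize the weighted ML discrepancy over G groups.

    ``covariances`` is a list of ``(S_g, n_g)`` pairs (alternatively pass the
    stacked array ``S`` plus ``weights``).  Cross-group equality and
    polynomial constraints are given either as label lists or as a prebuilt
    :class:`ParameterMapping`.

    The optimizer works on the weight-normalized objective
    ``F / sum(weights)``; ``gtol`` applies to its projected gradient.
    """
    cm = CompiledModel(spec)
    if covariances is not None:
        S = np.stack([np.asarray(s, float) for s, _ in covariances])
        weights = np.array([float(n) for _, n in covariances])
    S = np.asarray(S, float)
    if S.ndim == 2:
        S = S[None]
    weights = np.ones(S.shape[0]) if weights is None else np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValueError("group weights must be positive")
    G = S.shape[0]

    sign, logdetS = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        raise ValueError("all sample covariance matrices must be positive definite")

    if mapping is None:
        mapping = ParameterMapping.build(
            cm.free_labels, G, par_invariant, par_linear, par_quadratic,
            pw_linear, pw_quadratic)

    wsum = weights.sum()
    wn = weights / wsum

    def fun(u):
        Theta = mapping.theta(u)
        F, Gmat = cm.value_and_grad(Theta, S, logdetS, wn)
        if F is None:  # non-PD implied matrix: penalty forces backtracking
            return _PENALTY * (1.0 + np.dot(u, u)), np.zeros_like(u)
        return F, mapping.chain(Gmat)

    if start is not None:
        u0 = start if start.shape == (mapping.n_free,) else mapping.u_from_theta(
            np.atleast_2d(start) if start.ndim == 2 else
            np.broadcast_to(start, (G, cm.P)))
    else:
        theta0 = _start_values(cm, S)
        u0 = mapping.u_from_theta(np.broadcast_to(theta0, (G, cm.P)).copy())

    bounds = mapping.bounds(cm.variance_mask)
    rng = rng or np.random.default_rng(0)

    best = None
    u_try = u0
    for attempt in range(n_restarts + 1):
        res = minimize(fun, u_try, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol})
        gnorm = float(np.max(np.abs(res.jac)))
        ok = res.fun < _PENALTY / 2 and (res.success or gnorm < 10 * gtol)
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm, ok)
        if ok:
            break
        # jittered restart
        u_try = u0 * (1 + 0.1 * rng.standard_normal(u0.size)) \
            + 0.05 * rng.standard_normal(u0.size)
    res, gnorm, ok = best
    if not ok:
        warnings.warn("fit_groups did not converge "
                      f"(gradient max-norm {gnorm:.2e} after restarts)",
                      RuntimeWarning, stacklevel=2)

    Theta = mapping.theta(res.x)
    D = cm.discrepancies(Theta, S, logdetS)
    if D is None:
        raise ConvergenceError("optimum has non-positive-definite implied covariance")
    return FitResult(spec=spec, labels=cm.free_labels, theta=Theta, u=res.x,
                     mapping=mapping, discrepancy=float(np.dot(weights, D)),
                     group_discrepancies=D, weights=weights,
                     converged=ok, n_iter=int(res.nit), grad_norm=gnorm, S=S)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def fit_statistics(fit: FitResult, effective_n: float | None = None) -> dict[str, float]:
    """Global fit statistics for a (weighted) multi-group solution.

    chi2 is the weighted discrepancy sum; the baseline for CFI/TLI is the
    per-group diagonal (independence) covariance model, for which the ML
    solution is diag(S_g) in closed form.  With kernel weights as group
    weights, the effective N counts subjects with their kernel multiplicity,
    so these statistics are approximate (the objective is an M-estimation,
    not an ML, fitting function).
    """
    S, w = fit.S, fit.weights
    G, I = S.shape[0], S.shape[1]
    n = float(w.sum()) if effective_n is None else float(effective_n)
    P_free = fit.mapping.n_free
    df = G * I * (I + 1) // 2 - P_free

    chi2 = fit.discrepancy
    # baseline: diagonal covariance model
    sign, logdetS = np.linalg.slogdet(S)
    logdet_diag = np.sum(np.log(np.diagonal(S, axis1=1, axis2=2)), axis=1)
    D_base = logdet_diag - logdetS
    chi2_base = float(np.dot(w, D_base))
    df_base = G * I * (I + 1) // 2 - G * I

    if df > 0:
        rmsea = math.sqrt(max(0.0, (chi2 - df) / (df * n)))
    else:
        rmsea = 0.0
    denom = max(chi2 - df, chi2_base - df_base, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    if df > 0 and df_base > 0 and chi2_base / df_base > 1.0:
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = 1.0

    Sig = fit.implied()
    d = np.sqrt(np.diagonal(S, axis1=1, axis2=2))
    scale = d[:, :, None] * d[:, None, :]
    Rres = (S - Sig) / scale
    iu = np.tril_indices(I)
    srmr_g = np.sqrt(np.mean(Rres[:, iu[0], iu[1]] ** 2, axis=1))
    srmr = float(np.dot(w, srmr_g) / w.sum())

    Sinv_S = np.linalg.solve(Sig, S)
    eye = np.eye(I)
    gfi_g = 1.0 - np.einsum("gij,gji->g", Sinv_S - eye, Sinv_S - eye) \
        / np.einsum("gij,gji->g", Sinv_S, Sinv_S)
    gfi = float(np.dot(w, gfi_g) / w.sum())

    return {"chi2": chi2, "df": df, "effective_n": n, "rmsea": rmsea,
            "srmr": srmr, "cfi": min(cfi, 1.0), "tli": tli, "gfi": gfi,
            "chi2_baseline": chi2_base, "df_baseline": df_base}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_solution(spec: ModelSpec, Theta: np.ndarray) -> np.ndarray:
    """Fully standardized solution (correlation metric), per group.

    Loadings are scaled by factor SD / indicator SD, factor covariances
    become correlations, residual (co)variances are scaled by indicator SDs,
    regressions by predictor SD / outcome SD.  Returns an array shaped like
    ``Theta`` with the standardized value of every free parameter.
    """
    cm = CompiledModel(spec)
    Theta = np.atleast_2d(Theta)
    lam, b, phi, psi = cm.matrices(Theta)
    if cm.has_beta:
        Gm = np.linalg.inv(np.eye(cm.K) - b)
        Veta = Gm @ phi @ np.swapaxes(Gm, -1, -2)
        C = lam @ Gm
    else:
        Veta = phi
        C = lam
    Sig = C @ phi @ np.swapaxes(C, -1, -2) + psi if cm.has_beta else \
        lam @ phi @ np.swapaxes(lam, -1, -2) + psi
    sd_eta = np.sqrt(np.diagonal(Veta, axis1=-2, axis2=-1))
    sd_x = np.sqrt(np.diagonal(Sig, axis1=-2, axis2=-1))
    if np.any(sd_eta <= 0) or np.any(sd_x <= 0):
        raise ValueError("zero implied variance; cannot standardize")

    out = np.empty_like(Theta)
    for j, p in enumerate(spec.free_parameters):
        if p.matrix == LAMBDA:
            out[:, j] = lam[:, p.row, p.col] * sd_eta[:, p.col] / sd_x[:, p.row]
        elif p.matrix == PHI:
            out[:, j] = Veta[:, p.row, p.col] / (sd_eta[:, p.row] * sd_eta[:, p.col])
        elif p.matrix == PSI:
            out[:, j] = psi[:, p.row, p.col] / (sd_x[:, p.row] * sd_x[:, p.col])
        else:  # BETA
            out[:, j] = b[:, p.row, p.col] * sd_eta[:, p.col] / sd_eta[:, p.row]
    return out
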