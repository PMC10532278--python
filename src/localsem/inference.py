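"""Inference for parameter curves: bootstrap resampling, the bias-corrected
standard-deviation test, Wald tests, and the permutation test.

A parameter curve θ̂(a_1) … θ̂(a_T) is summarized by its density-weighted
mean M̂ = Σ_t f̂(a_t) θ̂(a_t) and SD, SD̂ = sqrt(Σ_t f̂(a_t)(θ̂(a_t) − M̂)²).
SD̂ is positively biased under the null of a flat curve; the bootstrap bias
correction subtracts the resampling bias of SD̂² and clamps at zero:

    SD̂_bc = sqrt( max(0, 2 SD̂² − mean_r SD̂*_r²) ).

The t statistic SD̂_bc / SE (SE = resampling SD of SD̂*) is referred to a
one-sided normal tail.  The Wald test contrasts the curve values with a
first-difference matrix H and the bootstrap covariance V of the curve:
χ² = (Hξ̂)ᵀ(H V Hᵀ)⁻¹(Hξ̂) with T − 1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["curve_mean_sd", "sd_bias_corrected", "sd_test",
           "wald_equality_test", "wald_functional_test", "WaldResult",
           "bootstrap", "LSEMBootstrapResults",
           "permutation_test", "PermutationResult"]


# ---------------------------------------------------------------------------
# curve summaries
# ---------------------------------------------------------------------------

def curve_mean_sd(curve: np.ndarray, f_hat: np.ndarray) -> tuple[float, float]:
    """Weighted mean and standard deviation of a parameter curve."""
    curve = np.asarray(curve, float)
    f = np.asarray(f_hat, float)
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("focal-point density weights must sum to 1")
    M = float(np.dot(f, curve))
    if np.ptp(curve) == 0.0:        # exactly flat (e.g. invariant parameter)
        return M, 0.0
    SD = float(np.sqrt(np.dot(f, (curve - M) ** 2)))
    return M, SD


def sd_bias_corrected(sd_hat: float, sd_reps: np.ndarray,
                      repl_factor: float | None = None) -> tuple[float, float]:
    """Bias-corrected curve SD and its resampling standard error.

    The bootstrap bias of SD̂² is B̂ = mean(SD*²) − SD̂²; the corrected
    estimate is sqrt+(SD̂² − B̂).  ``repl_factor`` scales the squared SE
    (1/R for the bootstrap, 1 or (R−1)/R for jackknife-style designs).
    """
    sd_reps = np.asarray(sd_reps, float)
    R = sd_reps.size
    if R < 2:
        raise ValueError("need at least 2 replicates")
    if repl_factor is None:
        repl_factor = 1.0 / R
    bias = float(np.mean(sd_reps ** 2)) - sd_hat ** 2
    sd_bc = float(np.sqrt(max(0.0, sd_hat ** 2 - bias)))
    se = float(np.sqrt(repl_factor * R * np.var(sd_reps)))
    return sd_bc, se


def sd_test(sd_bc: float, se: float) -> tuple[float, float]:
    """One-sided normal test of curve variation: t = SD̂_bc / SE."""
    if se <= 0:
        return np.nan, np.nan   # undefined test (e.g. invariant parameter)
    t = sd_bc / se
    return float(t), float(stats.norm.sf(t))


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------

@dataclass
class WaldResult:
    chi2: float
    df: int
    p: float
    H: np.ndarray
    coef: np.ndarray | None = None   # GLS coefficients for functional tests


def _quadratic_form(r: np.ndarray, C: np.ndarray) -> tuple[float, int]:
    """r' C^-1 r with pseudo-inverse fallback and rank-adjusted df."""
    try:
        L = np.linalg.cholesky(C)
        x = np.linalg.solve(L, r)
        return float(x @ x), r.size
    except np.linalg.LinAlgError:
        warnings.warn("singular contrast covariance; using pseudo-inverse "
                      "with rank-adjusted df", RuntimeWarning, stacklevel=2)
        Cp = np.linalg.pinv(C)
        return float(r @ Cp @ r), int(np.linalg.matrix_rank(C))


def wald_equality_test(xi: np.ndarray, V: np.ndarray,
                       H: np.ndarray | None = None) -> WaldResult:
    """Wald test of a flat parameter curve (H ξ = 0, H = first differences)."""
    xi = np.asarray(xi, float)
    T = xi.size
    if H is None:
        H = np.diff(np.eye(T), axis=0)          # (T-1, T) first differences
    r = H @ xi
    C = H @ V @ H.T
    chi2, df = _quadratic_form(r, C)
    return WaldResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), H=H)


def _hypothesis_design(a_t: np.ndarray, hypothesis) -> np.ndarray:
    """Design matrix [1, terms...] from e.g. "m + m^2" or a degree int."""
    m = np.asarray(a_t, float)
    if isinstance(hypothesis, int):
        degrees = list(range(1, hypothesis + 1))
    else:
        degrees = []
        for term in str(hypothesis).replace("I(", "").replace(")", "").split("+"):
            term = term.strip()
            if term in ("m", "a"):
                degrees.append(1)
            elif "^" in term:
                degrees.append(int(term.split("^")[1]))
            elif term:
                raise ValueError(f"cannot parse hypothesis term {term!r}")
    cols = [np.ones_like(m)] + [m ** d for d in degrees]
    return np.column_stack(cols)


def wald_functional_test(xi: np.ndarray, a_t: np.ndarray, V: np.ndarray,
                         hypothesis="m + m^2") -> WaldResult:
    """GLS regression of the curve on polynomial moderator terms and a Wald
    test that all non-intercept coefficients vanish."""
    X = _hypothesis_design(a_t, hypothesis)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient hypothesis design matrix")
    Vi = np.linalg.pinv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ np.asarray(xi, float))
    cov_b = np.linalg.inv(A)
    b1 = beta[1:]
    chi2, df = _quadratic_form(b1, cov_b[1:, 1:])
    return WaldResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
                      H=X, coef=beta)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _refit(results, X, a, sampling_weights=None):
    """Re-run moments + estimation on replicate rows, warm-started.

    Resampling noise dwarfs the last optimizer digits, so replicate fits run
    at a slightly looser gradient tolerance than the main fit.
    """
    model = results.model
    gtol = max(model.gtol, 1e-7)
    mom = model._recompute_moments(X, a, sampling_weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if results.mode == "pointwise":
            rep = model.fit(mode="pointwise", moments=mom, gtol=gtol)
            ok = bool(rep.pointwise_converged.all())
        else:
            start = results.fit.u if results.fit is not None else None
            rep = model.fit(mode="joint", moments=mom,
                            est_dif=results.dif is not None, start=start,
                            gtol=gtol)
            ok = rep.fit.converged
    return rep, ok


def _collect(rep) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(raw curves (P,T), standardized (P,T), dif (Pd,T)) of one replicate."""
    th = rep.theta.T
    std = rep.standardized.T
    dif = rep.dif.to_numpy().T if rep.dif is not None else np.empty((0, th.shape[1]))
    return th, std, dif


class LSEMBootstrapResults:
    """Replicate parameter curves and the inference built on them."""

    def __init__(self, results, reps_raw, reps_std, reps_dif, reps_f,
                 design: str, repl_factor: float, seed, n_dropped: int):
        self.results = results
        self.reps_raw = reps_raw        # (R, P, T)
        self.reps_std = reps_std
        self.reps_dif = reps_dif        # (R, Pd, T)
        self.reps_f = reps_f            # (R, T) replicate focal densities
        self.design = design
        self.repl_factor = repl_factor
        self.seed = seed
        self.n_dropped = n_dropped

    @property
    def R(self) -> int:
        return self.reps_raw.shape[0]

    def _rep_curves(self, label, standardized=False, dif=False) -> np.ndarray:
        if dif:
            cols = list(self.results.dif.columns)
            return self.reps_dif[:, cols.index(label), :]
        j = self.results.labels.index(label)
        return (self.reps_std if standardized else self.reps_raw)[:, j, :]

    def V(self, label: str, standardized: bool = False,
          dif: bool = False) -> np.ndarray:
        """repl_factor-scaled cross-replicate covariance of the curve."""
        Xi = self._rep_curves(label, standardized, dif)
        d = Xi - Xi.mean(axis=0)
        return self.repl_factor * (d.T @ d)

    def pointwise_se(self, label: str, standardized: bool = False,
                     dif: bool = False) -> np.ndarray:
        Xi = self._rep_curves(label, standardized, dif)
        return np.sqrt(self.repl_factor * self.R * np.var(Xi, axis=0))

    def _is_degenerate(self, label, standardized, dif):
        """Invariance-constrained raw curves are flat by construction."""
        return (not dif and not standardized
                and label in self.results.model.par_invariant)

    def _summary_row(self, label, standardized, dif):
        res = self.results
        curve = res.curve(label, standardized=standardized, dif=dif)
        M, SD = curve_mean_sd(curve, res.f_hat)
        if self._is_degenerate(label, standardized, dif):
            # exactly zero variation in every replicate: test undefined
            return M, 0.0, 0.0, 0.0, np.nan, np.nan
        Xi = self._rep_curves(label, standardized, dif)
        Ms = np.einsum("rt,rt->r", self.reps_f, Xi)
        sd_reps = np.sqrt(np.einsum("rt,rt->r", self.reps_f,
                                    (Xi - Ms[:, None]) ** 2))
        sd_bc, se = sd_bias_corrected(SD, sd_reps, self.repl_factor)
        t, p = sd_test(sd_bc, se)
        return M, SD, sd_bc, se, t, p

    def curve_summary(self, include_std: bool = True,
                      wald: bool = False) -> pd.DataFrame:
        """Per-parameter summary: M, SD, SD_bc, SE, t, p (plus Wald columns).

        Standardized rows (prefix ``std``) are added for factor covariances —
        the correlation metric in which structural hypotheses are usually
        read; DIF rows carry the ``dif`` prefix.
        """
        res = self.results
        rows = []

        def add(name, label, standardized, dif):
            M, SD, sd_bc, se, t, p = self._summary_row(label, standardized, dif)
            row = {"parameter": name, "M": M, "SD": SD, "SD_bc": sd_bc,
                   "SE": se, "t": t, "p": p}
            if wald:
                if self._is_degenerate(label, standardized, dif):
                    row.update({"wald_chi2": 0.0, "wald_df": 0, "wald_p": np.nan})
                else:
                    w = self.wald_equality(label, standardized=standardized, dif=dif)
                    row.update({"wald_chi2": w.chi2, "wald_df": w.df, "wald_p": w.p})
            rows.append(row)

        inv = set(res.model.par_invariant)
        for lab in res.labels:
            add(lab, lab, False, False)
        if include_std:
            for p_ in res.model.spec.free_parameters:
                if p_.matrix == "phi" and p_.row != p_.col:
                    add(f"std {p_.label}", p_.label, True, False)
        if res.dif is not None:
            for lab in res.dif.columns:
                add(f"dif {lab}", lab, False, True)
        df = pd.DataFrame(rows)
        df.attrs["invariant"] = sorted(inv)
        return df

    def wald_equality(self, label: str, standardized: bool = False,
                      dif: bool = False) -> WaldResult:
        xi = self.results.curve(label, standardized=standardized, dif=dif)
        return wald_equality_test(xi, self.V(label, standardized, dif))

    def wald_functional(self, label: str, hypothesis="m + m^2",
                        standardized: bool = False, dif: bool = False) -> WaldResult:
        xi = self.results.curve(label, standardized=standardized, dif=dif)
        return wald_functional_test(xi, self.results.grid.points,
                                    self.V(label, standardized, dif), hypothesis)


def _resample_indices(rng: np.random.Generator, N: int,
                      cluster_ids: np.ndarray | None = None) -> np.ndarray:
    """Row indices of one bootstrap replicate: subjects with replacement, or
    whole clusters with replacement when cluster ids are given (so every
    replicate's rows partition into original clusters)."""
    if cluster_ids is None:
        return rng.integers(0, N, N)
    uniq = np.unique(cluster_ids)
    chosen = rng.choice(uniq, size=uniq.size, replace=True)
    members = {u: np.flatnonzero(cluster_ids == u) for u in uniq}
    return np.concatenate([members[c] for c in chosen])


def bootstrap(results, R: int = 200, seed: int | None = None,
              design: str = "nonparametric", cluster: np.ndarray | None = None,
              repl_design: np.ndarray | None = None,
              repl_factor: float | None = None,
              max_failure_rate: float = 0.2) -> LSEMBootstrapResults:
    """Resampling inference for fitted parameter curves.

    design
        ``"nonparametric"`` resamples subjects with replacement;
        ``"cluster"`` resamples whole clusters (ids from the model's
        ``cluster`` column or the ``cluster`` argument); ``"repl_design"``
        applies the columns of a user N×R replicate-weight matrix, with a
        user ``repl_factor`` for correct scaling (1/R for bootstrap-like,
        1 or (R−1)/R for jackknife-like designs).
    """
    if R < 2:
        raise ValueError("R must be at least 2")
    model = results.model
    rng = np.random.default_rng(seed)
    N = model.N

    if design == "repl_design":
        if repl_design is None:
            raise ValueError("repl_design matrix required")
        repl_design = np.asarray(repl_design, float)
        if repl_design.shape[0] != N:
            raise ValueError("repl_design must have one row per subject")
        R = repl_design.shape[1]
        if repl_factor is None:
            raise ValueError("repl_factor must be given for repl_design")
    elif design == "cluster":
        ids = model.cluster if cluster is None else np.asarray(cluster)
        if ids is None or len(ids) != N:
            raise ValueError("cluster ids covering all rows are required")
    elif design != "nonparametric":
        raise ValueError(f"unknown bootstrap design {design!r}")
    if repl_factor is None:
        repl_factor = 1.0 / R

    reps_raw, reps_std, reps_dif, reps_f = [], [], [], []
    dropped = 0
    for r in range(R):
        if design == "repl_design":
            sw = repl_design[:, r]
            if model.sampling_weights is not None:
                sw = sw * model.sampling_weights
            X, a = model.X, model.a
        else:
            idx = _resample_indices(rng, N, ids if design == "cluster" else None)
            X, a = model.X[idx], model.a[idx]
            sw = (model.sampling_weights[idx]
                  if model.sampling_weights is not None else None)
        try:
            rep, ok = _refit(results, X, a, sw)
        except Exception:
            ok = False
        if not ok:
            dropped += 1
            continue
        th, std, dif = _collect(rep)
        reps_raw.append(th)
        reps_std.append(std)
        reps_dif.append(dif)
        reps_f.append(rep.f_hat)

    if dropped > max_failure_rate * R:
        raise RuntimeError(
            f"bootstrap aborted: {dropped}/{R} replicates failed to converge")
    return LSEMBootstrapResults(results, np.array(reps_raw), np.array(reps_std),
                                np.array(reps_dif), np.array(reps_f),
                                design=design, repl_factor=repl_factor,
                                seed=seed, n_dropped=dropped)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null distribution of curve SDs under random moderator reassignment."""

    summary: pd.DataFrame          # parameter, SD_obs, p
    sd_null: pd.DataFrame          # (B, n_param) permuted curve SDs
    B: int
    seed: int | None
    n_dropped: int


def permutation_test(results, B: int = 1000, seed: int | None = None,
                     include_dif: bool = True,
                     max_failure_rate: float = 0.2) -> PermutationResult:
    """Permutation test of parameter variation.

    Each replicate randomly permutes the moderator column (its multiset is
    preserved), re-runs the full estimation, and records every curve's
    weighted SD; p = (1 + #{SD* ≥ SD̂}) / (B + 1) per parameter.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    model = results.model
    rng = np.random.default_rng(seed)

    names = list(results.labels)
    dif_cols = list(results.dif.columns) if (include_dif and results.dif is not None) else []

    def all_sds(res) -> np.ndarray:
        out = [curve_mean_sd(res.curve(l), res.f_hat)[1] for l in names]
        out += [curve_mean_sd(res.curve(l, dif=True), res.f_hat)[1]
                for l in dif_cols]
        return np.array(out)

    sd_obs = all_sds(results)
    null = []
    dropped = 0
    for b in range(B):
        a_perm = model.a[rng.permutation(model.N)]
        try:
            rep, ok = _refit(results, model.X, a_perm, model.sampling_weights)
        except Exception:
            ok = False
        if not ok:
            dropped += 1
            continue
        null.append(all_sds(rep))
    if dropped > max_failure_rate * B:
        raise RuntimeError(
            f"permutation test aborted: {dropped}/{B} replicates failed")
    null = np.array(null)
    Beff = null.shape[0]
    p = (1.0 + (null >= sd_obs[None, :]).sum(axis=0)) / (Beff + 1.0)
    cols = names + [f"dif {l}" for l in dif_cols]
    summary = pd.DataFrame({"parameter": cols, "SD_obs": sd_obs, "p": p})
    return PermutationResult(summary=summary,
                             sd_null=pd.DataFrame(null, columns=cols),
                             B=Beff, seed=seed, n_dropped=dropped)
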