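"""Synthetic populations with exactly matched conditional moments, preset
data-generating models (DGMs), and Monte-Carlo harnesses for parameter
recovery and test size/power experiments.

The populations emulate a standard benchmark design: a moderator (age)
taking the 13 values 6, 7, …, 18 with equal group sizes, and multivariate
normal indicators whose per-age mean vector and covariance matrix *exactly*
equal the values implied by a specified parameter-curve family.  Three
invariance profiles are provided:

* ``dgm1`` — loadings and structural parameters vary with age, residual
  variances are invariant;
* ``dgm2`` — loadings and residual variances invariant, factor variances
  and the factor correlation vary;
* ``dgm3`` — everything invariant (the null model for size studies).

The exact per-age parameter values are the package's own documented choices
(loadings 0.5–0.9, factor correlation ranging over 0.4–0.75, residual
variances giving unit indicator variance at the central age); the invariance
*structure* is what drives every qualitative property these harnesses check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lsem import LocalSEM

__all__ = ["DGMSpec", "dgm_preset", "make_population", "draw_sample",
           "weighted_bias_rmse", "run_recovery_study", "run_size_power_study"]

DEFAULT_GRID = np.arange(6.0, 19.0)     # 13 moderator values
_CENTER, _HALFSPAN = 12.0, 6.0


def _u(a):
    return (np.asarray(a, float) - _CENTER) / _HALFSPAN   # in [-1, 1]


@dataclass
class DGMSpec:
    """A population: SEM parameter curves over a discrete moderator grid."""

    name: str
    indicators: list[str]
    factors: list[str]
    loading_fun: Callable[[float], np.ndarray]    # a -> (I, K)
    phi_fun: Callable[[float], np.ndarray]        # a -> (K, K)
    psi_fun: Callable[[float], np.ndarray]        # a -> (I,) residual variances
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    group_size: int = 10_000
    moderator: str = "age"

    def sigma(self, a: float) -> np.ndarray:
        lam = self.loading_fun(a)
        return lam @ self.phi_fun(a) @ lam.T + np.diag(self.psi_fun(a))

    def model_syntax(self) -> str:
        lines = []
        per_factor = len(self.indicators) // len(self.factors)
        for k, f in enumerate(self.factors):
            inds = self.indicators[k * per_factor:(k + 1) * per_factor]
            lines.append(f"{f} =~ " + " + ".join(inds))
        return "\n".join(lines)

    def invariant_loading_labels(self) -> list[str]:
        """Non-anchor loading labels (the usual par_invariant choice)."""
        labels = []
        per_factor = len(self.indicators) // len(self.factors)
        for k, f in enumerate(self.factors):
            inds = self.indicators[k * per_factor:(k + 1) * per_factor]
            labels += [f"{f}=~{v}" for v in inds[1:]]
        return labels

    # -- true curves in the fitted (marker indicator) metric ---------------
    def marker_curves(self) -> dict[str, np.ndarray]:
        """Generating parameter curves expressed in the metric of a fitted
        model whose first loading per factor is fixed at 1 (plus the
        standardized factor correlation under ``std `` keys)."""
        per_factor = len(self.indicators) // len(self.factors)
        out: dict[str, list[float]] = {}
        for a in self.grid:
            lam = self.loading_fun(a)
            phi = self.phi_fun(a)
            psi = self.psi_fun(a)
            anchors = np.array([lam[k * per_factor, k] for k in range(len(self.factors))])
            for k, f in enumerate(self.factors):
                for j, v in enumerate(self.indicators[k * per_factor:(k + 1) * per_factor]):
                    out.setdefault(f"{f}=~{v}", []).append(
                        lam[k * per_factor + j, k] / anchors[k])
                out.setdefault(f"{f}~~{f}", []).append(anchors[k] ** 2 * phi[k, k])
            for k in range(len(self.factors)):
                for m in range(k + 1, len(self.factors)):
                    fk, fm = self.factors[k], self.factors[m]
                    out.setdefault(f"{fk}~~{fm}", []).append(
                        anchors[k] * anchors[m] * phi[k, m])
                    out.setdefault(f"std {fk}~~{fm}", []).append(
                        phi[k, m] / np.sqrt(phi[k, k] * phi[m, m]))
            for i, v in enumerate(self.indicators):
                out.setdefault(f"{v}~~{v}", []).append(psi[i])
        return {k: np.asarray(v) for k, v in out.items()}

    def is_constant(self, label: str, tol: float = 1e-12) -> bool:
        c = self.marker_curves()[label]
        return bool(np.ptp(c) <= tol)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_BASE_LOAD = np.array([0.80, 0.70, 0.60, 0.75, 0.65, 0.70])
_SLOPE_LOAD = np.array([0.08, -0.07, 0.06, -0.08, 0.07, -0.06])


def dgm_preset(name: str, n_factors: int = 2, group_size: int = 10_000) -> DGMSpec:
    """Preset populations ``dgm1`` / ``dgm2`` / ``dgm3``.

    ``n_factors=1`` keeps the first three indicators and the first factor
    (the configuration of the recovery and size/power experiments);
    ``n_factors=2`` is the full six-indicator, two-factor design.
    """
    if name not in ("dgm1", "dgm2", "dgm3"):
        raise ValueError(f"unknown DGM preset {name!r}")
    if n_factors not in (1, 2):
        raise ValueError("n_factors must be 1 or 2")
    I = 3 * n_factors
    indicators = (["X1", "X2", "X3"] + ["Y1", "Y2", "Y3"])[:I]
    factors = ["FX", "FY"][:n_factors]
    base = _BASE_LOAD[:I]
    slope = _SLOPE_LOAD[:I]
    psi0 = 1.0 - base ** 2          # unit indicator variance at the center age

    loads_vary = name == "dgm1"
    struct_vary = name in ("dgm1", "dgm2")

    def loading_fun(a):
        lam_diag = base + (slope * _u(a) if loads_vary else 0.0)
        lam = np.zeros((I, n_factors))
        for k in range(n_factors):
            lam[3 * k:3 * k + 3, k] = lam_diag[3 * k:3 * k + 3]
        return lam

    def phi_fun(a):
        u = _u(a)
        if struct_vary:
            vx = 1.0 + 0.30 * u
            vy = 1.0 - 0.25 * u
            rho = 0.575 + 0.175 * u
        else:
            vx, vy, rho = 1.0, 1.0, 0.575
        if n_factors == 1:
            return np.array([[vx]])
        c = rho * np.sqrt(vx * vy)
        return np.array([[vx, c], [c, vy]])

    def psi_fun(a):
        return psi0.copy()

    return DGMSpec(name=name, indicators=indicators, factors=factors,
                   loading_fun=loading_fun, phi_fun=phi_fun, psi_fun=psi_fun,
                   group_size=group_size)


# ---------------------------------------------------------------------------
# population and sampling
# ---------------------------------------------------------------------------

def make_population(dgm: DGMSpec, seed: int | None = None) -> pd.DataFrame:
    """Exact-moment population table (13 × group_size rows by default).

    Within each moderator group the indicator block is drawn multivariate
    normal and then whitened and recolored so that the sample mean is
    exactly 0 and the (÷n) sample covariance exactly Σ(a).
    """
    rng = np.random.default_rng(seed)
    I = len(dgm.indicators)
    n = dgm.group_size
    if n <= I + 2:
        raise ValueError("group size must exceed the indicator count + 2")
    blocks = []
    for a in dgm.grid:
        Sigma = dgm.sigma(a)
        vals = np.linalg.eigvalsh(Sigma)
        if vals[0] <= 0:
            raise ValueError(f"target covariance at moderator {a} is not PD")
        Z = rng.standard_normal((n, I))
        Z -= Z.mean(axis=0)
        C = Z.T @ Z / n
        Lc = np.linalg.cholesky(C)
        Zw = np.linalg.solve(Lc, Z.T).T          # whiten: cov(Zw) = I exactly
        Xb = Zw @ np.linalg.cholesky(Sigma).T
        df = pd.DataFrame(Xb, columns=dgm.indicators)
        df.insert(0, dgm.moderator, a)
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)


def draw_sample(population: pd.DataFrame, N: int,
                seed: int | np.random.Generator | None = None,
                replace: bool = False) -> pd.DataFrame:
    """Uniform row subsample (without replacement by default)."""
    rng = np.random.default_rng(seed)
    M = len(population)
    if not replace and N > M:
        raise ValueError("N exceeds population size for sampling without replacement")
    idx = rng.choice(M, size=N, replace=replace)
    return population.iloc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Monte-Carlo harnesses
# ---------------------------------------------------------------------------

def weighted_bias_rmse(errors: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Density-weighted absolute bias and pointwise RMSE of curve errors.

    ``errors`` has shape (replications, T): estimate minus truth per focal
    point.  wBias = Σ_t f_t |mean_r err_rt|; wRMSE = Σ_t f_t sqrt(mean_r err_rt²).
    """
    E = np.atleast_2d(np.asarray(errors, float))
    f = np.asarray(f, float)
    wbias = float(np.dot(f, np.abs(E.mean(axis=0))))
    wrmse = float(np.dot(f, np.sqrt((E ** 2).mean(axis=0))))
    return wbias, wrmse


def _fit_once(sample: pd.DataFrame, dgm: DGMSpec, h: float, kernel: str,
              cov_mode: str, par_invariant, par_quadratic=(), est_dif=True):
    model = LocalSEM(sample, dgm.model_syntax(), dgm.moderator,
                     grid=dgm.grid, kernel=kernel, h=h, cov_mode=cov_mode,
                     par_invariant=par_invariant, par_quadratic=par_quadratic,
                     wt_floor=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(mode="joint", est_dif=est_dif)


def run_recovery_study(dgm: DGMSpec, N_list: Sequence[int], replications: int = 500,
                       h: float = 2.0, kernel: str = "gaussian",
                       cov_mode: str = "weighted",
                       params: Sequence[str] | None = None,
                       par_quadratic: Sequence[str] = (),
                       seed: int | None = None,
                       population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE of parameter curves under joint estimation.

    For each sample size, ``replications`` samples are drawn without
    replacement from the exact-moment population; the fitted curves of the
    selected parameters (default: the factor variance, the first invariant
    loading, and its DIF effect) are compared with the generating curves.

    Reports the density-weighted absolute bias wBias = Σ_t f(a_t)|Bias(a_t)|
    and the weighted pointwise RMSE, with f(a_t) the population moderator
    proportions.
    """
    if population is None:
        population = make_population(dgm, seed=seed)
    true = dgm.marker_curves()
    inv = dgm.invariant_loading_labels()
    if params is None:
        fac = dgm.factors[0]
        params = [f"{fac}~~{fac}", inv[0]]
        dif_params = [inv[0]]
    else:
        dif_params = [p for p in params if p in inv]
    f_pop = np.full(dgm.grid.size, 1.0 / dgm.grid.size)
    ss = np.random.SeedSequence(seed)
    rows = []
    for N in N_list:
        errs = {p: [] for p in list(params) + [f"dif {p}" for p in dif_params]}
        child = np.random.default_rng(ss.spawn(1)[0])
        for r in range(replications):
            sample = draw_sample(population, N, child)
            res = _fit_once(sample, dgm, h, kernel, cov_mode, inv)
            for p in params:
                errs[p].append(res.curve(p) - true[p])
            for p in dif_params:
                errs[f"dif {p}"].append(res.curve(p, dif=True) - true[p])
        for p, e in errs.items():
            wbias, wrmse = weighted_bias_rmse(np.array(e), f_pop)
            rows.append({"dgm": dgm.name, "N": N, "parameter": p,
                         "wBias": wbias, "wRMSE": wrmse,
                         "replications": replications})
    return pd.DataFrame(rows)


def run_size_power_study(dgm: DGMSpec, N: int, R_boot: int = 100,
                         replications: int = 500,
                         levels: Sequence[float] = (0.05, 0.01),
                         h: float = 2.0, kernel: str = "gaussian",
                         seed: int | None = None,
                         population: pd.DataFrame | None = None,
                         collect_sd: bool = False) -> pd.DataFrame:
    """Empirical rejection rates of the SD-based and Wald curve-variation
    tests, per parameter class and pooled.

    Per replication a sample of size N is drawn without replacement, the
    model is fitted jointly with invariant loadings and DIF estimation, and
    ``R_boot`` bootstrap replicates feed the bias-corrected-SD test and the
    first-difference Wald test for the factor variance(s), the loading DIF
    effects and the residual variances.

    Returns a table with columns dgm, parameter, test, level, rate, mc_se
    (plus mean_SD/mean_SD_bc when ``collect_sd``).
    """
    if population is None:
        population = make_population(dgm, seed=seed)
    inv = dgm.invariant_loading_labels()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng = np.random.default_rng(ss.spawn(1)[0])

    par_var = [f"{f}~~{f}" for f in dgm.factors]
    par_res = [f"{v}~~{v}" for v in dgm.indicators]
    pvals_sd: dict[str, list[float]] = {}
    pvals_wald: dict[str, list[float]] = {}
    sds: dict[str, list[tuple[float, float]]] = {}
    n_failed = 0
    for r in range(replications):
        boot_seed = int(rng.integers(0, 2 ** 31 - 1))
        sample = draw_sample(population, N, rng)
        try:
            res = _fit_once(sample, dgm, h, kernel, "weighted", inv)
            boot = res.bootstrap(R=R_boot, seed=boot_seed)
            summ = boot.curve_summary(include_std=False, wald=True)
        except Exception:
            n_failed += 1
            continue
        summ = summ.set_index("parameter")
        targets = par_var + [f"dif {l}" for l in res.dif.columns] + par_res
        for name in targets:
            row = summ.loc[name]
            pvals_sd.setdefault(name, []).append(row["p"])
            pvals_wald.setdefault(name, []).append(row["wald_p"])
            if collect_sd:
                sds.setdefault(name, []).append((row["SD"], row["SD_bc"]))
    if n_failed > 0.2 * replications:
        raise RuntimeError(f"size/power study: {n_failed}/{replications} "
                           "replications failed")

    rows = []
    names = list(pvals_sd)
    for test, pv in (("sd", pvals_sd), ("wald", pvals_wald)):
        for level in levels:
            for name in names + ["__pooled__"]:
                if name == "__pooled__":
                    ps = np.concatenate([np.asarray(pv[n]) for n in names])
                else:
                    ps = np.asarray(pv[name])
                rate = float(np.mean(ps < level))
                rows.append({"dgm": dgm.name, "N": N,
                             "parameter": "pooled" if name == "__pooled__" else name,
                             "test": test, "level": level, "rate": rate,
                             "mc_se": float(np.sqrt(rate * (1 - rate) / ps.size)),
                             "n": int(ps.size)})
    out = pd.DataFrame(rows)
    if collect_sd:
        sd_rows = []
        for name, v in sds.items():
            arr = np.array(v)
            sd_rows.append({"parameter": name, "mean_SD": arr[:, 0].mean(),
                            "mean_SD_bc": arr[:, 1].mean()})
        out.attrs["sd_means"] = pd.DataFrame(sd_rows)
    out.attrs["n_failed"] = n_failed
    return out
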