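"""Kernel functions, the bandwidth rule, focal-point grids, and the N x T
weight matrix that links subjects to focal points."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["kernel_value", "bandwidth", "KernelSpec", "FocalGrid",
           "WeightMatrix", "make_grid", "compute_weights"]


def _gaussian(x):
    return np.exp(-0.5 * np.square(x))


def _epanechnikov(x):
    # rescaled so that K(0) = 1 (the 3/4 density normalization is irrelevant
    # for weighting, which is scale-invariant)
    x = np.asarray(x, float)
    return np.where(np.abs(x) <= 1.0, 1.0 - np.square(x), 0.0)


def _uniform(x):
    x = np.asarray(x, float)
    return np.where(np.abs(x) <= 1.0, 1.0, 0.0)


_KERNELS = {"gaussian": _gaussian, "epanechnikov": _epanechnikov, "uniform": _uniform}


def kernel_value(kernel: str, x):
    """Evaluate kernel K at x; K(0)=1, symmetric, nonincreasing in |x|."""
    try:
        f = _KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(_KERNELS)}")
    return f(np.asarray(x, float))


def bandwidth(h: float, N: int, sigma_A: float) -> float:
    """Bandwidth rule bw = h * N^(-1/5) * sigma_A.

    h = 1.1 is the classical density-estimation factor; h = 2 is the
    simulation-backed default for locally weighted SEM.
    """
    if h <= 0:
        raise ValueError("bandwidth factor h must be positive")
    if sigma_A <= 0:
        raise ValueError("degenerate moderator: sigma_A must be positive")
    return float(h) * float(N) ** (-0.2) * float(sigma_A)


@dataclass
class KernelSpec:
    """Kernel name plus bandwidth; exactly one of (h, bw) is user-supplied,
    the other is derived from the moderator via the bandwidth rule."""

    kernel: str = "gaussian"
    h: float | None = None
    bw: float | None = None
    sigma_A: float | None = None

    def resolve(self, N: int, sigma_A: float) -> "KernelSpec":
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.bw is not None:
            if self.bw <= 0:
                raise ValueError("bw must be positive")
            h = self.h  # informational only when bw given directly
            return KernelSpec(self.kernel, h, float(self.bw), sigma_A)
        h = 2.0 if self.h is None else float(self.h)
        return KernelSpec(self.kernel, h, bandwidth(h, N, sigma_A), sigma_A)


@dataclass
class FocalGrid:
    """Strictly increasing focal points a_1 < ... < a_T."""

    points: np.ndarray
    spacing: str = "equidistant"   # "equidistant" | "percentile" | "explicit"

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 1 or self.points.size < 1:
            raise ValueError("focal grid must be a nonempty 1-d array")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("focal points must be strictly increasing")

    @property
    def T(self) -> int:
        return self.points.size

    @property
    def delta(self) -> float:
        if self.T < 2:
            raise ValueError("spacing undefined for a single focal point")
        return float(np.diff(self.points).mean())


def make_grid(a: np.ndarray, grid="equidistant:13") -> FocalGrid:
    """Build a focal grid from the moderator values.

    ``grid`` may be an explicit sequence of points, ``"equidistant:T"``
    (T points spanning the 5th-95th percentile, capped at the number of
    distinct moderator values) or ``"percentile:T"`` (equally spaced
    percentiles from 5 to 95).
    """
    a = np.asarray(a, float)
    a = a[np.isfinite(a)]
    if isinstance(grid, str):
        kind, _, num = grid.partition(":")
        T = int(num) if num else 13
        if kind == "equidistant":
            T = min(T, np.unique(a).size)
            lo, hi = np.percentile(a, [5, 95])
            if T == 1:
                return FocalGrid(np.array([(lo + hi) / 2]), "equidistant")
            return FocalGrid(np.linspace(lo, hi, T), "equidistant")
        if kind == "percentile":
            T = min(T, np.unique(a).size)
            pts = np.unique(np.percentile(a, np.linspace(5, 95, T)))
            return FocalGrid(pts, "percentile")
        raise ValueError(f"unknown grid specification {grid!r}")
    return FocalGrid(np.asarray(grid, float), "explicit")


@dataclass
class WeightMatrix:
    """Kernel weights w_nt in [0, 1] and their column sums W_t."""

    w: np.ndarray                 # (N, T)
    grid: FocalGrid
    bw: float
    kernel: str
    W: np.ndarray = field(init=False)
    dropped: np.ndarray = field(default=None)   # indices of dropped focal points

    def __post_init__(self):
        self.W = self.w.sum(axis=0)

    @property
    def f_hat(self) -> np.ndarray:
        """Discrete density of the moderator over retained focal points,
        f̂(a_t) = W_t / Σ_s W_s."""
        return self.W / self.W.sum()


def compute_weights(a: np.ndarray, grid: FocalGrid, kernel: KernelSpec,
                    sampling_weights: np.ndarray | None = None,
                    wt_floor: float | None = None) -> WeightMatrix:
    """Weight matrix w_nt = K((a_n - a_t)/bw), optionally fused
    multiplicatively with sampling weights.

    Focal points whose weight sum W_t falls below ``wt_floor`` are dropped
    with a warning (covariance matrices there would not be estimable).
    """
    a = np.asarray(a, float)
    if not np.all(np.isfinite(a)):
        raise ValueError("moderator contains non-finite values")
    if kernel.bw is None or kernel.bw <= 0:
        raise ValueError("kernel bandwidth not resolved; call KernelSpec.resolve")
    x = (a[:, None] - grid.points[None, :]) / kernel.bw
    w = kernel_value(kernel.kernel, x)
    if sampling_weights is not None:
        sw = np.asarray(sampling_weights, float)
        if sw.shape != a.shape or np.any(sw < 0):
            raise ValueError("sampling weights must be nonnegative, one per subject")
        w = w * sw[:, None]
    W = w.sum(axis=0)
    dropped = None
    if wt_floor is not None:
        keep = W >= wt_floor
        if not np.all(keep):
            dropped = np.flatnonzero(~keep)
            warnings.warn(
                f"dropping {dropped.size} focal point(s) with weight sum below "
                f"{wt_floor:g}: grid indices {dropped.tolist()}",
                RuntimeWarning, stacklevel=2)
            grid = FocalGrid(grid.points[keep], grid.spacing)
            w = w[:, keep]
        if w.shape[1] == 0:
            raise ValueError("all focal points dropped: weight sums below floor")
    wm = WeightMatrix(w=w, grid=grid, bw=kernel.bw, kernel=kernel.kernel)
    wm.dropped = dropped
    return wm
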