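"""Canonical analysis and constrained optimization of a fitted surface.

The fitted quadratic Y = b0 + b'x + sum b_ii x_i^2 + sum_{i<j} b_ij x_i x_j
has gradient b + H x with Hessian H_ii = 2 b_ii, H_ij = b_ij.  The
stationary point solves H x = -b and is classified by the Hessian's
eigenvalue signs (all negative: maximum; all positive: minimum; mixed:
saddle).  Because screening-stage surfaces are frequently saddles, the
constrained maximum over the coded design cube is found by a dense grid
scan followed by a bounded local polish, rather than by stationary-point
algebra alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import FactorDef
from .rsm import QuadraticResponseSurface

__all__ = [
    "StationaryPoint",
    "OptimumResult",
    "SurfaceGrid",
    "stationary_point",
    "constrained_max",
    "verification_summary",
    "surface_grid",
]

_EIG_TOL = 1e-10


@dataclass
class StationaryPoint:
    coded: np.ndarray
    nature: str  # "maximum" | "minimum" | "saddle"
    eigenvalues: np.ndarray


@dataclass
class OptimumResult:
    """Constrained optimum of a fitted surface over a coded box."""

    constrained_coded: np.ndarray
    predicted_response: float
    bounds: list[tuple[float, float]]
    stationary: StationaryPoint | None = None
    stationary_inside: bool | None = None
    constrained_actual: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "constrained_coded": self.constrained_coded.tolist(),
            "predicted_response": self.predicted_response,
            "bounds": [list(b) for b in self.bounds],
        }
        if self.stationary is not None:
            d["stationary_coded"] = self.stationary.coded.tolist()
            d["stationary_nature"] = self.stationary.nature
            d["stationary_eigenvalues"] = self.stationary.eigenvalues.tolist()
            d["stationary_inside_bounds"] = self.stationary_inside
        if self.constrained_actual is not None:
            d["constrained_actual"] = self.constrained_actual
        return d


def _hessian(fit: QuadraticResponseSurface) -> tuple[np.ndarray, np.ndarray]:
    """(gradient-at-origin b, Hessian H) of the fitted polynomial."""
    k = fit.n_factors_
    b = np.asarray(fit.coef_linear_.to_numpy(), dtype=float)
    H = np.diag(2.0 * fit.coef_quadratic_.to_numpy())
    inter = fit.coef_interaction_.to_numpy()
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            H[i, j] = H[j, i] = inter[idx]
            idx += 1
    return b, H


def _eval_on_grid(fit: QuadraticResponseSurface, axes: list[np.ndarray]) -> np.ndarray:
    """Fitted-polynomial values on the tensor grid of the given axes.

    Built by broadcasting 1-D axis arrays instead of materializing the
    expanded basis for every node, so dense scans stay cheap.
    """
    k = fit.n_factors_

    def ax(i):
        shape = [1] * k
        shape[i] = -1
        return np.asarray(axes[i], dtype=float).reshape(shape)

    cube = np.full([len(a) for a in axes], fit.intercept_)
    lin = fit.coef_linear_.to_numpy()
    quad = fit.coef_quadratic_.to_numpy()
    inter = fit.coef_interaction_.to_numpy()
    for i in range(k):
        cube += lin[i] * ax(i) + quad[i] * ax(i) ** 2
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            cube += inter[idx] * (ax(i) * ax(j))
            idx += 1
    return cube


def stationary_point(fit: QuadraticResponseSurface) -> StationaryPoint:
    """Solve grad Y = 0 and classify the surface by Hessian eigenvalues."""
    b, H = _hessian(fit)
    eig = np.linalg.eigvalsh(H)
    if np.min(np.abs(eig)) < _EIG_TOL * max(1.0, np.max(np.abs(eig))):
        ridge = np.linalg.eigh(H)[1][:, int(np.argmin(np.abs(eig)))]
        raise np.linalg.LinAlgError(
            f"singular Hessian: the surface has a stationary ridge along {np.round(ridge, 4)}"
        )
    x = np.linalg.solve(H, -b)
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    return StationaryPoint(coded=x, nature=nature, eigenvalues=eig)


def constrained_max(
    fit: QuadraticResponseSurface,
    bounds: tuple[float, float] | list[tuple[float, float]] = (-1.0, 1.0),
    factors: list[FactorDef] | None = None,
    grid_step: float = 0.01,
) -> OptimumResult:
    """Maximize the fitted surface over a coded box by grid scan + polish.

    A dense grid (spacing ``grid_step``, default 0.01 coded units) is
    scanned and the best node is refined with bounded L-BFGS-B.  When
    ``factors`` are supplied the optimum is also decoded to actual
    concentrations.  The interior stationary point, if the Hessian is
    nonsingular, is reported alongside.
    """
    k = fit.n_factors_
    if isinstance(bounds, tuple) and len(bounds) == 2 and np.isscalar(bounds[0]):
        bounds = [tuple(bounds)] * k
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != k:
        raise ValueError(f"expected {k} bound pairs, got {len(bounds)}")
    for lo, hi in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"invalid bounds ({lo}, {hi})")

    axes = [np.arange(lo, hi + grid_step / 2, grid_step) for lo, hi in bounds]
    cube = _eval_on_grid(fit, axes)
    idx = np.unravel_index(int(np.argmax(cube)), cube.shape)
    best_val = float(cube[idx])
    x0 = np.array([axes[d][i] for d, i in enumerate(idx)])
    del cube

    res = minimize(
        lambda x: -fit.predict(x[None, :])[0],
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-15, "gtol": 1e-12},
    )
    x_best = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    y_best = float(fit.predict(x_best[None, :])[0])
    # the polish must never lose to its own starting node
    if best_val > y_best:
        x_best, y_best = x0, best_val

    try:
        sp = stationary_point(fit)
        inside = bool(
            np.all([lo <= xi <= hi for xi, (lo, hi) in zip(sp.coded, bounds)])
        )
    except np.linalg.LinAlgError:
        sp, inside = None, None

    actual = None
    if factors is not None:
        if len(factors) != k:
            raise ValueError(f"expected {k} factor definitions, got {len(factors)}")
        actual = {f.name: float(f.decode(xi)) for f, xi in zip(factors, x_best)}
    return OptimumResult(
        constrained_coded=x_best,
        predicted_response=y_best,
        bounds=bounds,
        stationary=sp,
        stationary_inside=inside,
        constrained_actual=actual,
    )


def verification_summary(
    predicted: float, observed_mean: float, observed_se: float | None = None
) -> dict:
    """Compare the model-predicted optimum with a verification experiment."""
    abs_dev = abs(predicted - observed_mean)
    rel_dev = 100.0 * abs_dev / abs(predicted) if predicted != 0 else np.nan
    out = {
        "predicted": float(predicted),
        "observed_mean": float(observed_mean),
        "absolute_deviation": float(abs_dev),
        "relative_deviation_pct": float(rel_dev),
    }
    if observed_se is not None:
        out["observed_se"] = float(observed_se)
    return out


@dataclass
class SurfaceGrid:
    """Predicted-response matrix over two free factors, third held fixed."""

    fixed_factor: str
    fixed_level: float
    axis_names: tuple[str, str]
    axis1: np.ndarray  # coded
    axis2: np.ndarray
    values: np.ndarray  # shape (len(axis1), len(axis2))
    axis1_actual: np.ndarray | None = None
    axis2_actual: np.ndarray | None = None

    def to_long_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        df = pd.DataFrame(
            {
                self.axis_names[0]: a1.ravel(),
                self.axis_names[1]: a2.ravel(),
                "predicted": self.values.ravel(),
            }
        )
        return df


def surface_grid(
    fit: QuadraticResponseSurface,
    fixed_factor: str,
    fixed_level: float = 0.0,
    resolution: int = 101,
    bounds: tuple[float, float] = (-1.0, 1.0),
    factors: list[FactorDef] | None = None,
) -> SurfaceGrid:
    """Evaluate the fitted surface on a 2-D coded grid for plotting.

    One factor is held at ``fixed_level`` (the published contour plots fix
    it at the center, coded 0) and the remaining two sweep ``bounds`` with
    ``resolution`` points per axis.
    """
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    names = fit.feature_names_in_
    if fixed_factor not in names:
        raise ValueError(f"unknown factor {fixed_factor!r}; choose from {names}")
    fixed_idx = names.index(fixed_factor)
    free = [j for j in range(fit.n_factors_) if j != fixed_idx]
    axis = np.linspace(bounds[0], bounds[1], resolution)
    A1, A2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.zeros((resolution * resolution, fit.n_factors_))
    pts[:, fixed_idx] = fixed_level
    pts[:, free[0]] = A1.ravel()
    pts[:, free[1]] = A2.ravel()
    values = fit.predict(pts).reshape(resolution, resolution)

    a1_act = a2_act = None
    if factors is not None:
        fmap = {f.name: f for f in factors}
        a1_act = fmap[names[free[0]]].decode(axis)
        a2_act = fmap[names[free[1]]].decode(axis)
    return SurfaceGrid(
        fixed_factor=fixed_factor,
        fixed_level=float(fixed_level),
        axis_names=(names[free[0]], names[free[1]]),
        axis1=axis,
        axis2=axis.copy(),
        values=values,
        axis1_actual=a1_act,
        axis2_actual=a2_act,
    )
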