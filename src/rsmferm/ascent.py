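"""Path-of-steepest-ascent stage between screening and the response surface.

After screening, the region of the optimum is approached by a short series
of runs stepping each significant factor from a base point.  Two modes are
supported:

* **sign mode** — the textbook procedure: step k sets factor i to
  ``base_i + (k-1) * sign(b_i) * step_i``, i.e. each factor moves in the
  direction of its fitted first-order effect;
* **grid mode** — an explicitly supplied table of settings taken verbatim,
  for reproducing a published path whose construction rule is not stated.

The winning step (maximal observed response, first occurrence on ties)
becomes the center point of the follow-up Box-Behnken design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorDef
from .screening import FirstOrderScreening

__all__ = ["AscentPath", "propose_path", "path_from_grid", "select_center"]


@dataclass
class AscentPath:
    """An ordered series of actual-scale settings with optional responses."""

    steps: pd.DataFrame  # one row per step, one column per moving factor (actual units)
    fixed: dict[str, float] = field(default_factory=dict)
    response_mean: np.ndarray | None = None
    response_se: np.ndarray | None = None
    direction: dict[str, int] = field(default_factory=dict)
    step_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.steps.isna().any().any():
            raise ValueError("every step must specify every moving factor")
        overlap = set(self.steps.columns) & set(self.fixed)
        if overlap:
            raise ValueError(f"factors cannot be both moving and fixed: {sorted(overlap)}")
        if self.response_mean is not None:
            self.response_mean = np.asarray(self.response_mean, dtype=float)
            if len(self.response_mean) != len(self.steps):
                raise ValueError("response_mean length must match number of steps")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def best_index(self) -> int:
        """0-based index of the maximal observed response (first on ties)."""
        if self.response_mean is None:
            raise ValueError("no observed responses attached to this path")
        return int(np.argmax(self.response_mean))

    def with_responses(self, mean, se=None) -> "AscentPath":
        return AscentPath(
            steps=self.steps.copy(),
            fixed=dict(self.fixed),
            response_mean=np.asarray(mean, dtype=float),
            response_se=None if se is None else np.asarray(se, dtype=float),
            direction=dict(self.direction),
            step_sizes=dict(self.step_sizes),
        )

    def to_frame(self) -> pd.DataFrame:
        """Full table: moving factors, fixed factors, responses if present."""
        df = self.steps.copy()
        for name, level in self.fixed.items():
            df[name] = level
        if self.response_mean is not None:
            df["response_mean"] = self.response_mean
            if self.response_se is not None:
                df["response_se"] = self.response_se
        df.index = pd.RangeIndex(1, len(df) + 1, name="step")
        return df


def propose_path(
    fit: FirstOrderScreening,
    base: dict[str, float],
    step_sizes: dict[str, float],
    n_steps: int,
    fixed: dict[str, float] | None = None,
) -> AscentPath:
    """Coefficient-sign ascent path from a screening fit.

    Only factors named in ``step_sizes`` move; each moves from its ``base``
    value by ``(k-1) * sign(coef) * step`` at step k.  Factors in ``fixed``
    are held constant across all steps.
    """
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    known = set(fit.feature_names_in_)
    unknown = set(step_sizes) - known
    if unknown:
        raise ValueError(f"unknown factors in step_sizes: {sorted(unknown)}")
    if set(base) != set(step_sizes):
        raise ValueError("base must specify exactly the moving factors")
    bad = [f for f, s in step_sizes.items() if not s > 0]
    if bad:
        raise ValueError(f"step sizes must be > 0: {bad}")

    coefs = dict(zip(fit.feature_names_in_, fit.coef_))
    direction = {f: (1 if coefs[f] >= 0 else -1) for f in step_sizes}
    k = np.arange(n_steps)
    data = {
        f: base[f] + k * direction[f] * step_sizes[f] for f in step_sizes
    }
    return AscentPath(
        steps=pd.DataFrame(data),
        fixed=dict(fixed or {}),
        direction=direction,
        step_sizes=dict(step_sizes),
    )


def path_from_grid(
    grid: pd.DataFrame,
    fixed: dict[str, float] | None = None,
    response_mean=None,
    response_se=None,
) -> AscentPath:
    """Explicit-grid ascent path: the supplied settings are used verbatim."""
    steps = grid.reset_index(drop=True).astype(float)
    step_sizes = {
        c: float(np.diff(steps[c]).mean()) for c in steps.columns if len(steps) > 1
    }
    path = AscentPath(steps=steps, fixed=dict(fixed or {}), step_sizes=step_sizes)
    if response_mean is not None:
        path = path.with_responses(response_mean, response_se)
    return path


def select_center(
    path: AscentPath, step_sizes: dict[str, float] | None = None
) -> tuple[dict[str, float], list[FactorDef]]:
    """Pick the best step as the follow-up design's center point.

    Returns the winning settings and :class:`FactorDef` objects centered
    there, with coded step defaulting to the path increment per factor
    (override via ``step_sizes``).
    """
    if path.response_mean is None:
        raise ValueError("select_center requires observed responses for every step")
    best = path.best_index
    settings = {c: float(path.steps.iloc[best][c]) for c in path.steps.columns}
    steps = dict(path.step_sizes)
    if step_sizes:
        steps.update(step_sizes)
    factors = []
    for name, center in settings.items():
        if name not in steps or not steps[name] > 0:
            raise ValueError(f"no positive step size available for factor {name!r}")
        factors.append(FactorDef(name=name, center=center, step=abs(steps[name])))
    return settings, factors
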