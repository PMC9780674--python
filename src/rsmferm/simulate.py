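"""Synthetic fermentation-response generator for end-to-end testing.

The generator emulates the statistical structure the analysis assumes: a
true polynomial response surface in coded factor space plus i.i.d.
Gaussian replicate noise.  Replicate noise defaults to sigma = 0.03
percentage points, the middle of the replicate SEs typically seen in
triplicate protein determinations (0.01-0.13), with 3 replicates per run.

Randomness comes exclusively from ``numpy.random.default_rng`` (the
PCG64 generator), so a given (seed, truth) pair reproduces bit-identical
datasets across platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ascent import AscentPath
from .design import DesignMatrix, ResponseSet
from .rsm import QuadraticResponseSurface

__all__ = [
    "SurfaceTruth",
    "simulate_responses",
    "StudyScenario",
    "scenario_study",
    "recovery_study",
]


@dataclass
class SurfaceTruth:
    """A true response polynomial over named coded factors, plus noise.

    ``linear`` maps factor name -> coefficient; ``interaction`` maps
    ``"a:b"`` -> coefficient; ``quadratic`` maps factor name -> pure
    quadratic coefficient.  All coefficients are in response units per
    coded unit(s); ``sigma`` is the replicate noise SD in response units.
    """

    beta0: float
    linear: dict[str, float] = field(default_factory=dict)
    interaction: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.03
    n_reps: int = 3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def factor_names(self) -> list[str]:
        names = list(self.linear)
        for n in self.quadratic:
            if n not in names:
                names.append(n)
        for pair in self.interaction:
            for n in pair.split(":"):
                if n not in names:
                    names.append(n)
        return names

    def evaluate(self, coded: np.ndarray, names: list[str]) -> np.ndarray:
        """True surface value at coded points (rows) for the named factors."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        missing = set(self.factor_names) - set(names)
        if missing:
            raise ValueError(f"design lacks factors required by the truth: {sorted(missing)}")
        col = {n: coded[:, j] for j, n in enumerate(names)}
        y = np.full(coded.shape[0], self.beta0, dtype=float)
        for n, b in self.linear.items():
            y += b * col[n]
        for pair, b in self.interaction.items():
            a, bname = pair.split(":")
            y += b * col[a] * col[bname]
        for n, b in self.quadratic.items():
            y += b * col[n] ** 2
        return y


def simulate_responses(design: DesignMatrix, truth: SurfaceTruth, seed: int) -> ResponseSet:
    """Draw replicate responses on a design and summarize per run.

    Each run receives ``truth.n_reps`` draws of polynomial + N(0, sigma);
    the returned set carries the replicate mean and (for n_reps >= 2) the
    standard error of the mean.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    mu = truth.evaluate(design.coded, design.factor_names)
    reps = mu[:, None] + rng.normal(0.0, truth.sigma, size=(design.n_runs, truth.n_reps))
    mean = reps.mean(axis=1)
    # protein content is non-negative; extreme noise draws are floored
    mean = np.maximum(mean, 0.0)
    se = (
        reps.std(axis=1, ddof=1) / np.sqrt(truth.n_reps)
        if truth.n_reps >= 2
        else None
    )
    return ResponseSet(
        run_labels=list(design.run_labels),
        mean=mean,
        se=se,
        n_reps=np.full(design.n_runs, truth.n_reps),
    )


@dataclass
class StudyScenario:
    """Ready-made three-stage scenario mirroring the published study."""

    pb_design: DesignMatrix
    screen_truth: SurfaceTruth
    ascent_grid: AscentPath
    bbd_design: DesignMatrix
    surface_truth: SurfaceTruth

    def simulate_ascent(self, seed: int) -> AscentPath:
        """Attach simulated responses to the ascent grid.

        Each step's settings are coded against the surface-stage factor
        definitions and evaluated under the surface truth.
        """
        rng = np.random.default_rng(seed)
        factors = {f.name: f for f in self.bbd_design.factors}
        coded = np.column_stack(
            [factors[c].code(self.ascent_grid.steps[c].to_numpy()) for c in self.ascent_grid.steps.columns]
        )
        mu = self.surface_truth.evaluate(coded, list(self.ascent_grid.steps.columns))
        n_reps = self.surface_truth.n_reps
        reps = mu[:, None] + rng.normal(0.0, self.surface_truth.sigma, size=(len(mu), n_reps))
        se = reps.std(axis=1, ddof=1) / np.sqrt(n_reps) if n_reps >= 2 else None
        return self.ascent_grid.with_responses(np.maximum(reps.mean(axis=1), 0.0), se)


def scenario_study() -> StudyScenario:
    """The published study's designs with its fitted equations as truth.

    * Screening truth: the three dominant first-order effects (beef broth
      -0.0608, peptone +0.0925, glucose -0.0808 around intercept 1.64);
      the minor factors are set to zero so that, at low noise, the
      screening stage selects exactly the factors that truly matter.
    * Surface truth: the full fitted quadratic over beef broth, peptone
      and glucose (intercept 2.07, dominant terms glucose +0.18 and
      glucose^2 -0.26).
    * Ascent grid: the 5-step published path from (20, 0.1, 1) to
      (60, 0.9, 5) %.
    """
    from .datasets import ascent_path, bbd_experiment, pb_screen

    pb_design, _ = pb_screen()
    bbd_design, _ = bbd_experiment()
    screen_truth = SurfaceTruth(
        beta0=1.64,
        linear={"beef_broth": -0.0608, "peptone": 0.0925, "glucose": -0.0808},
        sigma=0.03,
        n_reps=3,
    )
    surface_truth = SurfaceTruth(
        beta0=2.07,
        linear={"beef_broth": 0.0275, "peptone": -0.04, "glucose": 0.18},
        interaction={
            "beef_broth:peptone": 0.03,
            "beef_broth:glucose": -0.05,
            "peptone:glucose": 0.095,
        },
        quadratic={"beef_broth": -0.045, "peptone": 0.04, "glucose": -0.26},
        sigma=0.03,
        n_reps=3,
    )
    grid = ascent_path()
    return StudyScenario(
        pb_design=pb_design,
        screen_truth=screen_truth,
        ascent_grid=AscentPath(
            steps=grid.steps.copy(),
            fixed=dict(grid.fixed),
            step_sizes=dict(grid.step_sizes),
        ),
        bbd_design=bbd_design,
        surface_truth=surface_truth,
    )


def recovery_study(
    truth: SurfaceTruth,
    design: DesignMatrix,
    n_sims: int,
    seed: int,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE/coverage of the quadratic fit under ``truth``.

    Repeats simulate -> fit ``n_sims`` times (child seeds spawned from
    ``seed``) and reports, per coefficient: the true value, empirical
    bias, RMSE, and the coverage of the nominal ``conf_level`` t-intervals.
    """
    if n_sims < 2:
        raise ValueError(f"n_sims must be >= 2, got {n_sims}")
    names = design.factor_names
    k = len(names)
    term_names = ["Intercept"] + names + [
        f"{names[i]}:{names[j]}" for i, j in itertools.combinations(range(k), 2)
    ] + [f"{n}^2" for n in names]
    true_vals = np.array(
        [truth.beta0]
        + [truth.linear.get(n, 0.0) for n in names]
        + [
            truth.interaction.get(f"{names[i]}:{names[j]}", truth.interaction.get(f"{names[j]}:{names[i]}", 0.0))
            for i, j in itertools.combinations(range(k), 2)
        ]
        + [truth.quadratic.get(n, 0.0) for n in names]
    )

    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    est = np.empty((n_sims, len(term_names)))
    covered = np.zeros((n_sims, len(term_names)), dtype=bool)
    for s in range(n_sims):
        resp = simulate_responses(design, truth, seed=int(seeds[s]))
        fit = QuadraticResponseSurface().fit(design.coded, resp.mean, feature_names=names)
        est[s] = np.concatenate([[fit.intercept_], fit.coef_])
        ci = fit.conf_int(alpha=1 - conf_level)
        covered[s] = (ci["lower"].to_numpy() <= true_vals) & (true_vals <= ci["upper"].to_numpy())

    bias = est.mean(axis=0) - true_vals
    rmse = np.sqrt(((est - true_vals) ** 2).mean(axis=0))
    return pd.DataFrame(
        {
            "true": true_vals,
            "bias": bias,
            "rmse": rmse,
            "coverage": covered.mean(axis=0),
            "mc_se_bias": est.std(axis=0, ddof=1) / np.sqrt(n_sims),
        },
        index=pd.Index(term_names, name="term"),
    )
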