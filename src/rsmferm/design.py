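"""Two-level screening and three-level response-surface designs.

Factor settings live on two scales: the *actual* scale (medium
concentrations, e.g. ``%% w/v``) and the *coded* scale, where the design
levels are -1, 0 and +1.  The mapping is affine,

    coded = (actual - center) / step,

so a :class:`FactorDef` is fully determined by its center and half-range
(``step``), or equivalently by the actual values at the -1 and +1 levels.

Coded design levels are stored as exact integers; actual concentrations
only materialize through :meth:`FactorDef.decode`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorDef",
    "DesignMatrix",
    "ResponseSet",
    "ValidationReport",
    "plackett_burman",
    "box_behnken",
    "validate_design",
    "shuffle_runs",
]


@dataclass(frozen=True)
class FactorDef:
    """One medium component with its coded<->actual affine mapping.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"beef broth"``.
    center : float
        Actual-scale value at coded 0.
    step : float
        Actual-scale half-range per coded unit; must be positive.
    unit : str, optional
        Unit of the actual scale, e.g. ``"% w/v"``.
    """

    name: str
    center: float
    step: float
    unit: str = "%"

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.step):
            raise ValueError(f"factor {self.name!r}: center/step must be finite")
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")

    @classmethod
    def from_levels(cls, name: str, low: float, high: float, unit: str = "%") -> "FactorDef":
        """Build from the actual values at the -1 and +1 levels."""
        if not high > low:
            raise ValueError(f"factor {name!r}: high must exceed low ({low=}, {high=})")
        return cls(name=name, center=(low + high) / 2.0, step=(high - low) / 2.0, unit=unit)

    @property
    def low(self) -> float:
        return self.center - self.step

    @property
    def high(self) -> float:
        return self.center + self.step

    def code(self, actual):
        """Map actual-scale value(s) to the coded scale."""
        return (np.asarray(actual, dtype=float) - self.center) / self.step

    def decode(self, coded):
        """Map coded value(s) back to the actual scale."""
        return self.center + self.step * np.asarray(coded, dtype=float)


@dataclass
class DesignMatrix:
    """A runs x factors table of coded levels.

    ``runs`` holds integer coded levels (-1/0/+1 for the designs in scope);
    columns beyond the declared factors (Plackett-Burman dummy columns) are
    kept with their own labels but excluded from model fits by default.
    """

    factors: list[FactorDef]
    runs: np.ndarray
    run_labels: list[str] = field(default_factory=list)
    dummy_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs)
        if self.runs.ndim != 2:
            raise ValueError("runs must be a 2-D array")
        n_cols = len(self.factors) + len(self.dummy_labels)
        if self.runs.shape[1] != n_cols:
            raise ValueError(
                f"design has {self.runs.shape[1]} columns but "
                f"{len(self.factors)} factors + {len(self.dummy_labels)} dummies declared"
            )
        if not self.run_labels:
            self.run_labels = [str(i + 1) for i in range(self.runs.shape[0])]
        if len(self.run_labels) != self.runs.shape[0]:
            raise ValueError("run_labels length must match number of runs")
        if len(set(self.run_labels)) != len(self.run_labels):
            raise ValueError("duplicate run labels")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def coded(self) -> np.ndarray:
        """Coded levels of the declared factors only (dummies dropped)."""
        return np.asarray(self.runs[:, : len(self.factors)], dtype=float)

    @property
    def center_flags(self) -> np.ndarray:
        """True for runs with every declared factor at coded 0."""
        return np.all(self.runs[:, : len(self.factors)] == 0, axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Coded design as a DataFrame indexed by run label."""
        cols = self.factor_names + self.dummy_labels
        df = pd.DataFrame(self.runs, columns=cols, index=pd.Index(self.run_labels, name="run"))
        df["is_center"] = self.center_flags.astype(int)
        return df

    def actual_frame(self) -> pd.DataFrame:
        """Declared factors decoded to actual concentrations."""
        data = {
            f.name: f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)
        }
        return pd.DataFrame(data, index=pd.Index(self.run_labels, name="run"))


@dataclass
class ResponseSet:
    """Per-run mean response (here: %% mycelial soluble protein).

    ``se`` and ``n_reps`` are optional replicate summaries carried through
    for display; fitting uses the per-run means.
    """

    run_labels: list[str]
    mean: np.ndarray
    se: np.ndarray | None = None
    n_reps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.ndim != 1 or len(self.mean) != len(self.run_labels):
            raise ValueError("mean must be 1-D and match run_labels")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("responses must be finite")
        if np.any(self.mean < 0):
            raise ValueError("protein content responses must be non-negative")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.mean.shape:
                raise ValueError("se must match mean shape")
        if len(set(self.run_labels)) != len(self.run_labels):
            raise ValueError("duplicate run labels in responses")

    def aligned_to(self, design: DesignMatrix) -> np.ndarray:
        """Mean responses reordered to the design's run order.

        Raises if the label sets are not bijective.
        """
        if set(self.run_labels) != set(design.run_labels):
            missing = set(design.run_labels) - set(self.run_labels)
            extra = set(self.run_labels) - set(design.run_labels)
            raise ValueError(
                f"run labels do not match design (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        order = [self.run_labels.index(lbl) for lbl in design.run_labels]
        return self.mean[order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean": self.mean}, index=pd.Index(self.run_labels, name="run"))
        if self.se is not None:
            df["se"] = self.se
        if self.n_reps is not None:
            df["n_reps"] = self.n_reps
        return df


# Standard cyclic first rows for Plackett-Burman designs (Plackett & Burman
# 1946); each design is the first row cycled n_runs-2 times plus an
# all-minus row.
_PB_FIRST_ROWS = {
    8: "++ +-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
}
_PB_FIRST_ROWS = {n: s.replace(" ", "") for n, s in _PB_FIRST_ROWS.items()}


def plackett_burman(
    n_factors: int,
    n_runs: int = 12,
    factors: list[FactorDef] | None = None,
) -> DesignMatrix:
    """Generate a two-level Plackett-Burman screening design.

    The first ``n_factors`` columns are assigned to factors in declared
    order; the remaining ``n_runs - 1 - n_factors`` columns are retained as
    labelled dummy columns (usable for error estimation, excluded from
    fits).

    Parameters
    ----------
    n_factors : int
        Number of real factors, ``1 <= n_factors <= n_runs - 1``.
    n_runs : int
        Design size; one of 8, 12, 16, 20.
    factors : list of FactorDef, optional
        Factor definitions; placeholder unit-step factors are created when
        omitted.
    """
    if n_runs not in _PB_FIRST_ROWS:
        raise ValueError(
            f"unsupported n_runs={n_runs}; supported sizes: {sorted(_PB_FIRST_ROWS)}"
        )
    if not 1 <= n_factors <= n_runs - 1:
        raise ValueError(f"n_factors must be in [1, {n_runs - 1}], got {n_factors}")
    if factors is not None and len(factors) != n_factors:
        raise ValueError("len(factors) must equal n_factors")

    first = np.array([1 if c == "+" else -1 for c in _PB_FIRST_ROWS[n_runs]], dtype=int)
    rows = [np.roll(first, k) for k in range(n_runs - 1)]
    rows.append(np.full(n_runs - 1, -1, dtype=int))
    full = np.vstack(rows)

    if factors is None:
        factors = [FactorDef(name=f"X{j + 1}", center=0.0, step=1.0) for j in range(n_factors)]
    dummy_labels = [f"dummy{j + 1}" for j in range(n_runs - 1 - n_factors)]
    return DesignMatrix(factors=factors, runs=full[:, : n_runs - 1], dummy_labels=dummy_labels)


def box_behnken(factors: list[FactorDef], n_center: int = 5) -> DesignMatrix:
    """Generate a three-factor Box-Behnken design.

    The 12 non-center runs are the edge midpoints of the factor cube: for
    each factor pair all four +/-1 sign combinations with the third factor
    at 0.  ``n_center`` replicated center runs are appended (5 gives the
    classical 17-run design whose center replicates supply pure error).
    """
    if len(factors) != 3:
        raise ValueError(f"box_behnken supports exactly 3 factors, got {len(factors)}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    rows = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1, 1), repeat=2):
            row = [0, 0, 0]
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend([[0, 0, 0]] * n_center)
    return DesignMatrix(factors=list(factors), runs=np.asarray(rows, dtype=int))


@dataclass
class ValidationReport:
    """Pass/fail report of a design's structural invariants."""

    checks: list[dict]

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.checks)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        lines = [f"ValidationReport [{status}]"]
        for c in self.checks:
            lines.append(f"  {'ok ' if c['passed'] else 'FAIL'} {c['name']}: {c['detail']}")
        return "\n".join(lines)


def validate_design(design: DesignMatrix) -> ValidationReport:
    """Check the structural invariants of a screening or BBD matrix.

    Report-only: balance and pairwise orthogonality for two-level designs,
    the edge/center structure for three-level designs, and the coded level
    set for both.  Offending rows/columns are listed in the details.
    """
    checks: list[dict] = []
    runs = np.asarray(design.runs)
    levels = set(np.unique(runs).tolist())
    checks.append(
        {
            "name": "levels",
            "passed": levels <= {-1, 0, 1},
            "detail": f"coded levels found: {sorted(levels)}",
        }
    )

    is_two_level = not np.any(runs == 0)
    if is_two_level:
        bad_cols = [
            design.to_frame().columns[j]
            for j in range(runs.shape[1])
            if np.sum(runs[:, j] == 1) != np.sum(runs[:, j] == -1)
        ]
        checks.append(
            {
                "name": "balance",
                "passed": not bad_cols,
                "detail": "all columns balanced" if not bad_cols else f"unbalanced columns: {bad_cols}",
            }
        )
        gram = runs.T @ runs
        off = gram - np.diag(np.diag(gram))
        bad_pairs = [
            (int(i), int(j))
            for i in range(runs.shape[1])
            for j in range(i + 1, runs.shape[1])
            if off[i, j] != 0
        ]
        checks.append(
            {
                "name": "orthogonality",
                "passed": not bad_pairs,
                "detail": "all column pairs orthogonal"
                if not bad_pairs
                else f"non-orthogonal column pairs: {bad_pairs}",
            }
        )
    else:
        coded = design.coded.astype(int)
        center = design.center_flags
        n_center = int(center.sum())
        checks.append(
            {
                "name": "center_runs",
                "passed": n_center >= 1,
                "detail": f"{n_center} center runs",
            }
        )
        edges = coded[~center]
        ok_edges = (
            edges.shape[0] == 12
            and np.all(np.sum(edges == 0, axis=1) == 1)
            and np.all(np.sum(np.abs(edges), axis=1) == 2)
        )
        if ok_edges:
            # every factor pair must show all 4 sign combinations exactly once
            for i, j in itertools.combinations(range(3), 2):
                sub = edges[(edges[:, i] != 0) & (edges[:, j] != 0)][:, [i, j]]
                pairs = {tuple(r) for r in sub}
                if len(sub) != 4 or pairs != {(-1, -1), (-1, 1), (1, -1), (1, 1)}:
                    ok_edges = False
                    break
        checks.append(
            {
                "name": "bbd_edges",
                "passed": bool(ok_edges),
                "detail": "12 edge runs covering all sign pairs"
                if ok_edges
                else "edge-run structure violated",
            }
        )
        sums = coded.sum(axis=0)
        checks.append(
            {
                "name": "column_sums",
                "passed": bool(np.all(sums == 0)),
                "detail": f"column sums {sums.tolist()}",
            }
        )
    return ValidationReport(checks=checks)


def shuffle_runs(design: DesignMatrix, seed: int) -> DesignMatrix:
    """Randomize run order for planning a new experiment (explicit seed)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(design.n_runs)
    return DesignMatrix(
        factors=design.factors,
        runs=design.runs[order],
        run_labels=[design.run_labels[i] for i in order],
        dummy_labels=design.dummy_labels,
    )
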