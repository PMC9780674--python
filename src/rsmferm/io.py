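"""CSV/JSON readers and writers, report formatting, and the pipeline.

File conventions
----------------
* Design CSV: header ``run,<factor1>,<factor2>,...[,is_center]`` with
  integer coded levels; UTF-8, comma-separated, ``.`` decimal.
* Response CSV: header ``run,mean[,se][,n_reps]``; a single response
  column containing ``"1.75 ± 0.01"`` strings is split into mean/se on
  ingest.
* Factor config: JSON or YAML list of ``{name, unit, center, step}`` or
  ``{name, unit, low, high}``.

Full-precision values always go into the JSON artifacts; the rounded
report layer (coefficients 4 dp, F 2 dp, p 4 dp) exists only to mirror how
published ANOVA tables are printed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .ascent import AscentPath, path_from_grid, select_center
from .design import DesignMatrix, FactorDef, ResponseSet
from .optimum import OptimumResult, constrained_max, verification_summary
from .rsm import QuadraticResponseSurface, fit_quadratic
from .screening import FirstOrderScreening, fit_first_order

logger = logging.getLogger("rsmferm")

__all__ = [
    "PipelineHalt",
    "read_factors",
    "write_factors",
    "read_design",
    "write_design",
    "read_response",
    "write_response",
    "format_anova",
    "format_equation",
    "write_report",
    "PipelineConfig",
    "run_pipeline",
]


class PipelineHalt(Exception):
    """A statistically-motivated stop (e.g. no significant screening factors)."""


def read_factors(path) -> list[FactorDef]:
    """Load factor definitions from a JSON or YAML list."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    items = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(items, list):
        raise ValueError(f"{path}: factor config must be a list of mappings")
    factors = []
    for i, item in enumerate(items):
        name = item.get("name")
        if not name:
            raise ValueError(f"{path}: factor entry {i} is missing 'name'")
        unit = item.get("unit", "%")
        if "center" in item and "step" in item:
            factors.append(FactorDef(name=name, center=float(item["center"]),
                                     step=float(item["step"]), unit=unit))
        elif "low" in item and "high" in item:
            factors.append(FactorDef.from_levels(name, float(item["low"]),
                                                 float(item["high"]), unit=unit))
        else:
            raise ValueError(
                f"{path}: factor {name!r} needs either center+step or low+high"
            )
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate factor names")
    return factors


def write_factors(factors: list[FactorDef], path) -> None:
    items = [
        {"name": f.name, "unit": f.unit, "center": f.center, "step": f.step}
        for f in factors
    ]
    Path(path).write_text(json.dumps(items, indent=2), encoding="utf-8")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return pd.read_csv(path, dtype=str).rename(columns=str.strip)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        row = int(bad[0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column {col!r}, line {row}"
        )
    if df[col].isna().any():
        run = df.index[df[col].isna()][0]
        label = df["run"].iloc[run] if "run" in df else run
        raise ValueError(f"{path}: missing value in column {col!r} for run {label!r}")
    return vals.to_numpy(dtype=float)


def read_design(path, factors: list[FactorDef] | None = None) -> DesignMatrix:
    """Read a coded design CSV.

    When ``factors`` are given, the header's factor columns must match
    their names (any order); otherwise unit-step placeholder factors are
    created from the header.  Columns named ``dummy*`` become dummy
    columns.
    """
    df = _read_csv(path)
    if "run" not in df.columns:
        raise ValueError(f"{path}: design CSV must have a 'run' column")
    cols = [c for c in df.columns if c not in {"run", "is_center"}]
    dummy_cols = [c for c in cols if c.lower().startswith("dummy")]
    factor_cols = [c for c in cols if c not in dummy_cols]
    if factors is not None:
        names = [f.name for f in factors]
        if set(names) != set(factor_cols):
            raise ValueError(
                f"{path}: design columns {factor_cols} do not match declared factors {names}"
            )
        factor_cols = names
    else:
        factors = [FactorDef(name=c, center=0.0, step=1.0) for c in factor_cols]

    mat = np.column_stack(
        [_numeric(df, c, path) for c in factor_cols + dummy_cols]
    )
    if not np.all(np.isin(mat, (-1.0, 0.0, 1.0))):
        bad = np.argwhere(~np.isin(mat, (-1.0, 0.0, 1.0)))[0]
        raise ValueError(
            f"{path}: coded levels must be -1/0/+1; found {mat[tuple(bad)]} "
            f"(run {df['run'].iloc[bad[0]]!r}, column {(factor_cols + dummy_cols)[bad[1]]!r})"
        )
    labels = [str(v).strip() for v in df["run"]]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate run labels {dupes}")
    return DesignMatrix(
        factors=factors,
        runs=mat.astype(int),
        run_labels=labels,
        dummy_labels=dummy_cols,
    )


def write_design(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path)


def read_response(path) -> ResponseSet:
    """Read a response CSV; ``mean ± se`` strings are split on ingest."""
    df = _read_csv(path)
    if "run" not in df.columns:
        raise ValueError(f"{path}: response CSV must have a 'run' column")
    labels = [str(v).strip() for v in df["run"]]
    se = None
    n_reps = None
    if "mean" in df.columns:
        mean = _numeric(df, "mean", path)
        if "se" in df.columns:
            se = _numeric(df, "se", path)
    else:
        value_cols = [c for c in df.columns if c not in {"run", "n_reps"}]
        if len(value_cols) != 1:
            raise ValueError(
                f"{path}: expected a 'mean' column or exactly one response column, got {value_cols}"
            )
        col = value_cols[0]
        if df[col].isna().any():
            run = labels[int(df.index[df[col].isna()][0])]
            raise ValueError(f"{path}: missing response for run {run!r}")
        if df[col].astype(str).str.contains("±").any():
            parts = df[col].astype(str).str.split("±", expand=True)
            df["mean"], df["se"] = parts[0].str.strip(), parts[1].str.strip()
            mean = _numeric(df, "mean", path)
            se = _numeric(df, "se", path)
        else:
            mean = _numeric(df, col, path)
    if "n_reps" in df.columns:
        n_reps = _numeric(df, "n_reps", path).astype(int)
    return ResponseSet(run_labels=labels, mean=mean, se=se, n_reps=n_reps)


def write_response(responses: ResponseSet, path) -> None:
    responses.to_frame().to_csv(path)


def format_anova(anova: pd.DataFrame) -> pd.DataFrame:
    """Round an ANOVA table the way published tables print it.

    SS/MS at 4 dp, F at 2 dp, p at 4 dp; full precision stays in the
    unrounded table and the JSON artifacts.
    """
    out = anova.copy()
    out["sum_sq"] = out["sum_sq"].round(4)
    out["mean_sq"] = out["mean_sq"].round(4)
    out["F"] = out["F"].round(2)
    out["p"] = out["p"].round(4)
    return out.rename(
        columns={"sum_sq": "Sum of squares", "df": "df", "mean_sq": "Mean square",
                 "F": "F-value", "p": "p-value", "signif": ""}
    )


def format_equation(intercept: float, coefs: pd.Series | dict, response: str = "Y%", dp: int = 4) -> str:
    """Human-readable fitted polynomial, e.g. ``Y% = 1.6442 + 0.0925*peptone``."""
    if isinstance(coefs, dict):
        coefs = pd.Series(coefs)
    parts = [f"{response} = {round(intercept, dp)}"]
    for name, c in coefs.items():
        sign = "+" if c >= 0 else "-"
        parts.append(f"{sign} {round(abs(c), dp)}*{name}")
    return " ".join(parts)


def _fit_payload(fit) -> dict:
    payload = {
        "intercept": fit.intercept_,
        "coefficients": dict(zip(getattr(fit, "term_names_", fit.feature_names_in_), fit.coef_)),
        "r2": fit.r2_,
        "r2_adj": fit.r2_adj_,
        "anova": fit.anova_.replace({np.nan: None}).reset_index().to_dict(orient="records"),
        "fitted_values": fit.fitted_values_.tolist(),
        "residuals": fit.residuals_.tolist(),
    }
    if isinstance(fit, QuadraticResponseSurface):
        payload["cv_percent"] = fit.cv_percent_
    if isinstance(fit, FirstOrderScreening) and fit.contribution_ is not None:
        payload["contribution_pct"] = fit.contribution_.to_dict()
    return payload


def write_report(
    outdir,
    screening_fit: FirstOrderScreening | None = None,
    quadratic_fit: QuadraticResponseSurface | None = None,
    optimum: OptimumResult | None = None,
    verification: dict | None = None,
) -> dict:
    """Persist fitted-stage artifacts: CSV tables, JSON, and a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: list[str] = []
    artifacts: dict = {}

    if screening_fit is not None:
        format_anova(screening_fit.anova_).to_csv(outdir / "screening_anova.csv")
        artifacts["screening"] = _fit_payload(screening_fit)
        eq = format_equation(
            screening_fit.intercept_,
            pd.Series(screening_fit.coef_, index=screening_fit.feature_names_in_),
        )
        summary += [
            "Screening (first-order) fit",
            f"  {eq}",
            f"  R2 = {screening_fit.r2_:.4f}, adj R2 = {screening_fit.r2_adj_:.4f}",
            "",
        ]
    if quadratic_fit is not None:
        format_anova(quadratic_fit.anova_).to_csv(outdir / "rsm_anova.csv")
        artifacts["rsm"] = _fit_payload(quadratic_fit)
        eq = format_equation(
            quadratic_fit.intercept_,
            pd.Series(quadratic_fit.coef_, index=quadratic_fit.term_names_),
        )
        summary += [
            "Response-surface (quadratic) fit",
            f"  {eq}",
            f"  R2 = {quadratic_fit.r2_:.4f}, adj R2 = {quadratic_fit.r2_adj_:.4f}, "
            f"CV = {quadratic_fit.cv_percent_:.2f}%",
            "",
        ]
    if optimum is not None:
        artifacts["optimum"] = optimum.to_dict()
        summary.append("Constrained optimum (coded design cube)")
        summary.append(
            f"  coded {np.round(optimum.constrained_coded, 3).tolist()} -> "
            f"predicted {optimum.predicted_response:.4f}%"
        )
        if optimum.constrained_actual:
            summary.append(f"  actual settings: {optimum.constrained_actual}")
        if optimum.stationary is not None:
            summary.append(
                f"  stationary point {np.round(optimum.stationary.coded, 3).tolist()} "
                f"({optimum.stationary.nature})"
            )
        summary.append("")
    if verification is not None:
        artifacts["verification"] = verification
        summary.append(
            f"Verification: predicted {verification['predicted']:.2f}% vs observed "
            f"{verification['observed_mean']:.2f}% "
            f"(abs dev {verification['absolute_deviation']:.2f} pp)"
        )

    (outdir / "report.json").write_text(
        json.dumps(artifacts, indent=2, default=float), encoding="utf-8"
    )
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    return artifacts


class PipelineConfig(BaseModel):
    """End-to-end three-stage pipeline configuration."""

    mode: str = Field("files", pattern="^(files|synthetic)$")
    alpha: float = 0.05
    bounds: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    sigma: float | None = None  # synthetic mode noise override
    outdir: str = "rsmferm_out"
    # files mode inputs
    pb_factors: str | None = None
    pb_design: str | None = None
    pb_response: str | None = None
    ascent_path: str | None = None
    bbd_factors: str | None = None
    bbd_design: str | None = None
    bbd_response: str | None = None
    verification_mean: float | None = None
    verification_se: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode == "files":
            required = ["pb_design", "pb_response", "ascent_path", "bbd_design", "bbd_response"]
            missing = [f for f in required if getattr(self, f) is None]
            if missing:
                raise ValueError(f"files mode requires paths for: {missing}")
        return self


def _load_ascent_csv(path) -> AscentPath:
    df = _read_csv(path)
    resp_cols = [c for c in df.columns if c.startswith("response")]
    id_cols = [c for c in df.columns if c in {"step", "run"}]
    factor_cols = [c for c in df.columns if c not in resp_cols + id_cols]
    data = pd.DataFrame({c: _numeric(df, c, path) for c in factor_cols})
    moving = [c for c in factor_cols if data[c].nunique() > 1]
    fixed = {c: float(data[c].iloc[0]) for c in factor_cols if c not in moving}
    mean = _numeric(df, "response_mean", path) if "response_mean" in df.columns else None
    se = _numeric(df, "response_se", path) if "response_se" in df.columns else None
    return path_from_grid(data[moving], fixed=fixed, response_mean=mean, response_se=se)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute screening -> ascent -> quadratic surface -> optimum.

    Returns the artifact dictionary also persisted under ``config.outdir``.
    Raises :class:`PipelineHalt` when screening selects no factor at the
    configured ``alpha``.
    """
    logger.info(
        "pipeline start: version=%s seed=%d config_sha256=%s",
        __version__,
        config.seed,
        hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12],
    )
    if config.mode == "synthetic":
        from .simulate import scenario_study, simulate_responses

        scen = scenario_study()
        if config.sigma is not None:
            scen.screen_truth.sigma = config.sigma
            scen.surface_truth.sigma = config.sigma
        pb_design = scen.pb_design
        pb_resp = simulate_responses(pb_design, scen.screen_truth, seed=config.seed)
        bbd_design = scen.bbd_design
        bbd_resp = simulate_responses(bbd_design, scen.surface_truth, seed=config.seed + 1)
        path = scen.simulate_ascent(seed=config.seed + 2)
        bbd_factors = bbd_design.factors
        verification = None
    else:
        pb_factors = read_factors(config.pb_factors) if config.pb_factors else None
        pb_design = read_design(config.pb_design, factors=pb_factors)
        pb_resp = read_response(config.pb_response)
        path = _load_ascent_csv(config.ascent_path)
        bbd_factors = read_factors(config.bbd_factors) if config.bbd_factors else None
        bbd_design = read_design(config.bbd_design, factors=bbd_factors)
        bbd_resp = read_response(config.bbd_response)
        bbd_factors = bbd_design.factors
        verification = None

    screen = fit_first_order(pb_design, pb_resp)
    selection = screen.select(config.alpha)
    if not selection["selected"].any():
        raise PipelineHalt(
            f"no significant factors at alpha={config.alpha}; screening cannot "
            "direct the ascent stage"
        )
    logger.info("selected factors: %s", list(selection.index[selection["selected"]]))

    center_settings, _center_factors = select_center(path)
    logger.info("ascent center: %s", center_settings)

    quad = fit_quadratic(bbd_design, bbd_resp)
    opt = constrained_max(quad, bounds=config.bounds, factors=bbd_factors)
    if config.verification_mean is not None:
        verification = verification_summary(
            opt.predicted_response, config.verification_mean, config.verification_se
        )

    artifacts = write_report(
        config.outdir,
        screening_fit=screen,
        quadratic_fit=quad,
        optimum=opt,
        verification=verification,
    )
    artifacts["selection"] = selection.reset_index().to_dict(orient="records")
    artifacts["ascent_center"] = center_settings
    (Path(config.outdir) / "report.json").write_text(
        json.dumps(artifacts, indent=2, default=_json_default), encoding="utf-8"
    )
    return artifacts


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return float(obj)
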