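"""End-to-end case-crossover analysis pipeline.

Orchestrates the full study: link gridded exposures to the stratum table,
fit unadjusted / adjusted single-pollutant models, concentration-response
curves, two-pollutant models behind a Pearson-correlation collinearity
screen, subgroup (effect-modification) analyses with a joint interaction
test, and lag-structure sensitivity analyses.

Model conventions, all config-exposed:

* the pollutant enters at its MA 0-1 (event day and the day before) mean,
  pre-divided by the reporting unit (10 ug/m3; 1 mg/m3 for CO) so the
  coefficient is directly the per-unit log odds ratio;
* adjusted models add natural cubic splines (df = 4) of the MA 0-4
  temperature and relative humidity;
* pollutant pairs with Pearson r above 0.8 over the observation days are
  refused in two-pollutant models;
* model comparisons (lag sensitivity, meteorology-lag BIC selection) are
  restricted to the rows on which every candidate is observable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clogit import (
    ClogitDesign,
    EffectEstimate,
    fit_clogit,
    likelihood_ratio_test,
    percent_change,
)
from .grids import GridField, LagSpec, lagged_points
from .referents import drop_incomplete
from .simulate import DEFAULT_UNIT_SCALES
from .splines import SplineSpec

__all__ = [
    "AnalysisConfig",
    "ScreenRefusal",
    "link_exposure",
    "exposure_long_table",
    "run_single_pollutant",
    "correlation_screen",
    "run_two_pollutant",
    "run_subgroups",
    "concentration_response",
    "lag_sensitivity",
    "bic_lag_selection",
    "CurveEstimate",
    "write_report",
]

#: Display names used in emitted tables.
POLLUTANT_LABELS = {
    "pm1": "PM1",
    "pm25": "PM2.5",
    "pm10": "PM10",
    "co": "CO",
    "no2": "NO2",
    "o3": "O3",
    "so2": "SO2",
}

PM_POLLUTANTS = ("pm1", "pm25", "pm10")
GAS_POLLUTANTS = ("co", "no2", "o3", "so2")


class ScreenRefusal(RuntimeError):
    """Two-pollutant model refused by the collinearity screen."""


@dataclass
class AnalysisConfig:
    """All tunable analysis settings with the study defaults."""

    pollutants: list[str] = field(default_factory=lambda: list(POLLUTANT_LABELS))
    main_lag: str = "MA 0-1"
    met_lag: str = "MA 0-4"
    spline_df: int = 4
    correlation_threshold: float = 0.8
    unit_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UNIT_SCALES))
    subgroup_variables: list[str] = field(
        default_factory=lambda: ["age_band", "sex", "education", "marital",
                                 "occupation", "subtype", "season", "year", "region"]
    )
    sensitivity_lags: list[str] = field(
        default_factory=lambda: ["lag 0", "lag 1", "lag 2", "lag 3",
                                 "MA 0-1", "MA 0-2", "MA 0-3"]
    )
    candidate_met_lags: list[str] = field(
        default_factory=lambda: ["lag 0", "MA 0-1", "MA 0-2", "MA 0-3", "MA 0-4"]
    )
    min_strata_per_level: int = 50
    curve_reference: str = "median"
    curve_grid_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError("correlation threshold must lie in (0, 1]")
        for p in self.pollutants:
            if p not in self.unit_scales:
                raise ValueError(f"pollutant {p!r} lacks a unit scale")

    @property
    def main_lag_spec(self) -> LagSpec:
        return LagSpec.parse(self.main_lag)

    @property
    def met_lag_spec(self) -> LagSpec:
        return LagSpec.parse(self.met_lag)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


# ---------------------------------------------------------------------------
# Exposure linkage
# ---------------------------------------------------------------------------

def _met_columns(config: AnalysisConfig, lag: LagSpec | None = None) -> list[str]:
    lag = lag or config.met_lag_spec
    return [f"temperature_{lag.tag}", f"humidity_{lag.tag}"]


def link_exposure(
    strata: pd.DataFrame,
    cases: pd.DataFrame,
    fields: dict[str, GridField],
    requests: list[tuple[str, LagSpec]],
) -> pd.DataFrame:
    """Attach lagged, point-interpolated exposure columns to a stratum table.

    ``cases`` supplies each stratum's residential coordinates (column ``id``
    matching ``stratum_id``).  One column ``{variable}_{lagtag}`` is added
    per request; days whose window is missing or precedes the field's date
    axis get NaN.
    """
    out = strata.copy()
    coord = cases.set_index("id")
    lats = coord["lat"].reindex(out["stratum_id"]).to_numpy()
    lons = coord["lon"].reindex(out["stratum_id"]).to_numpy()
    days = pd.to_datetime(out["date"]).to_numpy().astype("datetime64[D]")
    for var, spec in requests:
        vals, _ = lagged_points(fields[var], lats, lons, days, spec)
        out[f"{var}_{spec.tag}"] = vals
    return out


def exposure_long_table(
    strata: pd.DataFrame,
    cases: pd.DataFrame,
    fields: dict[str, GridField],
    variables: list[str],
) -> pd.DataFrame:
    """Long per-day exposure export: point_id, variable, date, value, n_grids_used."""
    coord = cases.set_index("id")
    lats = coord["lat"].reindex(strata["stratum_id"]).to_numpy()
    lons = coord["lon"].reindex(strata["stratum_id"]).to_numpy()
    days = pd.to_datetime(strata["date"]).to_numpy().astype("datetime64[D]")
    frames = []
    for var in variables:
        fld = fields[var]
        tidx = ((days - fld.start) / np.timedelta64(1, "D")).astype(np.int64)
        from .grids import interpolate_points

        vals, n_used = interpolate_points(fld, lats, lons, tidx)
        frames.append(
            pd.DataFrame(
                {
                    "point_id": strata["stratum_id"].to_numpy(),
                    "variable": var,
                    "date": days.astype(str),
                    "value": vals,
                    "n_grids_used": n_used,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _spline_block(df: pd.DataFrame, col: str, sp: int, specs: dict) -> tuple[np.ndarray, list[str]]:
    if col not in specs:
        specs[col] = SplineSpec.from_data(df[col].to_numpy(), df=sp)
    basis = specs[col].basis(df[col].to_numpy())
    names = [f"ns({col})[{i}]" for i in range(basis.shape[1])]
    return basis, names


def _build_design(
    df: pd.DataFrame,
    config: AnalysisConfig,
    pollutant_cols: list[tuple[str, str]],
    *,
    adjusted: bool = True,
    met_lag: LagSpec | None = None,
    extra: list[tuple[str, np.ndarray]] | None = None,
    spline_specs: dict | None = None,
):
    """Assemble a ClogitDesign: scaled pollutant terms [+ met splines][+ extra].

    ``pollutant_cols`` holds (pollutant, linked column) pairs; the scaled
    covariate is named after the pollutant.  Returns (design, spline_specs).
    """
    specs = spline_specs if spline_specs is not None else {}
    mats, names = [], []
    for pol, col in pollutant_cols:
        mats.append(df[col].to_numpy(dtype=float)[:, None] / config.unit_scales[pol])
        names.append(pol)
    if adjusted:
        for col in _met_columns(config, met_lag):
            b, nm = _spline_block(df, col, config.spline_df, specs)
            mats.append(b)
            names.extend(nm)
    for nm, arr in extra or []:
        mats.append(np.asarray(arr, dtype=float)[:, None])
        names.append(nm)
    X = np.hstack(mats)
    tmp = df[["stratum_id", "is_case"]].copy()
    work = pd.concat([tmp.reset_index(drop=True), pd.DataFrame(X, columns=names)], axis=1)
    design = ClogitDesign.from_frame(work, names)
    return design, specs


def _prepare(
    strata: pd.DataFrame, config: AnalysisConfig, required: list[str]
) -> tuple[pd.DataFrame, dict]:
    clean, log = drop_incomplete(strata, required)
    if clean.empty:
        raise ValueError("no strata remain after missing-data exclusion")
    return clean, log


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def run_single_pollutant(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutant: str,
    *,
    adjusted: bool = True,
    lag: LagSpec | None = None,
    return_fit: bool = False,
):
    """Unadjusted or meteorology-adjusted single-pollutant model.

    The unadjusted model contains the pollutant term only (the matched-set
    conditioning itself accounts for case clustering); the adjusted model
    adds the df-4 natural splines of MA 0-4 temperature and humidity.
    """
    lag = lag or config.main_lag_spec
    col = f"{pollutant}_{lag.tag}"
    required = [col] + (_met_columns(config) if adjusted else [])
    clean, _ = _prepare(strata, config, required)
    design, _ = _build_design(
        clean, config, [(pollutant, col)], adjusted=adjusted
    )
    fit = fit_clogit(design)
    est = percent_change(
        fit,
        pollutant,
        pollutant=POLLUTANT_LABELS.get(pollutant, pollutant),
        lag=lag.label,
        model="adjusted" if adjusted else "unadjusted",
    )
    return (est, fit) if return_fit else est


def correlation_screen(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutants: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of MA 0-1 exposures over observation days.

    Pairs with r above the threshold (or undefined r from a zero-variance
    series) are excluded from two-pollutant modelling.  Returns the screen
    report (pollutant_a, pollutant_b, r, excluded, reason).
    """
    pollutants = pollutants or config.pollutants
    tag = config.main_lag_spec.tag
    rows = []
    for i, a in enumerate(pollutants):
        for b in pollutants[i + 1:]:
            xa = strata[f"{a}_{tag}"].to_numpy(dtype=float)
            xb = strata[f"{b}_{tag}"].to_numpy(dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3 or np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
                rows.append((a, b, np.nan, True, "undefined r"))
                continue
            r = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
            excl = r > config.correlation_threshold
            rows.append((a, b, r, excl, "r above threshold" if excl else "kept"))
    return pd.DataFrame(
        rows, columns=["pollutant_a", "pollutant_b", "r", "excluded", "reason"]
    )


def run_two_pollutant(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutant_a: str,
    pollutant_b: str,
    *,
    screen: pd.DataFrame | None = None,
):
    """Adjusted model with both pollutant terms; refused for collinear pairs."""
    if pollutant_a == pollutant_b:
        raise ScreenRefusal(f"{pollutant_a} with itself has r = 1")
    if screen is None:
        screen = correlation_screen(strata, config, [pollutant_a, pollutant_b])
    pair = screen[
        ((screen["pollutant_a"] == pollutant_a) & (screen["pollutant_b"] == pollutant_b))
        | ((screen["pollutant_a"] == pollutant_b) & (screen["pollutant_b"] == pollutant_a))
    ]
    if pair.empty:
        raise ValueError("pair missing from screen report")
    row = pair.iloc[0]
    if bool(row["excluded"]):
        raise ScreenRefusal(
            f"pair ({pollutant_a}, {pollutant_b}) excluded by the screen: "
            f"r = {row['r']:.3f} ({row['reason']})"
        )
    tag = config.main_lag_spec.tag
    cols = [(pollutant_a, f"{pollutant_a}_{tag}"), (pollutant_b, f"{pollutant_b}_{tag}")]
    required = [c for _, c in cols] + _met_columns(config)
    clean, _ = _prepare(strata, config, required)
    design, _ = _build_design(clean, config, cols, adjusted=True)
    fit = fit_clogit(design)
    lag = config.main_lag_spec.label
    out = []
    for pol in (pollutant_a, pollutant_b):
        other = pollutant_b if pol == pollutant_a else pollutant_a
        out.append(
            percent_change(
                fit,
                pol,
                pollutant=POLLUTANT_LABELS.get(pol, pol),
                lag=lag,
                model=f"two-pollutant (+{POLLUTANT_LABELS.get(other, other)})",
            )
        )
    return tuple(out)


def run_subgroups(
    strata: pd.DataFrame,
    cases: pd.DataFrame,
    config: AnalysisConfig,
    pollutant: str,
    variable: str,
):
    """Stratified estimates by subgroup level plus a joint interaction test.

    Levels with fewer strata than the configured minimum are skipped (and
    reported).  The joint test compares the pooled adjusted model with and
    without pollutant-by-level interaction terms via a likelihood-ratio
    chi-square on L-1 degrees of freedom; with a single level it is refused
    (0 df).
    """
    tag = config.main_lag_spec.tag
    col = f"{pollutant}_{tag}"
    level_of = cases.set_index("id")[variable]
    work = strata.copy()
    work["_level"] = level_of.reindex(work["stratum_id"]).to_numpy()

    required = [col] + _met_columns(config)
    clean, _ = _prepare(work, config, required)
    levels = sorted(pd.unique(clean["_level"].astype(str)))

    per_level: list[EffectEstimate] = []
    skipped: list[str] = []
    for lv in levels:
        sub = clean[clean["_level"].astype(str) == lv]
        if sub["stratum_id"].nunique() < config.min_strata_per_level:
            skipped.append(lv)
            continue
        est = run_single_pollutant(sub, config, pollutant, adjusted=True)
        est.model = f"subgroup {variable}={lv}"
        per_level.append(est)

    if len(levels) < 2:
        return per_level, None, {"skipped_levels": skipped, "df": 0,
                                 "note": "interaction test refused: single level"}

    # pooled fits with / without pollutant x level interaction columns
    x = clean[col].to_numpy(dtype=float) / config.unit_scales[pollutant]
    extra = [
        (f"{pollutant}:{variable}={lv}",
         x * (clean["_level"].astype(str) == lv).to_numpy(dtype=float))
        for lv in levels[1:]
    ]
    specs: dict = {}
    full_design, specs = _build_design(
        clean, config, [(pollutant, col)], adjusted=True, extra=extra,
        spline_specs=specs,
    )
    red_design, _ = _build_design(
        clean, config, [(pollutant, col)], adjusted=True, spline_specs=specs
    )
    full = fit_clogit(full_design)
    red = fit_clogit(red_design)
    stat, df, p = likelihood_ratio_test(full, red)
    return per_level, p, {"skipped_levels": skipped, "statistic": stat, "df": df}


@dataclass
class CurveEstimate:
    """Concentration-response curve on the log-odds scale vs a reference."""

    pollutant: str
    grid: np.ndarray
    log_odds: np.ndarray
    se: np.ndarray
    reference: float

    @property
    def ci_low(self) -> np.ndarray:
        return self.log_odds - 1.959964 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.log_odds + 1.959964 * self.se

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pollutant": self.pollutant,
                "concentration": self.grid,
                "log_odds": self.log_odds,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "reference": self.reference,
            }
        )


def concentration_response(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutant: str,
) -> CurveEstimate:
    """Adjusted spline concentration-response curve for one pollutant.

    The pollutant's MA 0-1 concentration enters through a df-4 natural
    cubic spline alongside the meteorology splines; the curve is
    eta(c) = [B(c) - B(c_ref)]' beta over a 1st-99th percentile grid with
    pointwise delta-method CIs, anchored at 0 (zero-width CI) at the
    reference concentration (the retained-day median by default).
    """
    tag = config.main_lag_spec.tag
    col = f"{pollutant}_{tag}"
    required = [col] + _met_columns(config)
    clean, _ = _prepare(strata, config, required)

    xvals = clean[col].to_numpy(dtype=float)
    pol_spec = SplineSpec.from_data(xvals, df=config.spline_df)
    basis = pol_spec.basis(xvals)
    names = [f"ns({pollutant})[{i}]" for i in range(basis.shape[1])]
    extra = [(nm, basis[:, i]) for i, nm in enumerate(names)]
    design, _ = _build_design(clean, config, [], adjusted=True, extra=extra)
    fit = fit_clogit(design)

    if config.curve_reference == "median":
        ref = float(np.median(xvals))
    else:
        ref = float(config.curve_reference)
    lo, hi = np.percentile(xvals, [1.0, 99.0])
    grid = np.linspace(lo, hi, config.curve_grid_points)
    grid = np.unique(np.append(grid, ref))  # anchor point carried exactly
    A = pol_spec.basis(grid) - pol_spec.basis(np.full(1, ref))
    beta = fit.params[names].to_numpy()
    cov = fit.cov.loc[names, names].to_numpy()
    eta = A @ beta
    var = np.einsum("ij,jk,ik->i", A, cov, A)
    return CurveEstimate(
        pollutant=POLLUTANT_LABELS.get(pollutant, pollutant),
        grid=grid,
        log_odds=eta,
        se=np.sqrt(np.maximum(var, 0.0)),
        reference=ref,
    )


def _common_rows(strata: pd.DataFrame, config: AnalysisConfig, cols: list[str]):
    """Restrict to rows observable under every candidate column, then apply
    the usual case/control completeness rules once."""
    return _prepare(strata, config, cols)


def lag_sensitivity(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutant: str,
) -> pd.DataFrame:
    """Adjusted estimates across alternative pollutant lag structures.

    All candidate lags are fitted on the common rows where every lag and
    the meteorology covariates are observed, so estimates are comparable.
    """
    specs = [LagSpec.parse(s) for s in config.sensitivity_lags]
    cols = [f"{pollutant}_{sp.tag}" for sp in specs]
    clean, _ = _common_rows(strata, config, cols + _met_columns(config))
    rows = []
    for sp, col in zip(specs, cols):
        design, _ = _build_design(clean, config, [(pollutant, col)], adjusted=True)
        fit = fit_clogit(design)
        est = percent_change(
            fit, pollutant,
            pollutant=POLLUTANT_LABELS.get(pollutant, pollutant),
            lag=sp.label, model="adjusted",
        )
        rows.append(est.as_dict())
    return pd.DataFrame(rows)


def bic_lag_selection(
    strata: pd.DataFrame,
    config: AnalysisConfig,
    pollutant: str,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Rank meteorology lag candidates by BIC of the adjusted model.

    Each candidate applies the same lag spec to both temperature and
    relative humidity; all candidates are fitted on identical rows and the
    table is sorted ascending by BIC (ties broken by label for
    determinism).
    """
    labels = candidates if candidates is not None else config.candidate_met_lags
    specs = [LagSpec.parse(s) for s in labels]
    all_cols = [c for sp in specs for c in _met_columns(config, sp)]
    main_col = f"{pollutant}_{config.main_lag_spec.tag}"
    clean, _ = _common_rows(strata, config, [main_col] + all_cols)
    rows = []
    for label, sp in zip(labels, specs):
        design, _ = _build_design(
            clean, config, [(pollutant, main_col)], adjusted=True, met_lag=sp
        )
        fit = fit_clogit(design)
        rows.append(
            {
                "met_lag": label,
                "bic": fit.bic,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "n_strata": fit.n_strata,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["bic", "met_lag"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_report(
    outdir: str | Path,
    config: AnalysisConfig,
    *,
    tables: dict[str, pd.DataFrame],
    manifest_extra: dict | None = None,
) -> Path:
    """Write a deterministic results bundle: CSV tables plus a JSON manifest
    (config hash, seed, row counts).  Identical inputs produce byte-identical
    files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "tables": {},
    }
    for name, df in sorted(tables.items()):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["tables"][name] = {"rows": int(len(df)), "file": path.name}
    if manifest_extra:
        manifest.update(manifest_extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
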