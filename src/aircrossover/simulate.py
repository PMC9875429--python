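"""Synthetic study generator with known truth.

Three layers are simulated so that every pipeline stage can be exercised
end-to-end without any external data:

* **Fields** — daily values of each pollutant / meteorological variable on a
  regular lat/lon grid, built from a seasonal cycle plus a unit-variance
  AR(1)-in-time, spatially smooth Gaussian anomaly.  Cross-variable
  correlation (e.g. the strong PM1/PM2.5/PM10 coupling) comes from shared
  latent factors.  Pollutants are log-normal by default (median and
  geometric SD are the parameters); meteorology is Gaussian.
* **Population** — residential locations uniform in the grid interior and
  categorical attributes (age band, sex, education, ...) drawn from
  configurable frequencies.
* **Deaths** — stratum-first: sample a person, a year-month and a weekday;
  the candidate days are all such weekdays of that month (the exact
  time-stratified referent set); the case day is drawn from the multinomial
  with weights exp(beta' x + gamma' z), where x is the causal pollutant's
  MA 0-1 exposure per reporting unit *computed through the same bilinear
  interpolation the analysis uses* and z are the meteorology confounder
  terms.  This is precisely the law whose conditional likelihood the fit
  maximises, so the fitted model is consistent for the injected truth.

All randomness flows through explicitly passed seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import GridField, LagSpec, lagged_points
from .referents import candidate_days, derive_season

__all__ = [
    "VariableParams",
    "FieldParams",
    "SimulationTruth",
    "simulate_fields",
    "simulate_population",
    "simulate_deaths",
    "national_fields",
    "national_truth",
    "DEFAULT_UNIT_SCALES",
    "DEFAULT_ATTRIBUTE_FREQUENCIES",
]

_DAY = np.timedelta64(1, "D")

#: Reporting units: percent changes are per 10 ug/m3, except CO per 1 mg/m3.
DEFAULT_UNIT_SCALES = {
    "pm1": 10.0,
    "pm25": 10.0,
    "pm10": 10.0,
    "co": 1.0,
    "no2": 10.0,
    "o3": 10.0,
    "so2": 10.0,
}

#: Default composition of the simulated deaths (shares per category).
DEFAULT_ATTRIBUTE_FREQUENCIES = {
    "sex": {"men": 0.579, "women": 0.421},
    "age_band": {"<60": 0.26, "60-69": 0.22, "70-79": 0.27, ">79": 0.25},
    "education": {"<HS": 0.895, ">=HS": 0.105},
    "marital": {"married": 0.728, "widowed": 0.201, "divorced/unmarried": 0.071},
    "occupation": {"retired": 0.134, "farmer": 0.665, "other": 0.201},
    "subtype": {
        "glomerular": 0.616,
        "acute kidney failure": 0.056,
        "chronic kidney disease": 0.098,
        "unspecified kidney failure": 0.143,
        "other": 0.087,
    },
    "region": {
        "Central": 0.185,
        "East": 0.257,
        "North": 0.088,
        "Northeast": 0.082,
        "Northwest": 0.056,
        "South": 0.137,
        "Southwest": 0.195,
    },
}


@dataclass(frozen=True)
class VariableParams:
    """Generative parameters of one daily field.

    ``dist`` is 'lognormal' (``level`` = median, ``sd`` = log-scale SD) or
    'gaussian' (``level`` = mean, ``sd`` = SD).  ``seasonal_amp`` and
    ``seasonal_phase`` act on the transform scale:
    s(t) = amp * cos(2*pi*doy/365.25 - phase), so phase 0 peaks on Jan 1 and
    phase pi peaks mid-year.  ``ar`` is the day-to-day AR(1) coefficient of
    the standardised anomaly; ``loadings`` map shared latent factor names to
    loadings (the residual loading is set so the anomaly stays unit
    variance).  ``nonnegative`` enforces the positivity margin for Gaussian
    concentration-like fields (mean at least 4 innovation SDs above zero).
    """

    name: str
    dist: str
    level: float
    sd: float
    seasonal_amp: float = 0.0
    seasonal_phase: float = 0.0
    ar: float = 0.3
    loadings: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    units: str = ""
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "gaussian"):
            raise ValueError("dist must be 'lognormal' or 'gaussian'")
        if not -1.0 < self.ar < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.sd < 0 or self.missing_rate < 0 or self.missing_rate >= 1:
            raise ValueError("invalid sd or missing rate")
        lam2 = sum(v * v for v in self.loadings.values())
        if lam2 > 1.0 + 1e-12:
            raise ValueError("squared factor loadings exceed 1")
        if self.dist == "gaussian" and self.nonnegative:
            innov_sd = self.sd * np.sqrt(1.0 - self.ar**2)
            if self.level < 4.0 * innov_sd:
                raise ValueError(
                    f"{self.name}: mean must sit >= 4 innovation SDs above zero"
                )


@dataclass(frozen=True)
class FieldParams:
    """Grid extent, date range (with lag buffer) and the variable set."""

    lat0: float
    lon0: float
    n_lat: int
    n_lon: int
    spacing: float
    start: str
    end: str
    variables: tuple[VariableParams, ...]
    buffer_days: int = 6
    spatial_range: float = 0.25
    factor_ar: float = 0.3

    def __post_init__(self) -> None:
        if self.n_lat < 2 or self.n_lon < 2 or self.spacing <= 0:
            raise ValueError("grid needs >= 2x2 cells with positive spacing")
        if self.buffer_days < 4:
            raise ValueError("date range needs a >= 4-day pre-study lag buffer")

    @property
    def dates(self) -> np.ndarray:
        d0 = np.datetime64(self.start, "D")
        d1 = np.datetime64(self.end, "D")
        return np.arange(d0, d1 + _DAY)

    @property
    def study_start(self) -> np.datetime64:
        return np.datetime64(self.start, "D") + self.buffer_days * _DAY

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.spacing * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.spacing * np.arange(self.n_lon)

    def variable(self, name: str) -> VariableParams:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class SimulationTruth:
    """Injected truth for recovery tests.

    ``causal`` maps pollutant names to the true percent change in odds per
    reporting unit.  ``gamma_temp`` / ``gamma_rh`` are log-odds per degree C
    / per percentage point of the MA 0-4 meteorology confounders.
    ``link`` is 'loglinear' or 'concave' (square-root, tangent-matched at
    ``concave_ref`` reporting units so the local slope there equals the
    causal coefficient).  ``modifiers`` optionally adds level-specific
    percent shifts of the causal effect for one subgroup variable.
    """

    causal: dict[str, float] = field(default_factory=dict)
    gamma_temp: float = 0.0
    gamma_rh: float = 0.0
    link: str = "loglinear"
    concave_ref: float = 3.0
    modifiers: dict[str, dict[str, float]] = field(default_factory=dict)
    unit_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UNIT_SCALES))

    def __post_init__(self) -> None:
        if self.link not in ("loglinear", "concave"):
            raise ValueError("link must be 'loglinear' or 'concave'")
        if len(self.modifiers) > 1:
            raise ValueError("at most one subgroup modifier variable")

    def beta(self, pollutant: str) -> float:
        """Log-odds per reporting unit implied by the percent truth."""
        return float(np.log1p(self.causal[pollutant] / 100.0))


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------

def _spatial_chol(lats: np.ndarray, lons: np.ndarray, rng_range: float) -> np.ndarray:
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    pts = np.column_stack([glat.ravel(), glon.ravel()])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * rng_range**2)) if rng_range > 0 else np.eye(len(pts))
    cov += 1e-8 * np.eye(len(pts))
    L = np.linalg.cholesky(cov)
    # normalise rows so marginal variance is exactly 1
    return L / np.sqrt((L**2).sum(axis=1, keepdims=True))


def _unit_process(rng: np.random.Generator, n_days: int, L: np.ndarray, ar: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) process with spatially smooth innovations."""
    n_cells = L.shape[0]
    eta = rng.standard_normal((n_days, n_cells)) @ L.T
    z = np.empty_like(eta)
    z[0] = eta[0]
    a, b = ar, np.sqrt(1.0 - ar**2)
    for t in range(1, n_days):
        z[t] = a * z[t - 1] + b * eta[t]
    return z


def simulate_fields(params: FieldParams, seed: int) -> dict[str, GridField]:
    """Generate all variable fields; reproducible from the seed."""
    rng = np.random.default_rng(seed)
    dates = params.dates
    n_days = dates.size
    lats, lons = params.lats, params.lons
    L = _spatial_chol(lats, lons, params.spatial_range)

    factor_names = sorted({f for v in params.variables for f in v.loadings})
    factors = {f: _unit_process(rng, n_days, L, params.factor_ar) for f in factor_names}

    doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")) / _DAY
    shape = (n_days, lats.size, lons.size)
    out: dict[str, GridField] = {}
    for v in params.variables:
        lam2 = sum(w * w for w in v.loadings.values())
        z = np.zeros((n_days, L.shape[0]))
        for f, w in v.loadings.items():
            z += w * factors[f]
        if lam2 < 1.0:
            z += np.sqrt(1.0 - lam2) * _unit_process(rng, n_days, L, v.ar)
        seasonal = v.seasonal_amp * np.cos(2.0 * np.pi * doy / 365.25 - v.seasonal_phase)
        anom = v.sd * z + seasonal[:, None]
        if v.dist == "lognormal":
            vals = np.exp(np.log(v.level) + anom)
        else:
            vals = v.level + anom
        vals = vals.reshape(shape)
        if v.missing_rate > 0:
            vals = np.where(rng.random(shape) < v.missing_rate, np.nan, vals)
        out[v.name] = GridField(
            name=v.name, lats=lats, lons=lons, dates=dates, values=vals, units=v.units
        )
    return out


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def simulate_population(
    n_persons: int,
    params: FieldParams,
    seed: int,
    *,
    frequencies: dict | None = None,
    edge_testing: bool = False,
) -> pd.DataFrame:
    """Residential locations and subgroup attributes for ``n_persons``.

    Locations are uniform at least one cell inside the hull of grid centers;
    with ``edge_testing`` one tenth are placed in the half-spacing band just
    outside the hull, exercising bilinear weight re-distribution.
    """
    if n_persons < 1:
        raise ValueError("need n_persons >= 1")
    rng = np.random.default_rng(seed)
    freqs = frequencies or DEFAULT_ATTRIBUTE_FREQUENCIES
    lats, lons, d = params.lats, params.lons, params.spacing
    lat = rng.uniform(lats[0] + d, lats[-1] - d, n_persons)
    lon = rng.uniform(lons[0] + d, lons[-1] - d, n_persons)
    if edge_testing:
        n_edge = max(1, n_persons // 10)
        idx = rng.choice(n_persons, n_edge, replace=False)
        lat[idx] = lats[-1] + rng.uniform(0.05, 0.45, n_edge) * d
        lon[idx] = rng.uniform(lons[0], lons[-1], n_edge)
    df = pd.DataFrame({"person": np.arange(n_persons), "lat": lat, "lon": lon})
    for var, table in freqs.items():
        levels = list(table)
        p = np.asarray([table[k] for k in levels], dtype=float)
        df[var] = rng.choice(levels, size=n_persons, p=p / p.sum())
    return df


# ---------------------------------------------------------------------------
# Deaths
# ---------------------------------------------------------------------------

def _study_months(params: FieldParams) -> np.ndarray:
    """Year-months fully contained in the post-buffer study window."""
    first = params.study_start.astype("datetime64[M]")
    if first.astype("datetime64[D]") < params.study_start:
        first += 1
    last = (params.dates[-1] + _DAY).astype("datetime64[M]") - 1
    if (last + 1).astype("datetime64[D]") - _DAY > params.dates[-1]:
        last -= 1
    if last < first:
        raise ValueError("date range contains no complete study month")
    return np.arange(first, last + 1)


def _pollutant_term(x: np.ndarray, beta: np.ndarray, truth: SimulationTruth) -> np.ndarray:
    if truth.link == "loglinear":
        return beta * x
    r = truth.concave_ref
    # concave-down, tangent-matched at x = r: slope there equals beta
    return beta * (2.0 * np.sqrt(np.maximum(x, 0.0) * r) - r)


def simulate_deaths(
    fields: dict[str, GridField],
    persons: pd.DataFrame,
    truth: SimulationTruth,
    n_strata: int,
    seed: int,
    params: FieldParams,
    *,
    return_diagnostics: bool = False,
):
    """Draw case days from the exact conditional-logit law.

    Returns a case table (one row per death: id, date, lat, lon, subgroup
    attributes) and an info dict with resampling counts; with
    ``return_diagnostics`` the per-candidate linear predictor and stratum
    index are included for generative-inferential match checks.
    """
    rng = np.random.default_rng(seed)
    months = _study_months(params)
    causal = list(truth.causal)
    met_lag = LagSpec.moving_average(0, 4)
    main_lag = LagSpec.moving_average(0, 1)

    need = n_strata
    rows_person: list[np.ndarray] = []
    rows_date: list[np.ndarray] = []
    n_resampled = 0
    results_p, results_d = None, None
    diag: dict = {}
    for round_ in range(25):
        if need == 0:
            break
        p_idx = rng.integers(0, len(persons), need)
        m_idx = rng.integers(0, months.size, need)
        wday = rng.integers(0, 7, need)

        # candidate table, grouped by stratum
        key = m_idx * 7 + wday
        order = np.argsort(key, kind="stable")
        p_idx, m_idx, wday, key = p_idx[order], m_idx[order], wday[order], key[order]
        uniq, first_pos = np.unique(key, return_index=True)
        cand_sets = {
            k: candidate_days(months[k // 7], int(k % 7)) for k in uniq
        }
        counts = np.array([cand_sets[k].size for k in key])
        starts = np.r_[0, np.cumsum(counts)[:-1]]
        seg = np.repeat(np.arange(need), counts)
        cand_dates = np.concatenate([cand_sets[k] for k in key])

        plat = persons["lat"].to_numpy()[p_idx][seg]
        plon = persons["lon"].to_numpy()[p_idx][seg]

        eta = np.zeros(cand_dates.size)
        valid = np.ones(cand_dates.size, dtype=bool)
        for pol in causal:
            x, _ = lagged_points(fields[pol], plat, plon, cand_dates, main_lag)
            x = x / truth.unit_scales[pol]
            beta_s = np.full(need, truth.beta(pol))
            for var, table in truth.modifiers.items():
                lv = persons[var].to_numpy()[p_idx]
                shift = np.array([table.get(l, 0.0) for l in lv])
                beta_s = np.log1p((truth.causal[pol] + shift) / 100.0)
            ok = np.isfinite(x)
            eta += np.where(ok, _pollutant_term(np.where(ok, x, 0.0), beta_s[seg], truth), 0.0)
            valid &= ok
        if truth.gamma_temp != 0.0:
            zt, _ = lagged_points(fields["temperature"], plat, plon, cand_dates, met_lag)
            ok = np.isfinite(zt)
            eta += np.where(ok, truth.gamma_temp * np.where(ok, zt, 0.0), 0.0)
            valid &= ok
        if truth.gamma_rh != 0.0:
            zh, _ = lagged_points(fields["humidity"], plat, plon, cand_dates, met_lag)
            ok = np.isfinite(zh)
            eta += np.where(ok, truth.gamma_rh * np.where(ok, zh, 0.0), 0.0)
            valid &= ok

        score = np.where(valid, eta + rng.gumbel(size=eta.size), -np.inf)
        n_valid = np.add.reduceat(valid.astype(np.int64), starts)
        smax = np.maximum.reduceat(score, starts)
        ok_stratum = n_valid >= 2
        win = score == smax[seg]
        win_rows = np.flatnonzero(win & ok_stratum[seg])
        # first winner per stratum (exact float ties have probability zero)
        _, keep = np.unique(seg[win_rows], return_index=True)
        win_rows = win_rows[keep]
        rows_person.append(p_idx[seg[win_rows]])
        rows_date.append(cand_dates[win_rows])
        if return_diagnostics and round_ == 0:
            diag = {
                "eta": eta,
                "valid": valid,
                "stratum": seg,
                "candidate_dates": cand_dates,
                "person_row": p_idx[seg],
                "case_rows": win_rows,
            }
        n_ok = int(ok_stratum.sum())
        n_resampled += need - n_ok
        need -= n_ok
    if need > 0:
        raise RuntimeError("could not place all strata (too much missingness)")

    person_rows = np.concatenate(rows_person)
    case_dates = np.concatenate(rows_date)
    attrs = persons.iloc[person_rows].reset_index(drop=True)
    cases = pd.DataFrame(
        {
            "id": [f"s{i:07d}" for i in range(n_strata)],
            "date": case_dates.astype(str),
            "lat": attrs["lat"].to_numpy(),
            "lon": attrs["lon"].to_numpy(),
        }
    )
    for var in attrs.columns:
        if var not in ("person", "lat", "lon"):
            cases[var] = attrs[var].to_numpy()
    cases["season"] = derive_season(case_dates)
    cases["year"] = case_dates.astype("datetime64[Y]").astype(int) + 1970
    info = {"n_resampled": n_resampled, **diag}
    return cases, info


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_PM_LOADING = float(np.sqrt(0.9))  # PM1/PM2.5/PM10 pairwise anomaly corr 0.9

# Geometric SDs are set once from an a-priori power target: the
# within-stratum SD of the per-reporting-unit MA 0-1 exposure is ~3 units
# for every causal pollutant, which keeps the Monte Carlo SE of a
# 10-replicate mean recovery below ~0.07 percentage points at 30,000 strata.
_NATIONAL_POLLUTANTS = {
    # name: (median, log-sd, seasonal log-amp, phase, loadings)
    "pm1": (24.68, 0.86, 0.25, 0.0, {"pm": _PM_LOADING}),
    "pm25": (36.36, 0.70, 0.25, 0.0, {"pm": _PM_LOADING}),
    "pm10": (63.32, 0.49, 0.25, 0.0, {"pm": _PM_LOADING}),
    "co": (0.88, 0.50, 0.20, 0.0, {"pm": 0.40}),
    "no2": (26.07, 0.84, 0.20, 0.0, {}),
    "o3": (81.55, 0.45, 0.30, np.pi, {}),
    "so2": (13.54, 1.10, 0.25, 0.0, {}),
}


def national_fields(
    variables: list[str] | None = None,
    *,
    start: str = "2014-12-26",
    end: str = "2016-12-31",
    n_lat: int = 8,
    n_lon: int = 8,
    missing_rate: float = 0.0,
    extra_loadings: dict[str, dict[str, float]] | None = None,
) -> FieldParams:
    """The 'national-preset' preset: pollutant medians matched to a polluted
    national setting (PM2.5 ~36, SO2 ~13.5 ug/m3), winter-peaking pollutant
    seasons, summer-peaking ozone and temperature, strongly coupled PM
    series, and strong day-to-day variability so per-10-unit effects are
    estimable at 30,000 strata.

    ``variables`` restricts generation (temperature/humidity are always
    included); ``extra_loadings`` merges additional factor loadings per
    variable (e.g. to couple a gas with a PM series in dedicated scenarios).
    """
    wanted = variables or list(_NATIONAL_POLLUTANTS)
    extra = extra_loadings or {}
    pollutant_units = {"co": "mg/m3"}
    var_list = []
    for name in wanted:
        med, lsd, amp, phase, load = _NATIONAL_POLLUTANTS[name]
        load = {**load, **extra.get(name, {})}
        var_list.append(
            VariableParams(
                name=name,
                dist="lognormal",
                level=med,
                sd=lsd,
                seasonal_amp=amp,
                seasonal_phase=phase,
                ar=0.3,
                loadings=load,
                missing_rate=missing_rate,
                units=pollutant_units.get(name, "ug/m3"),
            )
        )
    var_list.append(
        VariableParams(
            name="temperature",
            dist="gaussian",
            level=16.25,
            sd=4.0,
            seasonal_amp=11.0,
            seasonal_phase=np.pi,
            ar=0.8,
            loadings=extra.get("temperature", {}),
            units="degC",
        )
    )
    var_list.append(
        VariableParams(
            name="humidity",
            dist="gaussian",
            level=72.8,
            sd=8.0,
            seasonal_amp=6.0,
            seasonal_phase=np.pi,
            ar=0.8,
            nonnegative=True,
            loadings=extra.get("humidity", {}),
            units="%",
        )
    )
    return FieldParams(
        lat0=29.0,
        lon0=110.0,
        n_lat=n_lat,
        n_lon=n_lon,
        spacing=0.1,
        start=start,
        end=end,
        variables=tuple(var_list),
        buffer_days=6,
        spatial_range=0.25,
        factor_ar=0.3,
    )


def national_truth(pollutant: str, percent: float, **kwargs) -> SimulationTruth:
    """Truth with one causal pollutant and the preset's mild meteorology
    confounders (log-odds 0.06 per degC and 0.02 per %RH on MA 0-4)."""
    defaults = {"gamma_temp": 0.06, "gamma_rh": 0.02}
    defaults.update(kwargs)
    return SimulationTruth(causal={pollutant: percent}, **defaults)


def confounded_fields(**kwargs) -> FieldParams:
    """Variant with a shared synoptic factor: cold snaps raise PM2.5, so the
    pollutant is correlated with temperature within strata and the
    unadjusted model is biased while the spline-adjusted one is not."""
    params = national_fields(extra_loadings={"temperature": {"synoptic": 0.60}}, **kwargs)
    variables = tuple(
        replace(v, loadings={"synoptic": -0.45}) if v.name == "pm25" else v
        for v in params.variables
    )
    return replace(params, variables=variables)
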