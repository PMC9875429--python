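"""Time-stratified case-crossover referent (control-day) construction.

For each death the case day is the death date and the control days are all
other days in the same calendar year and month that fall on the same day of
week — e.g. a death on Wednesday 2018-05-02 is compared with May 9, 16, 23
and 30, 2018.  Each case therefore has 3 or 4 controls before any
missing-data exclusion, and controls automatically match season, long-term
trend and day of week.  Strata are keyed by the person identifier.

Dates are plain proleptic-Gregorian calendar dates (numpy datetime64[D]);
no time-zone arithmetic is involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "referent_days",
    "build_strata",
    "candidate_days",
    "average_referent_count",
    "drop_incomplete",
    "derive_season",
    "SUBGROUP_VARIABLES",
]

_DAY = np.timedelta64(1, "D")

#: Case-table attribute columns usable for stratified analyses.
SUBGROUP_VARIABLES = (
    "age_band",
    "sex",
    "education",
    "marital",
    "occupation",
    "subtype",
    "region",
    "season",
    "year",
)


def _month_start(days: np.ndarray) -> np.ndarray:
    return days.astype("datetime64[M]").astype("datetime64[D]")


def _weekday(days: np.ndarray) -> np.ndarray:
    # Days since Monday 1969-12-29, mod 7: 0 = Monday ... 6 = Sunday.
    days = np.asarray(days, dtype="datetime64[D]")
    return ((days - np.datetime64("1969-12-29", "D")) / _DAY).astype(np.int64) % 7


def candidate_days(month: np.datetime64, weekday: int) -> np.ndarray:
    """All days of ``month`` (a datetime64[M]-like) with the given ISO weekday-1.

    ``weekday`` uses 0 = Monday ... 6 = Sunday.  The returned array has 4 or
    5 entries; it is the case day plus its referents.
    """
    start = np.datetime64(month, "M").astype("datetime64[D]")
    n_days = int(((np.datetime64(month, "M") + 1).astype("datetime64[D]") - start) / _DAY)
    first = (weekday - int(_weekday(np.array([start]))[0])) % 7
    offsets = np.arange(first, n_days, 7)
    return start + offsets * _DAY


def referent_days(case_date) -> np.ndarray:
    """Control days for one case day: same year-month, same day of week.

    Excludes the case day itself; the result has 3 or 4 dates, in ascending
    order.
    """
    d = np.datetime64(case_date, "D")
    wd = int(_weekday(np.array([d]))[0])
    cands = candidate_days(d.astype("datetime64[M]"), wd)
    return cands[cands != d]


def build_strata(cases: pd.DataFrame) -> pd.DataFrame:
    """Expand a case table into the long stratum table of observation days.

    ``cases`` must have columns ``id`` (unique per case — the stratum key)
    and ``date``.  The result has one row per observation day with columns
    (stratum_id, date, is_case), ordered by (stratum_id, date).
    """
    if cases.empty:
        raise ValueError("case table is empty")
    ids = cases["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate person ids: ids are the stratum key")
    case_days = pd.to_datetime(cases["date"]).to_numpy().astype("datetime64[D]")
    months = case_days.astype("datetime64[M]")
    wds = _weekday(case_days)

    # Expand per unique (month, weekday) pattern: every case in a pattern
    # shares the same candidate-day set.
    pat = pd.DataFrame({"month": months, "wd": wds})
    out_frames = []
    for (month, wd), grp in pat.groupby(["month", "wd"], sort=False):
        cands = candidate_days(np.datetime64(month, "M"), int(wd))
        sel = grp.index.to_numpy()
        n_c, n_s = cands.size, sel.size
        frame = pd.DataFrame(
            {
                "stratum_id": np.repeat(ids[sel], n_c),
                "date": np.tile(cands, n_s),
                "is_case": (np.tile(cands, n_s) == np.repeat(case_days[sel], n_c)).astype(np.int8),
            }
        )
        out_frames.append(frame)
    out = pd.concat(out_frames, ignore_index=True)
    out = out.sort_values(["stratum_id", "date"], kind="mergesort").reset_index(drop=True)
    return out


def average_referent_count(strata: pd.DataFrame) -> float:
    """Mean number of control days per case (total controls / strata)."""
    n_strata = strata["stratum_id"].nunique()
    if n_strata == 0:
        raise ValueError("no strata")
    n_controls = int((strata["is_case"] == 0).sum())
    return n_controls / n_strata


def drop_incomplete(strata: pd.DataFrame, required: list[str]):
    """Remove observation days with missing required covariates.

    Missing data are never imputed.  A stratum whose *case* day is removed
    is dropped whole (its conditional likelihood is undefined); a stratum
    left with zero controls is dropped as uninformative.  Returns
    (clean table, exclusion log).  The log assigns every removed observation
    day to exactly one category: the first required column found missing on
    that row, plus the stratum-level removals.
    """
    miss = strata[required].isna()
    any_miss = miss.any(axis=1).to_numpy()
    first_reason = np.full(len(strata), "", dtype=object)
    remaining = any_miss.copy()
    for col in required:
        hit = remaining & miss[col].to_numpy()
        first_reason[hit] = col
        remaining &= ~hit

    log: dict[str, int] = {f"rows_missing_{c}": int((first_reason == c).sum()) for c in required}
    kept = strata.loc[~any_miss]

    by = kept.groupby("stratum_id", sort=False)["is_case"]
    has_case = by.transform("max") == 1
    has_control = by.transform("count") - by.transform("sum") >= 1
    n_strata_before = strata["stratum_id"].nunique()
    keep_mask = has_case & has_control
    clean = kept.loc[keep_mask].reset_index(drop=True)
    n_after = clean["stratum_id"].nunique()
    lost_case = kept.loc[~has_case, "stratum_id"].nunique()
    log["strata_dropped_case_missing"] = int(lost_case)
    log["strata_dropped_no_controls"] = int(n_strata_before - n_after - lost_case)
    log["strata_kept"] = int(n_after)
    log["rows_dropped_with_stratum"] = int((~keep_mask).sum())
    return clean, log


def derive_season(dates) -> np.ndarray:
    """Warm season = May through October; cold = November through April."""
    months = pd.to_datetime(np.asarray(dates)).month
    return np.where((months >= 5) & (months <= 10), "warm", "cold")
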