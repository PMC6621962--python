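"""Fix cleaning, den delineation, step construction and diel/season labels.

The cleaning rule mirrors the standard collar-quality screen: unresolved
fixes are discarded; weakly resolved fixes (QFP-uncertain or 2D) are
discarded when PDOP exceeds 5; strongly resolved fixes (QFP-certain or
3D) when PDOP exceeds 20.  Denning is delineated automatically from a
rolling daily net-displacement criterion, replacing visual inspection.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .calendars import DEFAULT_CALENDAR, SeasonCalendar

log = logging.getLogger(__name__)

_WEAK = ("qfp_uncertain", "two_d")
_STRONG = ("qfp_certain", "three_d")


def filter_fixes(fixes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the PDOP/fix-class quality screen.

    Returns (retained fixes, removal report).  The report has one row
    per bear (bear_id, n_fixes, n_removed, fraction_removed) plus a
    pooled ``all`` row, since a mean loss can be quoted per bear or
    pooled.  Resolved fixes with missing PDOP are removed and counted.
    """
    cls = fixes["fix_class"].astype(str)
    pdop = pd.to_numeric(fixes["pdop"], errors="coerce")
    missing = pdop.isna() & (cls != "unresolved")
    if missing.any():
        log.warning("%d resolved fixes with missing PDOP removed", int(missing.sum()))
    remove = (
        (cls == "unresolved")
        | (cls.isin(_WEAK) & (pdop > 5))
        | (cls.isin(_STRONG) & (pdop > 20))
        | missing
    )
    kept = fixes.loc[~remove].reset_index(drop=True)

    rows = []
    for bear, grp in fixes.groupby("bear_id", sort=True):
        n_rem = int(remove.loc[grp.index].sum())
        rows.append({"bear_id": bear, "n_fixes": len(grp), "n_removed": n_rem,
                     "fraction_removed": n_rem / len(grp) if len(grp) else 0.0})
    rows.append({"bear_id": "all", "n_fixes": len(fixes), "n_removed": int(remove.sum()),
                 "fraction_removed": float(remove.mean()) if len(fixes) else 0.0})
    return kept, pd.DataFrame(rows)


def detect_den_period(
    track: pd.DataFrame,
    threshold_m: float = 100.0,
    min_days: int = 30,
    search_months: tuple[int, ...] = (10, 11, 12, 1, 2, 3, 4, 5),
    timezone: str = "America/New_York",
) -> tuple[dt.date, dt.date] | None:
    """Delineate a den period from rolling daily net displacement.

    Computes the displacement between consecutive daily mean positions
    and finds the longest run of days below `threshold_m` whose dates
    fall in the den search window (October-May by default).  Runs
    shorter than `min_days` are ignored.  Returns (den_entry,
    den_emergence) dates — emergence is the first day movement resumes —
    or None for a bear that never dens.
    """
    t = track.copy()
    t["date"] = pd.to_datetime(t["timestamp"], utc=True).dt.tz_convert(timezone).dt.date
    if t["date"].nunique() < 60:
        raise ValueError("den detection needs at least 60 days of data")
    daily = t.groupby("date")[["x", "y"]].mean()
    disp = np.hypot(daily["x"].diff(), daily["y"].diff())
    stationary = (disp < threshold_m) & pd.Series(
        [d.month in search_months for d in daily.index], index=daily.index
    )

    best_start = best_len = None
    run_start = run_len = 0
    vals = stationary.to_numpy()
    for i, flag in enumerate(np.append(vals, False)):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
        else:
            if run_len >= min_days and (best_len is None or run_len > best_len):
                best_start, best_len = run_start, run_len
            run_len = 0
    if best_start is None:
        warnings.warn("no qualifying stationary run; bear treated as non-denning")
        return None
    dates = list(daily.index)
    entry = dates[max(best_start - 1, 0)]  # displacement at i compares day i to i-1
    emergence = dates[min(best_start + best_len, len(dates) - 1)]
    if best_len >= len(dates) - 2:
        warnings.warn("track is stationary over the whole search window")
    return entry, emergence


def exclude_den_fixes(
    fixes: pd.DataFrame, den_dates: dict[str, tuple[dt.date, dt.date] | None], timezone: str = "America/New_York"
) -> pd.DataFrame:
    """Drop fixes between each bear's den entry and emergence."""
    local_date = pd.to_datetime(fixes["timestamp"], utc=True).dt.tz_convert(timezone).dt.date
    keep = np.ones(len(fixes), bool)
    for bear, dates in den_dates.items():
        if dates is None:
            continue
        entry, emergence = dates
        m = (fixes["bear_id"] == bear).to_numpy()
        in_den = np.array([entry <= d < emergence for d in local_date])
        keep &= ~(m & in_den)
    return fixes.loc[keep].reset_index(drop=True)


def build_steps(fixes: pd.DataFrame, nominal_interval: int = 45, tolerance: float = 2.0) -> pd.DataFrame:
    """Build movement steps from consecutive fixes.

    A step joins two successive fixes whose time difference is within
    `tolerance` minutes of `nominal_interval`; gaps break the sequence
    and no step spans them.  Turning angle is the signed change in
    heading between successive steps, defined only when the previous
    step ends where this one starts.
    """
    out = []
    for bear, grp in fixes.groupby("bear_id", sort=True):
        if len(grp) < 3:
            continue
        g = grp.sort_values("timestamp").reset_index(drop=True)
        ts = pd.to_datetime(g["timestamp"], utc=True)
        dt_min = ts.diff().dt.total_seconds().to_numpy() / 60.0
        dx = g["x"].diff().to_numpy()
        dy = g["y"].diff().to_numpy()
        ok = np.abs(dt_min - nominal_interval) <= tolerance
        heading = np.arctan2(dy, dx)
        prev_ok = np.roll(ok, 1)
        prev_ok[0] = False
        turn = heading - np.roll(heading, 1)
        turn = (turn + np.pi) % (2 * np.pi) - np.pi
        turn = np.where(turn == -np.pi, np.pi, turn)  # angles in (-pi, pi]
        for i in np.flatnonzero(ok):
            rec = {
                "bear_id": bear,
                "start_time": ts.iloc[i - 1],
                "end_time": ts.iloc[i],
                "x0": g["x"].iloc[i - 1],
                "y0": g["y"].iloc[i - 1],
                "x1": g["x"].iloc[i],
                "y1": g["y"].iloc[i],
                "length": float(np.hypot(dx[i], dy[i])),
                "heading": float(heading[i]),
                "turning_angle": float(turn[i]) if prev_ok[i] else np.nan,
                "duration": float(dt_min[i]),
            }
            if "true_state" in g.columns:
                rec["true_state"] = g["true_state"].iloc[i]
            out.append(rec)
    cols = ["bear_id", "start_time", "end_time", "x0", "y0", "x1", "y1",
            "length", "heading", "turning_angle", "duration"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out)


def assign_diel(
    steps: pd.DataFrame, latitude: float = 42.38, longitude: float = -72.52, timezone: str = "America/New_York"
) -> pd.DataFrame:
    """Label each step day/night by its start time vs local sunrise/sunset.

    Day is the half-open interval [sunrise, sunset).  Sunrise/sunset are
    computed per local calendar date from standard solar geometry.
    """
    if not -66.0 < latitude < 66.0:
        raise ValueError("latitudes with polar day/night are unsupported")
    out = steps.copy()
    local = pd.to_datetime(out["start_time"], utc=True).dt.tz_convert(timezone)
    events: dict[dt.date, tuple[dt.datetime, dt.datetime]] = {}
    labels = []
    for when in local:
        d = when.date()
        if d not in events:
            events[d] = solar.sunrise_sunset(d, latitude, longitude, timezone)
        rise, sset = events[d]
        labels.append("day" if rise <= when < sset else "night")
    out["diel"] = labels
    return out


def assign_season(
    steps: pd.DataFrame,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
    den_dates: dict[str, tuple[dt.date, dt.date] | None] | None = None,
    timezone: str = "America/New_York",
) -> pd.DataFrame:
    """Label steps with their ecological season.

    Steps inside a bear's den period (per `den_dates`) are excluded and
    counted in the ``n_excluded_denning`` attribute of the result.
    """
    out = steps.copy()
    local_date = pd.to_datetime(out["start_time"], utc=True).dt.tz_convert(timezone).dt.date
    out["season"] = [calendar.season_of(d) for d in local_date]
    n_excluded = 0
    if den_dates:
        keep = np.ones(len(out), bool)
        for bear, dates in den_dates.items():
            if dates is None:
                continue
            entry, emergence = dates
            m = (out["bear_id"] == bear).to_numpy()
            in_den = np.array([entry <= d < emergence for d in local_date])
            keep &= ~(m & in_den)
        n_excluded = int((~keep).sum())
        out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_excluded_denning"] = n_excluded
    return out
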