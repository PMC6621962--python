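"""Ecologically based seasons from movement and habitat time series.

Daily movement (speed, turning angle) and habitat-use series (point
indicators for the main cover classes and percent impervious) are
smoothed with a 5-day moving window, range-standardized to [0, 1] per
bear-year, clustered with k-means, and the number of clusters chosen by
the gap statistic.  Cluster labels over calendar time are pooled across
bear-years into one season calendar by modal label per day of year, with
a 7-day majority smoothing.
"""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .calendars import SeasonCalendar
from .landscape import LandscapeStack

HABITAT_VARS = ("coniferous_forest", "deciduous_forest", "forested_wetland", "agriculture")


def point_covariates(steps: pd.DataFrame, land: LandscapeStack) -> pd.DataFrame:
    """Step table with habitat values sampled at each step's end fix."""
    out = steps.copy()
    ok = land.in_bounds(out["x1"].to_numpy(), out["y1"].to_numpy())
    out = out.loc[ok].reset_index(drop=True)
    for var in list(HABITAT_VARS) + ["percent_impervious"]:
        if var in land.layers:
            out[var] = land.value_at(var, out["x1"].to_numpy(), out["y1"].to_numpy())
    return out


def build_season_features(
    steps_with_cov: pd.DataFrame,
    window_days: int = 5,
    timezone: str = "America/New_York",
) -> pd.DataFrame:
    """Smoothed, range-standardized daily feature series per bear-year.

    Features: speed (m/min), |turning angle|, daily mean of each habitat
    indicator and of percent impervious at step endpoints.  Smoothing is
    a centered `window_days` moving mean over days; standardization maps
    each feature's range to [0, 1] within a bear-year (zero-range
    features are flagged and set to 0).
    """
    t = steps_with_cov.copy()
    local = pd.to_datetime(t["start_time"], utc=True).dt.tz_convert(timezone)
    t["date"] = local.dt.date
    t["bear_year"] = t["bear_id"].astype(str) + "-" + local.dt.year.astype(str)
    t["speed"] = t["length"] / t["duration"]
    t["abs_turn"] = np.abs(t["turning_angle"])
    feat_cols = ["speed", "abs_turn"] + [v for v in list(HABITAT_VARS) + ["percent_impervious"] if v in t]

    frames = []
    for by, grp in t.groupby("bear_year", sort=True):
        daily = grp.groupby("date")[feat_cols].mean()
        if len(daily) < window_days:
            raise ValueError(f"bear-year {by} shorter than the smoothing window")
        sm = daily.rolling(window_days, center=True, min_periods=1).mean()
        for col in feat_cols:
            lo, hi = sm[col].min(), sm[col].max()
            if hi - lo <= 0 or not np.isfinite(hi - lo):
                warnings.warn(f"feature {col} has zero range in {by}; set to 0")
                sm[col] = 0.0
            else:
                sm[col] = (sm[col] - lo) / (hi - lo)
        sm = sm.reset_index()
        sm["bear_year"] = by
        frames.append(sm)
    return pd.concat(frames, ignore_index=True)


def _within_dispersion(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def choose_k_gap(
    X: np.ndarray,
    k_max: int = 6,
    B: int = 20,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of k-means clusters with the gap statistic.

    gap(k) = mean_B log(W_k^ref) - log(W_k), with reference data uniform
    over each feature's observed range; the chosen k is the smallest
    with gap(k) >= gap(k+1) - s_{k+1} (one-standard-error rule).
    Returns (k, per-k table with gap and s values).
    """
    X = np.asarray(X, float)
    if len(X) < 50:
        raise ValueError("need at least 50 observations for the gap statistic")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def dispersion(data, k, rs):
        if k == 1:
            return float(((data - data.mean(axis=0)) ** 2).sum())
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(data)
        return _within_dispersion(data, km.labels_, km.cluster_centers_)

    ks = list(range(1, k_max + 1))
    log_w = [np.log(dispersion(X, k, int(rng.integers(2**31)))) for k in ks]
    ref_log_w = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for i, k in enumerate(ks):
            ref_log_w[b, i] = np.log(dispersion(ref, k, int(rng.integers(2**31))))
    gap = ref_log_w.mean(axis=0) - np.asarray(log_w)
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = ks[i]
            break
    table = pd.DataFrame({"k": ks, "gap": gap, "s": s, "log_w": log_w})
    return chosen, table


def cluster_days(features: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """k-means labels for the pooled daily feature table."""
    feat_cols = [c for c in features.columns if c not in ("date", "bear_year")]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(features[feat_cols].to_numpy())
    out = features[["bear_year", "date"]].copy()
    out["cluster"] = km.labels_
    return out


def derive_season_dates(
    labeled_days: pd.DataFrame,
    season_names: tuple[str, ...] = ("spring", "summer", "fall"),
    majority_window: int = 7,
) -> SeasonCalendar:
    """Pool per-bear-year cluster labels into one season calendar.

    The modal cluster per calendar day (across bear-years) is smoothed
    with a `majority_window`-day modal filter; contiguous runs become
    seasons, named in calendar order.  Non-contiguous remnants raise a
    warning and only the longest run per cluster is kept.
    """
    t = labeled_days.copy()
    t["doy"] = [d.timetuple().tm_yday for d in t["date"]]
    modal = t.groupby("doy")["cluster"].agg(lambda s: s.mode().iloc[0]).sort_index()
    doys = modal.index.to_numpy()
    labels = modal.to_numpy()
    half = majority_window // 2
    smoothed = np.array(
        [stats.mode(labels[max(0, i - half): i + half + 1], keepdims=False).mode for i in range(len(labels))]
    )

    # contiguous runs
    runs = []  # (label, start_doy, length)
    start = 0
    for i in range(1, len(smoothed) + 1):
        if i == len(smoothed) or smoothed[i] != smoothed[start]:
            runs.append((smoothed[start], doys[start], i - start))
            start = i
    if len({r[0] for r in runs}) < len(runs):
        warnings.warn("non-contiguous modal labels; keeping the longest run per cluster")
        best = {}
        for lab, s, ln in runs:
            if lab not in best or ln > best[lab][2]:
                best[lab] = (lab, s, ln)
        runs = sorted(best.values(), key=lambda r: r[1])
    if len(runs) == 1:
        warnings.warn("labels constant over the year; single season")
    starts = []
    for i, (lab, s, ln) in enumerate(runs[: len(season_names)]):
        d = dt.date(2001, 1, 1) + dt.timedelta(days=int(s) - 1)
        starts.append((season_names[i] if i < len(season_names) else f"season{i}", (d.month, d.day)))
    # first season starts at Jan 1 by convention (denning truncates it anyway)
    starts[0] = (starts[0][0], (1, 1))
    return SeasonCalendar(starts=tuple(starts))
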