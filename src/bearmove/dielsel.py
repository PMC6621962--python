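"""Diel movement summaries and third-order selection ratios.

Step lengths are summarized per 45-minute bin of the local day with a
bear-level bootstrap.  Habitat selection per bin is the mean fraction of
the step path inside a category divided by that category's proportion in
the bear's seasonal 95% kernel-density home range — Johnson's
within-home-range (third-order) selection ratio — again bootstrapped
across bears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import LandscapeStack

N_BINS = 32  # 45-min bins covering 24 h

#: category groups combined before ratio computation (unions of layers)
DEFAULT_GROUPS = {
    "forest": ("deciduous_forest", "coniferous_forest", "mixed_forest"),
    "wetland": ("forested_wetland",),
    "agriculture": ("agriculture",),
    "roads": ("roads",),
    "residential": ("low_density_residential",),
}


@dataclass
class HomeRange:
    """Seasonal kernel-density home range on the landscape grid."""

    bear_id: str
    season: str
    density: np.ndarray  # sums to 1 over the grid
    isopleth_mask: np.ndarray  # smallest level set holding >= the isopleth mass
    centroid: tuple[float, float]
    availability: dict[str, float]  # categorical layer -> proportion inside isopleth
    housing_density: float  # houses/km^2 inside the isopleth
    isopleth: float = 0.95


def estimate_kde_home_range(
    fixes: pd.DataFrame,
    land: LandscapeStack,
    bear_id: str = "",
    season: str = "all",
    isopleth: float = 0.95,
    categories: dict[str, tuple[str, ...]] | None = None,
) -> HomeRange:
    """Bivariate Gaussian KDE home range with normal-scale bandwidth.

    The KDE is a binned estimate: fix counts on the landscape grid
    smoothed with an axis-wise Gaussian whose SD is the reference-rule
    bandwidth h_i = sd_i * n^(-1/6).  The isopleth is the smallest-area
    level set containing at least the requested mass; availability is
    the mean of each (possibly grouped) categorical layer inside it.
    """
    if len(fixes) < 30:
        raise ValueError("need at least 30 fixes for a home range")
    x = fixes["x"].to_numpy() if "x" in fixes else fixes["x1"].to_numpy()
    y = fixes["y"].to_numpy() if "y" in fixes else fixes["y1"].to_numpy()
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("all fixes identical; bandwidth degenerate")
    n = len(x)
    hx = x.std(ddof=1) * n ** (-1 / 6)
    hy = y.std(ddof=1) * n ** (-1 / 6)
    if hx == 0 or hy == 0:
        hx = hy = max(hx, hy, land.res / 2)

    nr, nc = land.shape
    counts = np.zeros((nr, nc))
    ok = land.in_bounds(x, y)
    r, c = land.xy_to_rc(x[ok], y[ok])
    np.add.at(counts, (r, c), 1.0)
    dens = ndimage.gaussian_filter(counts, sigma=(hy / land.res, hx / land.res), mode="constant")
    total = dens.sum()
    if total <= 0:
        raise ValueError("no fixes inside the landscape")
    dens /= total

    flat = dens.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, isopleth)) + 1
    mask = np.zeros(flat.size, bool)
    mask[order[:k]] = True
    mask = mask.reshape(dens.shape)

    gx, gy = land.cell_centers()
    centroid = (float((gx * dens).sum()), float((gy * dens).sum()))

    categories = categories if categories is not None else {
        name: members for name, members in DEFAULT_GROUPS.items()
        if all(m in land.layers for m in members)
    }
    availability = {}
    for name, members in categories.items():
        union = np.zeros(land.shape)
        for m in members:
            union = np.maximum(union, land.layers[m])
        availability[name] = float(union[mask].mean())
    hd = float(land.layers["housing_density"][mask].mean()) if "housing_density" in land.layers else float("nan")
    return HomeRange(
        bear_id=bear_id,
        season=season,
        density=dens,
        isopleth_mask=mask,
        centroid=centroid,
        availability=availability,
        housing_density=hd,
        isopleth=isopleth,
    )


def _diel_bin(times: pd.Series, timezone: str) -> np.ndarray:
    local = pd.to_datetime(times, utc=True).dt.tz_convert(timezone)
    minutes = local.dt.hour * 60 + local.dt.minute
    return (minutes // 45).to_numpy()


def bootstrap_step_lengths(
    steps: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    timezone: str = "America/New_York",
) -> pd.DataFrame:
    """Bear-level bootstrap of mean step length per 45-min bin and season.

    Within each (season, bin) the unit of resampling is the bear: bear
    mean step lengths are resampled with replacement `n_boot` times; the
    point estimate is the mean of bear means and the CI the 2.5/97.5
    bootstrap percentiles.  Bins with fewer than two bears carry NaN CIs
    and ci_flagged=True.
    """
    t = steps.copy()
    t["bin"] = _diel_bin(t["start_time"], timezone)
    if "season" not in t:
        t["season"] = "all"
    rng = np.random.default_rng(seed)
    rows = []
    for (season, b), grp in t.groupby(["season", "bin"], sort=True):
        bear_means = grp.groupby("bear_id")["length"].mean().to_numpy()
        m = float(bear_means.mean())
        if len(bear_means) >= 2:
            idx = rng.integers(0, len(bear_means), size=(n_boot, len(bear_means)))
            boot = bear_means[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            boot_mean = float(boot.mean())
            flagged = False
        else:
            lo = hi = boot_mean = float("nan")
            flagged = True
        rows.append({"season": season, "bin": int(b), "bin_start_hhmm": f"{b * 45 // 60:02d}{b * 45 % 60:02d}",
                     "mean_length": m, "boot_mean": boot_mean, "ci_low": float(lo), "ci_high": float(hi),
                     "n_bears": len(bear_means), "ci_flagged": flagged})
    return pd.DataFrame(rows)


def step_category_fraction(
    steps: pd.DataFrame, land: LandscapeStack, members: tuple[str, ...], sample_every: float = 10.0
) -> np.ndarray:
    """Fraction of each step path inside the union of `members` layers.

    The segment is sampled every `sample_every` meters (endpoints
    included) and the layer union averaged over in-bounds samples.
    """
    union = np.zeros(land.shape)
    for m in members:
        union = np.maximum(union, land.layers[m])
    out = np.empty(len(steps))
    x0 = steps["x0"].to_numpy(); y0 = steps["y0"].to_numpy()
    x1 = steps["x1"].to_numpy(); y1 = steps["y1"].to_numpy()
    for i in range(len(steps)):
        length = float(np.hypot(x1[i] - x0[i], y1[i] - y0[i]))
        n = max(int(np.ceil(length / sample_every)) + 1, 2)
        ts = np.linspace(0.0, 1.0, n)
        px = x0[i] + ts * (x1[i] - x0[i])
        py = y0[i] + ts * (y1[i] - y0[i])
        ok = land.in_bounds(px, py)
        if not ok.any():
            out[i] = np.nan
            continue
        r, c = land.xy_to_rc(px[ok], py[ok])
        out[i] = union[r, c].mean()
    return out


def selection_ratio_by_bin(
    steps: pd.DataFrame,
    home_ranges: dict[tuple[str, str], HomeRange],
    land: LandscapeStack,
    categories: dict[str, tuple[str, ...]] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    timezone: str = "America/New_York",
) -> pd.DataFrame:
    """Third-order selection ratios per 45-min bin with bear bootstrap.

    Per bear and bin: (mean fraction of the step path in the category) /
    (category proportion in that bear's seasonal home range).  Bears
    with zero availability for a category are excluded with a warning.
    `home_ranges` is keyed by (bear_id, season).
    """
    categories = categories if categories is not None else {
        name: members for name, members in DEFAULT_GROUPS.items()
        if all(m in land.layers for m in members)
    }
    t = steps.copy()
    t["bin"] = _diel_bin(t["start_time"], timezone)
    if "season" not in t:
        t["season"] = "all"
    for name, members in categories.items():
        t[f"frac_{name}"] = step_category_fraction(t, land, members)

    rng = np.random.default_rng(seed)
    rows = []
    for (season, b), grp in t.groupby(["season", "bin"], sort=True):
        for name in categories:
            ratios = []
            for bear, bg in grp.groupby("bear_id"):
                hr = home_ranges.get((bear, season)) or home_ranges.get((bear, "all"))
                if hr is None:
                    continue
                avail = hr.availability.get(name, np.nan)
                if not np.isfinite(avail) or avail <= 0:
                    warnings.warn(f"zero availability of {name} for {bear}/{season}; excluded")
                    continue
                used = np.nanmean(bg[f"frac_{name}"].to_numpy())
                ratios.append(used / avail)
            if not ratios:
                continue
            ratios = np.asarray(ratios)
            m = float(ratios.mean())
            if len(ratios) >= 2:
                idx = rng.integers(0, len(ratios), size=(n_boot, len(ratios)))
                boot = ratios[idx].mean(axis=1)
                lo, hi = np.percentile(boot, [2.5, 97.5])
                flagged = False
            else:
                lo = hi = float("nan")
                flagged = True
            rows.append({"season": season, "bin": int(b),
                         "bin_start_hhmm": f"{b * 45 // 60:02d}{b * 45 % 60:02d}",
                         "category": name, "mean_ratio": m, "ci_low": float(lo),
                         "ci_high": float(hi), "n_bears": len(ratios), "ci_flagged": flagged})
    return pd.DataFrame(rows)
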