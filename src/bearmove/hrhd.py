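"""Home-range housing density (HRHD) and the acclimation meta-model.

Across bears, the standardized step-selection coefficient for percent
impervious surface is modeled as a function of the housing density
inside each bear's 95% home range.  Three candidate shapes are compared
by AICc under Gaussian error: a four-parameter logistic

    beta(x) = L0 + (L1 - L0) / (1 + exp(-s (x - x0))),

a straight line, and an intercept-only model.  A winning logistic (or
linear) with positive slope between its asymptotes is read as bears with
more housing showing weaker avoidance of impervious surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dielsel import HomeRange
from .landscape import LandscapeStack
from .ssf import aicc


def housing_density_in_home_range(hr: HomeRange, land: LandscapeStack) -> float:
    """Houses per km^2 inside the 95% isopleth.

    The housing raster stores a density (houses/km^2), so total houses =
    sum(density * cell area); dividing by isopleth area returns the mean
    density over the isopleth.
    """
    mask = hr.isopleth_mask
    if not mask.any():
        raise ValueError("isopleth has zero area")
    cell_km2 = (land.res / 1000.0) ** 2
    houses = float(land.layers["housing_density"][mask].sum() * cell_km2)
    area = float(mask.sum() * cell_km2)
    return houses / area


def _logistic(x, L0, L1, x0, s):
    return L0 + (L1 - L0) / (1.0 + np.exp(-s * (x - x0)))


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    rss = float((resid**2).sum())
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


@dataclass
class CoefCurveFit:
    """AICc comparison of logistic / linear / intercept-only curves."""

    table: pd.DataFrame  # per-bear rows: bear_id, hrhd, beta_impervious
    params: dict[str, dict[str, float]]
    aicc: dict[str, float]
    best: str

    @property
    def inflection(self) -> float | None:
        p = self.params.get("logistic")
        return p["x0"] if p else None


def fit_coefficient_curves(rows: pd.DataFrame, min_bears: int = 8, n_starts: int = 5, seed: int = 0) -> CoefCurveFit:
    """Fit and rank the three HRHD curves.

    `rows` needs columns hrhd (houses/km^2) and beta_impervious (the
    standardized SSF coefficient).  Each model's AICc uses k = number of
    curve parameters + 1 for the error variance.  Logistic fitting uses
    quantile-based start values with `n_starts` perturbations; if no
    start converges the logistic is excluded with a warning.
    """
    t = rows.dropna(subset=["hrhd", "beta_impervious"]).reset_index(drop=True)
    if len(t) < min_bears:
        raise ValueError(f"need at least {min_bears} bears with an impervious coefficient")
    x = t["hrhd"].to_numpy(float)
    y = t["beta_impervious"].to_numpy(float)
    n = len(t)
    params: dict[str, dict[str, float]] = {}
    crit: dict[str, float] = {}

    # intercept only
    c = float(y.mean())
    params["intercept"] = {"c": c}
    crit["intercept"] = aicc(_gaussian_loglik(y - c), 2, n)

    # linear
    b, a = np.polyfit(x, y, 1)
    params["linear"] = {"a": float(a), "b": float(b)}
    crit["linear"] = aicc(_gaussian_loglik(y - (a + b * x)), 3, n)

    # 4-parameter logistic, multi-start least squares
    rng = np.random.default_rng(seed)
    xr = np.ptp(x) if np.ptp(x) > 0 else 1.0
    base = np.array([np.quantile(y, 0.1), np.quantile(y, 0.9), float(np.median(x)), 4.0 / xr])
    best_fit = None
    for i in range(n_starts):
        p0 = base if i == 0 else base * rng.uniform(0.7, 1.3, 4) + np.array([0, 0, 0.1 * xr, 0]) * rng.normal()
        try:
            res = optimize.least_squares(
                lambda p: _logistic(x, *p) - y, p0,
                bounds=([-np.inf, -np.inf, x.min() - xr, 0.0], [np.inf, np.inf, x.max() + xr, np.inf]),
                max_nfev=2000,
            )
        except ValueError:
            continue
        if res.success and (best_fit is None or res.cost < best_fit.cost):
            best_fit = res
    if best_fit is not None and n - 6 > 0:
        L0, L1, x0, s = best_fit.x
        params["logistic"] = {"L0": float(L0), "L1": float(L1), "x0": float(x0), "s": float(s)}
        crit["logistic"] = aicc(_gaussian_loglik(_logistic(x, *best_fit.x) - y), 5, n)
    else:
        warnings.warn("logistic curve did not converge; excluded from ranking")

    best = min(crit, key=crit.get)
    return CoefCurveFit(table=t, params=params, aicc=crit, best=best)


def hrhd_table(
    models: list, home_ranges: dict[tuple[str, str], HomeRange], land: LandscapeStack, season: str = "all"
) -> pd.DataFrame:
    """Per-bear HRHD vs impervious-coefficient table from fitted SSFs."""
    rows = []
    for m in models:
        if m is None or m.season != season or "percent_impervious" not in m.betas:
            continue
        hr = home_ranges.get((m.bear_id, season)) or home_ranges.get((m.bear_id, "all"))
        if hr is None:
            continue
        rows.append({
            "bear_id": m.bear_id,
            "hrhd": housing_density_in_home_range(hr, land),
            "beta_impervious": m.betas["percent_impervious"],
        })
    return pd.DataFrame(rows)
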