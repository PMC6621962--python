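"""Predictive movement surfaces, spatial combination and validation.

Each bear's fitted SSF is projected over the landscape as the
exponentiated linear predictor w(x) = exp(sum(beta_v * z_v(x))), where
each covariate raster is first smoothed with a Gaussian of SD equal to
its characteristic scale and standardized with the fit-time constants.
Per-bear surfaces are combined into one population surface by
inverse-distance-from-home-range-centroid weights normalized per pixel.
Validation uses the Boyce index: the Spearman rank correlation between
habitat-suitability class rank and the predicted-to-expected frequency
ratio of hold-out locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeStack
from .ssf import SSFModel, smoothed_layers


@dataclass
class Surface:
    """Relative probability-of-movement raster (exponential scale, >= 0)."""

    values: np.ndarray
    provenance: str  # bear id or "combined"
    season: str = "all"
    diel: str = "all"


@dataclass
class BoyceResult:
    n_bins: int
    bin_rank: np.ndarray  # ranks of the non-empty classes
    f_ratio: np.ndarray  # predicted-to-expected ratio per class
    spearman: float


def predict_bear_surface(model: SSFModel, land: LandscapeStack, smooth_at_scale: bool = False) -> Surface:
    """Project one bear's SSF across the landscape.

    Each covariate raster is z-scored with the stored fit-time constants,
    weighted by its coefficient, summed and exponentiated — the classic
    coefficients-times-rasters projection.  With ``smooth_at_scale`` the
    rasters are first smoothed with a Gaussian of SD equal to each
    variable's characteristic scale (mirroring availability extraction);
    on synthetic studies this flattens the surface and sharply degrades
    hold-out calibration, so the raw projection is the default.
    """
    lp = np.zeros(land.shape)
    for var in model.variables:
        if var not in land.layers:
            raise KeyError(f"model variable {var!r} missing from the landscape")
        if var not in model.z_constants:
            raise KeyError(f"missing z-scoring constants for {var!r}")
        sigma = model.scales[var] if smooth_at_scale else 0.0
        sm = smoothed_layers(land, sigma, [var])[var] if sigma > 0 else land.layers[var]
        mean, sd = model.z_constants[var]
        lp += model.betas[var] * (sm - mean) / sd
    return Surface(values=np.exp(lp), provenance=model.bear_id, season=model.season, diel=model.diel)


def rescale_minmax(surface: Surface) -> Surface:
    """Min-max rescale a surface to [0, 1] (display and combination aid).

    The exponential projection can span many orders of magnitude when a
    bear's linear predictor is steep; rescaling each bear to a common
    [0, 1] range before inverse-distance combination keeps one extreme
    individual from dominating the population surface.
    """
    v = surface.values
    rng = v.max() - v.min()
    if rng <= 0:
        raise ValueError("constant surface cannot be rescaled")
    return Surface(values=(v - v.min()) / rng, provenance=surface.provenance,
                   season=surface.season, diel=surface.diel)


def weight_and_combine(
    surfaces: list[Surface],
    centroids: dict[str, tuple[float, float]],
    land: LandscapeStack,
    season: str = "all",
    diel: str = "all",
) -> Surface:
    """Inverse-distance-weighted combination of per-bear surfaces.

    Per bear b the weight at pixel p is 1/max(d(p, centroid_b), eps)
    with eps half a pixel; weights are normalized per pixel to sum to
    one, so the combined surface is a pixelwise convex combination.
    """
    if not surfaces:
        raise ValueError("no surfaces to combine")
    gx, gy = land.cell_centers()
    eps = land.res / 2.0
    weights = []
    for s in surfaces:
        cx, cy = centroids[s.provenance]
        if not land.in_bounds(cx, cy):
            raise ValueError(f"centroid of {s.provenance} outside the landscape")
        d = np.hypot(gx - cx, gy - cy)
        weights.append(1.0 / np.maximum(d, eps))
    w = np.stack(weights)
    w /= w.sum(axis=0, keepdims=True)
    combined = np.sum(w * np.stack([s.values for s in surfaces]), axis=0)
    return Surface(values=combined, provenance="combined", season=season, diel=diel)


def boyce_index(surface: Surface, points: pd.DataFrame, land: LandscapeStack, n_bins: int = 10) -> BoyceResult:
    """Boyce index of a surface against hold-out locations.

    The surface's value range is cut into `n_bins` equal-width classes;
    F_i = (share of hold-out points in class i) / (share of study-area
    pixels in class i); the index is the Spearman correlation between
    F_i and the class rank, omitting empty classes.
    """
    x = points["x"].to_numpy()
    y = points["y"].to_numpy()
    ok = land.in_bounds(x, y)
    if ok.sum() < 50:
        raise ValueError("need at least 50 hold-out points inside the surface")
    r, c = land.xy_to_rc(x[ok], y[ok])
    vals_pts = surface.values[r, c]
    vmin, vmax = surface.values.min(), surface.values.max()
    if vmax <= vmin:
        raise ValueError("constant surface; Boyce undefined")
    edges = np.linspace(vmin, vmax, n_bins + 1)
    pt_counts, _ = np.histogram(vals_pts, bins=edges)
    px_counts, _ = np.histogram(surface.values.ravel(), bins=edges)
    obs = pt_counts / pt_counts.sum()
    exp = px_counts / px_counts.sum()
    nonempty = px_counts > 0
    f = obs[nonempty] / exp[nonempty]
    ranks = np.arange(1, n_bins + 1)[nonempty]
    valid = np.isfinite(f)
    if valid.sum() < 2 or np.all(f[valid] == f[valid][0]):
        raise ValueError("all hold-out points fall in one class; correlation undefined")
    rho = stats.spearmanr(ranks[valid], f[valid]).statistic
    return BoyceResult(n_bins=n_bins, bin_rank=ranks[valid], f_ratio=f[valid], spearman=float(rho))


def compare_surfaces(a: Surface, b: Surface, quantile: float = 0.2) -> dict:
    """Pearson correlation, difference raster, and top-quantile masks.

    The difference is a - b; the positive mask marks the `quantile`
    most-positive pixels among positive differences, the negative mask
    the most-negative among negative differences.
    """
    av, bv = a.values.ravel(), b.values.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("constant surface; Pearson correlation undefined")
    r = float(np.corrcoef(av, bv)[0, 1])
    diff = a.values - b.values
    pos = diff > 0
    neg = diff < 0
    pos_mask = np.zeros_like(diff, bool)
    neg_mask = np.zeros_like(diff, bool)
    if pos.any():
        thr = np.quantile(diff[pos], 1.0 - quantile)
        pos_mask = pos & (diff >= thr)
    if neg.any():
        thr = np.quantile(diff[neg], quantile)
        neg_mask = neg & (diff <= thr)
    return {"pearson_r": r, "difference": diff, "top_positive": pos_mask, "top_negative": neg_mask}


def sample_points_from_surface(
    surface: Surface, land: LandscapeStack, n: int, seed: int = 0, uniform: bool = False
) -> pd.DataFrame:
    """Random locations with probability proportional to the surface value
    (or uniform), for validation harnesses and hold-out generation."""
    rng = np.random.default_rng(seed)
    p = np.ones(surface.values.size) if uniform else surface.values.ravel().astype(float)
    p = p / p.sum()
    idx = rng.choice(surface.values.size, size=n, p=p)
    r, c = np.unravel_index(idx, surface.values.shape)
    x, y = land.rc_to_xy(r, c)
    jitter = rng.uniform(-land.res / 2, land.res / 2, size=(2, n))
    return pd.DataFrame({"x": x + jitter[0], "y": y + jitter[1]})
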