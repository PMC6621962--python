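"""Multi-scale step selection functions.

For each bear (optionally split by season and diel period) the observed
("used") covariates of every movement step are contrasted against the
"available" covariates of the same step, in a 1:1 matched conditional
logistic regression.  Used covariates are summarized within a 30 m
uniform buffer around the step segment; available covariates within a
Gaussian kernel centered on the step whose standard deviation sigma is a
candidate scale (by default the mean distance moved over 45 min to 6 h).
Model building follows a two-stage multi-scale protocol:

1. univariate fits per (variable, scale); the scale with the lowest AICc
   is the variable's characteristic scale;
2. variables correlated |r| > 0.7 at their characteristic scales are
   pruned, keeping the lower-AICc member of each pair;
3. greedy bidirectional stepwise selection by AICc from the null model.

The matched-pair conditional likelihood reduces to intercept-free
logistic regression on within-stratum covariate differences and is
maximized here by damped Newton iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import LandscapeStack

#: the six availability-scale time horizons (minutes)
DEFAULT_HORIZONS = (45, 90, 135, 180, 270, 360)
#: characteristic-scale candidates reported by the field study (m), usable as override
REFERENCE_SCALES = (360.0, 650.0, 837.0, 1007.0, 1288.0, 1523.0)


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

def _segment_distance(px, py, x0, y0, x1, y1):
    """Distance from points (px, py) to segment (x0,y0)-(x1,y1)."""
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    if L2 == 0.0:
        return np.hypot(px - x0, py - y0)
    t = np.clip(((px - x0) * dx + (py - y0) * dy) / L2, 0.0, 1.0)
    return np.hypot(px - (x0 + t * dx), py - (y0 + t * dy))


def extract_used(
    steps: pd.DataFrame,
    land: LandscapeStack,
    variables: list[str] | None = None,
    buffer_m: float = 30.0,
) -> pd.DataFrame:
    """Mean (continuous) or areal proportion (categorical) in a uniform
    buffer around each step segment.

    A cell belongs to the buffer when its center lies within `buffer_m`
    of the segment.  Steps whose buffer is entirely off-raster are
    dropped (the count is in ``result.attrs['n_dropped']``).
    """
    variables = list(variables or land.layers)
    nr, nc = land.shape
    res = land.res
    stack = np.stack([land.layers[v] for v in variables])
    rows, dropped = {}, 0
    for idx, s in steps.iterrows():
        x0, y0, x1, y1 = s["x0"], s["y0"], s["x1"], s["y1"]
        cmin = int(np.floor((min(x0, x1) - buffer_m - land.x0) / res))
        cmax = int(np.floor((max(x0, x1) + buffer_m - land.x0) / res))
        rmin = nr - 1 - int(np.floor((max(y0, y1) + buffer_m - land.y0) / res))
        rmax = nr - 1 - int(np.floor((min(y0, y1) - buffer_m - land.y0) / res))
        cmin, cmax = max(cmin, 0), min(cmax, nc - 1)
        rmin, rmax = max(rmin, 0), min(rmax, nr - 1)
        if cmin > cmax or rmin > rmax:
            dropped += 1
            continue
        rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij")
        cx, cy = land.rc_to_xy(rr, cc)
        inside = _segment_distance(cx, cy, x0, y0, x1, y1) <= buffer_m
        if not inside.any():
            dropped += 1
            continue
        vals = stack[:, rr[inside], cc[inside]].mean(axis=1)
        rows[idx] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=variables)
    out.attrs["n_dropped"] = dropped
    return out


def _kernel_weights(sigma: float, res: float) -> np.ndarray:
    """1-D Gaussian weights truncated at 3 sigma (cell-center distances)."""
    radius = int(math.floor(3.0 * sigma / res))
    d = np.arange(-radius, radius + 1) * res
    return np.exp(-(d**2) / (2.0 * sigma**2))


def smoothed_layers(
    land: LandscapeStack, sigma: float, variables: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Gaussian-kernel weighted mean of each layer at every cell.

    The kernel is the separable product of 1-D Gaussians truncated at
    3 sigma and is renormalized over in-raster cells, so edge cells are
    averages of the cells actually under the kernel.
    """
    variables = list(variables or land.layers)
    w = _kernel_weights(sigma, land.res)

    def smooth(arr):
        tmp = ndimage.correlate1d(arr, w, axis=0, mode="constant", cval=0.0)
        return ndimage.correlate1d(tmp, w, axis=1, mode="constant", cval=0.0)

    denom = smooth(np.ones(land.shape))
    return {v: smooth(land.layers[v]) / denom for v in variables}


def extract_available(
    steps: pd.DataFrame,
    land: LandscapeStack,
    sigma: float,
    variables: list[str] | None = None,
    center: str = "midpoint",
) -> pd.DataFrame:
    """Gaussian-kernel availability at scale `sigma` for each step.

    The kernel is centered on the step midpoint (or start point), snapped
    to the nearest cell center.  Steps whose center is off-raster are
    dropped.
    """
    variables = list(variables or land.layers)
    sm = smoothed_layers(land, sigma, variables)
    if center == "midpoint":
        cx = (steps["x0"].to_numpy() + steps["x1"].to_numpy()) / 2.0
        cy = (steps["y0"].to_numpy() + steps["y1"].to_numpy()) / 2.0
    elif center == "start":
        cx, cy = steps["x0"].to_numpy(), steps["y0"].to_numpy()
    else:
        raise ValueError(f"unknown kernel center {center!r}")
    ok = land.in_bounds(cx, cy)
    r, c = land.xy_to_rc(cx[ok], cy[ok])
    data = {v: sm[v][r, c] for v in variables}
    out = pd.DataFrame(data, index=steps.index[ok])
    out.attrs["n_dropped"] = int((~ok).sum())
    return out


def compute_scales(steps: pd.DataFrame, horizons=DEFAULT_HORIZONS, fix_interval: int | None = None) -> list[float]:
    """Mean net displacement over each time horizon, pooled across bears.

    Positions are taken from runs of temporally consecutive steps; a
    horizon must be a multiple of the fix interval.
    """
    if fix_interval is None:
        fix_interval = int(round(steps["duration"].median()))
    if min(horizons) < fix_interval:
        raise ValueError("horizon shorter than the fix interval")
    sums = {h: [] for h in horizons}
    for _, grp in steps.groupby("bear_id", sort=True):
        g = grp.sort_values("start_time")
        # split into runs of back-to-back steps
        breaks = (g["start_time"].to_numpy() != np.roll(g["end_time"].to_numpy(), 1))
        breaks[0] = True
        run_id = np.cumsum(breaks)
        for _, run in g.groupby(run_id):
            xs = np.append(run["x0"].to_numpy(), run["x1"].iloc[-1])
            ys = np.append(run["y0"].to_numpy(), run["y1"].iloc[-1])
            for h in horizons:
                k = int(round(h / fix_interval))
                if k < len(xs):
                    sums[h].append(np.hypot(xs[k:] - xs[:-k], ys[k:] - ys[:-k]))
    scales = []
    for h in horizons:
        if not sums[h]:
            raise ValueError(f"no consecutive runs long enough for horizon {h} min")
        scales.append(float(np.concatenate(sums[h]).mean()))
    return scales


# ---------------------------------------------------------------------------
# conditional logistic regression (1:1 matched)
# ---------------------------------------------------------------------------

@dataclass
class CLogitFit:
    beta: np.ndarray
    log_likelihood: float
    converged: bool
    separated: bool = False
    n_strata: int = 0
    variables: tuple[str, ...] = ()


def fit_conditional_logit(diff: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> CLogitFit:
    """Maximize the 1:1 matched conditional likelihood.

    `diff` is the n x k matrix of (used - available) covariate rows, one
    per stratum; the log-likelihood is sum(log sigmoid(diff @ beta)).
    Damped Newton iteration; complete separation (some direction makes
    every stratum's difference strictly positive) is flagged and the
    coefficients reported non-finite.
    """
    d = np.atleast_2d(np.asarray(diff, float))
    n, k = d.shape
    # a covariate whose used value beats (or loses to) the available value in
    # every stratum separates the matched likelihood completely
    one_signed = np.any((d > 0).all(axis=0) | (d < 0).all(axis=0))
    if one_signed:
        return CLogitFit(
            beta=np.full(k, np.nan), log_likelihood=float("nan"),
            converged=False, separated=True, n_strata=n,
        )
    beta = np.zeros(k)

    def nll(b):
        z = d @ b
        return float(np.logaddexp(0.0, -z).sum())

    cur = nll(beta)
    converged = False
    for _ in range(max_iter):
        z = d @ beta
        p = 1.0 / (1.0 + np.exp(-z))  # P(used | pair)
        grad = d.T @ (1.0 - p)
        w = p * (1.0 - p)
        hess = (d * w[:, None]).T @ d
        if np.linalg.norm(grad) < 1e-8:
            converged = True
            break
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        while t > 1e-6:
            new = nll(beta + t * step)
            if new <= cur + 1e-12:
                beta = beta + t * step
                cur = new
                break
            t /= 2.0
        else:
            converged = np.linalg.norm(grad) < 1e-6
            break
    separated = bool(np.abs(beta).max(initial=0.0) > 50.0)
    if separated:
        beta = np.full(k, np.nan)
        converged = False
    return CLogitFit(beta=beta, log_likelihood=-cur, converged=converged, separated=separated, n_strata=n)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# design assembly and model building
# ---------------------------------------------------------------------------

def standardize_pair(used: pd.DataFrame, avail: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Z-score used and available jointly; returns standardized copies and
    the constants {var: (mean, sd)}.  Zero-spread covariates are dropped."""
    pooled = pd.concat([used, avail])
    constants = {}
    u, a = used.copy(), avail.copy()
    for var in list(used.columns):
        m, sd = float(pooled[var].mean()), float(pooled[var].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            u = u.drop(columns=var)
            a = a.drop(columns=var)
            continue
        constants[var] = (m, sd)
        u[var] = (u[var] - m) / sd
        a[var] = (a[var] - m) / sd
    return u, a, constants


@dataclass
class SSFModel:
    """A fitted per-bear step selection function."""

    bear_id: str
    season: str
    diel: str
    variables: tuple[str, ...]
    scales: dict[str, float]  # characteristic scale sigma per variable (m)
    betas: dict[str, float]  # standardized coefficients
    z_constants: dict[str, tuple[float, float]]
    log_likelihood: float
    aicc: float
    n_strata: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "bear_id": self.bear_id,
                "season": self.season,
                "diel": self.diel,
                "variable": v,
                "scale_m": self.scales[v],
                "beta": self.betas[v],
                "z_mean": self.z_constants[v][0],
                "z_sd": self.z_constants[v][1],
                "aicc": self.aicc,
                "log_likelihood": self.log_likelihood,
                "n_strata": self.n_strata,
            }
            for v in self.variables
        ]


def select_characteristic_scales(
    used: pd.DataFrame, avail_by_scale: dict[float, pd.DataFrame]
) -> tuple[dict[str, float], dict[str, float]]:
    """Univariate conditional-logit screen: per variable, the scale with
    the lowest AICc.  Ties (and near-ties within 1e-9) favor the
    smaller sigma.  Returns ({var: sigma*}, {var: univariate AICc})."""
    scales_sorted = sorted(avail_by_scale)
    chosen, best_aicc = {}, {}
    for var in used.columns:
        best = None
        for sigma in scales_sorted:
            avail = avail_by_scale[sigma]
            idx = used.index.intersection(avail.index)
            u, a, consts = standardize_pair(used.loc[idx, [var]], avail.loc[idx, [var]])
            if var not in consts:
                continue
            diff = (u[var] - a[var]).to_numpy()[:, None]
            fit = fit_conditional_logit(diff)
            if fit.separated or not np.isfinite(fit.log_likelihood):
                continue
            crit = aicc(fit.log_likelihood, 1, fit.n_strata)
            if best is None or crit < best[0] - 1e-9:
                best = (crit, sigma)
        if best is not None:
            best_aicc[var] = best[0]
            chosen[var] = best[1]
    return chosen, best_aicc


def prune_correlated(
    used: pd.DataFrame,
    avail: pd.DataFrame,
    univariate_aicc: dict[str, float],
    threshold: float = 0.7,
) -> list[str]:
    """Drop the worse (higher univariate AICc) member of each pair whose
    pooled used+available values correlate with |r| strictly above the
    threshold."""
    keep = [v for v in used.columns if v in univariate_aicc]
    pooled = pd.concat([used[keep], avail[keep]])
    while True:
        if len(keep) < 2:
            break
        corr = pooled[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        drop = keep[i] if univariate_aicc[keep[i]] > univariate_aicc[keep[j]] else keep[j]
        keep.remove(drop)
    return keep


def stepwise_select(
    used: pd.DataFrame, avail: pd.DataFrame, candidates: list[str]
) -> tuple[tuple[str, ...], CLogitFit, float]:
    """Greedy bidirectional stepwise AICc selection from the null model.

    At each iteration the single add or drop that most lowers AICc is
    taken; stops when no move improves.  Returns (variables, fit, aicc);
    the null model (no variables) has log-likelihood n log(1/2).
    """
    n = len(used)
    diffs = {v: (used[v] - avail[v]).to_numpy() for v in candidates}
    cache: dict[frozenset, tuple[CLogitFit, float]] = {}

    def evaluate(varset: frozenset) -> tuple[CLogitFit, float]:
        if varset in cache:
            return cache[varset]
        if not varset:
            ll = n * math.log(0.5)
            fit = CLogitFit(beta=np.zeros(0), log_likelihood=ll, converged=True, n_strata=n)
            crit = -2.0 * ll
        else:
            ordered = tuple(v for v in candidates if v in varset)
            d = np.column_stack([diffs[v] for v in ordered])
            fit = fit_conditional_logit(d)
            fit.variables = ordered
            crit = (
                math.inf
                if fit.separated or not np.isfinite(fit.log_likelihood)
                else aicc(fit.log_likelihood, len(ordered), n)
            )
        cache[varset] = (fit, crit)
        return fit, crit

    current = frozenset()
    fit, crit = evaluate(current)
    while True:
        moves = [current | {v} for v in candidates if v not in current]
        moves += [current - {v} for v in current]
        best = min(((evaluate(m)[1], m) for m in moves), default=None, key=lambda t: t[0])
        if best is None or best[0] >= crit - 1e-9:
            break
        crit = best[0]
        current = best[1]
        fit = evaluate(current)[0]
    ordered = tuple(v for v in candidates if v in current)
    return ordered, fit, crit


def fit_ssf(
    steps: pd.DataFrame,
    land: LandscapeStack,
    scales: list[float],
    variables: list[str] | None = None,
    bear_id: str = "",
    season: str = "all",
    diel: str = "all",
    min_strata: int = 20,
) -> SSFModel | None:
    """Full multi-scale SSF for one bear(-season-diel) step set.

    Returns None when fewer than `min_strata` complete strata survive
    extraction.  The returned model stores standardized coefficients and
    the z-scoring constants needed for prediction.
    """
    variables = list(variables or [v for v in land.layers if v != "housing_density"])
    used = extract_used(steps, land, variables)
    avail_by_scale = {s: extract_available(steps, land, s, variables) for s in scales}
    common = used.index
    for a in avail_by_scale.values():
        common = common.intersection(a.index)
    used = used.loc[common]
    avail_by_scale = {s: a.loc[common] for s, a in avail_by_scale.items()}
    if len(common) < min_strata:
        return None

    char_scales, uni_aicc = select_characteristic_scales(used, avail_by_scale)
    if not char_scales:
        return None
    avail_char = pd.DataFrame(
        {v: avail_by_scale[s].loc[common, v] for v, s in char_scales.items()}, index=common
    )
    used_char = used[list(char_scales)]
    kept = prune_correlated(used_char, avail_char, uni_aicc)
    u, a, consts = standardize_pair(used_char[kept], avail_char[kept])
    kept = [v for v in kept if v in consts]
    sel_vars, fit, crit = stepwise_select(u, a, kept)
    betas = dict(zip(fit.variables, fit.beta)) if len(sel_vars) else {}
    return SSFModel(
        bear_id=bear_id,
        season=season,
        diel=diel,
        variables=sel_vars,
        scales={v: char_scales[v] for v in sel_vars},
        betas={v: float(betas[v]) for v in sel_vars},
        z_constants={v: consts[v] for v in sel_vars},
        log_likelihood=fit.log_likelihood,
        aicc=crit if np.isfinite(crit) else float("nan"),
        n_strata=len(common),
    )


def models_to_frame(models: list[SSFModel]) -> pd.DataFrame:
    rows = [r for m in models if m is not None for r in m.to_rows()]
    return pd.DataFrame(rows)


def models_from_frame(frame: pd.DataFrame) -> list[SSFModel]:
    models = []
    for (bear, season, diel), grp in frame.groupby(["bear_id", "season", "diel"], sort=True):
        models.append(
            SSFModel(
                bear_id=bear,
                season=season,
                diel=diel,
                variables=tuple(grp["variable"]),
                scales=dict(zip(grp["variable"], grp["scale_m"])),
                betas=dict(zip(grp["variable"], grp["beta"])),
                z_constants={v: (m, s) for v, m, s in zip(grp["variable"], grp["z_mean"], grp["z_sd"])},
                log_likelihood=float(grp["log_likelihood"].iloc[0]),
                aicc=float(grp["aicc"].iloc[0]),
                n_strata=int(grp["n_strata"].iloc[0]),
            )
        )
    return models
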