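"""Synthetic GPS-collar studies with known ground truth.

Each simulated bear follows a 3-state switching biased correlated random
walk: a latent Markov chain (encamped / foraging / movement) emits step
lengths from state-specific gamma distributions and turning angles from
von Mises distributions, and candidate step endpoints are accepted by
rejection sampling with probability proportional to exp(sum(beta * x)),
so the realized selection obeys a step-selection function with the
configured coefficients.  Coefficients can differ by season and by diel
period (switching at configured sunrise/sunset hours).  Between den
entry and emergence the bear sits at its den with small Gaussian jitter.

Collar imperfections (unresolved fixes, quality classes, PDOP values,
dropped fixes) are injected afterwards so the cleaning rules have known
truth to recover.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import DEFAULT_CALENDAR, SeasonCalendar
from .landscape import ConfigurationError, LandscapeStack, make_landscape

STATE_NAMES = ("encamped", "foraging", "movement")
FIX_CLASSES = ("unresolved", "qfp_uncertain", "qfp_certain", "two_d", "three_d")


@dataclass
class HMMTruth:
    """Ground-truth emission and transition parameters for the 3 states."""

    step_means: tuple[float, ...] = (20.0, 120.0, 500.0)  # m
    step_sds: tuple[float, ...] = (15.0, 70.0, 250.0)
    angle_means: tuple[float, ...] = (math.pi, 0.0, 0.0)
    angle_kappas: tuple[float, ...] = (0.3, 0.8, 3.0)
    tpm: tuple[tuple[float, ...], ...] = (
        (0.80, 0.15, 0.05),
        (0.15, 0.70, 0.15),
        (0.05, 0.15, 0.80),
    )
    initial: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        tpm = np.asarray(self.tpm)
        if not np.allclose(tpm.sum(axis=1), 1.0):
            raise ConfigurationError("transition-matrix rows must sum to 1")
        if min(self.step_means) <= 0 or min(self.step_sds) <= 0:
            raise ConfigurationError("gamma parameters must be positive")
        if min(self.angle_kappas) < 0:
            raise ConfigurationError("von Mises concentration must be >= 0")


@dataclass
class BearConfig:
    """One simulated bear: where it lives, what it selects, how it moves."""

    bear_id: str
    home_center: tuple[float, float]
    true_coefficients: dict  # var -> beta, or (season, diel) -> {var -> beta}
    hmm_truth: HMMTruth = field(default_factory=HMMTruth)
    fix_interval: int = 45  # minutes
    den_entry: dt.date | None = None
    den_emergence: dt.date | None = None

    def coefficients_for(self, season: str, diel: str) -> dict[str, float]:
        first = next(iter(self.true_coefficients.values()), 0.0)
        if isinstance(first, dict):
            key = (season, diel)
            if key in self.true_coefficients:
                return self.true_coefficients[key]
            return self.true_coefficients.get(season, {})
        return self.true_coefficients


@dataclass
class HRHDCurve:
    """Logistic curve linking home-range housing density to the impervious beta.

    beta(x) = lower + (upper - lower) / (1 + exp(-slope * (x - inflection)))
    with housing density x in houses/km^2.  Rural bears (low x) sit near
    `lower` (strong avoidance); suburban bears approach `upper`.
    """

    lower: float = -1.2
    upper: float = -0.1
    inflection: float = 75.0
    slope: float = 0.08

    def __call__(self, housing_density):
        x = np.asarray(housing_density, float)
        return self.lower + (self.upper - self.lower) / (1.0 + np.exp(-self.slope * (x - self.inflection)))


@dataclass
class SyntheticStudy:
    """A landscape plus a population of bears with stored ground truth."""

    landscape: LandscapeStack
    bears: list[BearConfig]
    hrhd_curve: HRHDCurve = field(default_factory=HRHDCurve)
    hrhd_noise_sd: float = 0.05
    site_latitude: float = 42.38
    site_longitude: float = -72.52
    timezone: str = "America/New_York"
    day_start_hour: float = 6.0  # simulator's configured sunrise (local)
    day_end_hour: float = 19.0  # configured sunset
    season_calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)
    rng_seed: int = 0

    @property
    def housing_density(self) -> np.ndarray:
        return self.landscape.layers["housing_density"]


def default_study(
    n_bears: int = 5,
    seed: int = 0,
    shape: tuple[int, int] = (200, 200),
    fix_interval: int = 45,
    den_entry: dt.date | None = None,
    den_emergence: dt.date | None = None,
    beta_overrides: dict | None = None,
    landscape: LandscapeStack | None = None,
) -> SyntheticStudy:
    """Build the standard synthetic study used across the analysis.

    Bears share season/diel-varying preferences for forest, agriculture
    and roads; each bear's impervious-surface coefficient is its home
    housing density pushed through the population HRHD logistic plus
    individual noise (stored, so the acclimation analysis has truth).
    """
    rng = np.random.default_rng(seed)
    land = landscape if landscape is not None else make_landscape(shape=shape, seed=seed)
    curve = HRHDCurve()
    noise_sd = 0.05

    xmin, ymin, xmax, ymax = land.extent
    margin = 0.2 * (xmax - xmin)
    bears = []
    for i in range(n_bears):
        center = (
            float(rng.uniform(xmin + margin, xmax - margin)),
            float(rng.uniform(ymin + margin, ymax - margin)),
        )
        hd = float(land.value_at("housing_density", *center))
        beta_imp = float(curve(hd) + rng.normal(0.0, noise_sd))
        base = {
            "deciduous_forest": 0.6,
            "coniferous_forest": 0.4,
            "mixed_forest": 0.5,
            "forested_wetland": 0.5,
            "agriculture": -0.5,
            "percent_impervious": beta_imp,
            "roads": -0.4,
        }
        if beta_overrides:
            base.update(beta_overrides)
        coefs = {}
        for season in ("spring", "summer", "fall"):
            for diel in ("day", "night"):
                c = dict(base)
                if diel == "night":
                    # nocturnal tolerance of development, strongest spring/fall
                    relax = 0.6 if season in ("spring", "fall") else 0.3
                    c["percent_impervious"] = beta_imp * (1 - relax)
                    c["roads"] = base["roads"] * (1 - relax)
                    if season == "fall":
                        c["agriculture"] = 0.3  # fall-night crop raiding
                coefs[(season, diel)] = c
        bears.append(
            BearConfig(
                bear_id=f"bear{i + 1:02d}",
                home_center=center,
                true_coefficients=coefs,
                fix_interval=fix_interval,
                den_entry=den_entry,
                den_emergence=den_emergence,
            )
        )
    return SyntheticStudy(landscape=land, bears=bears, hrhd_curve=curve, hrhd_noise_sd=noise_sd, rng_seed=seed)


def _linear_predictor_grid(land: LandscapeStack, coefs: dict[str, float]) -> np.ndarray:
    lp = np.zeros(land.shape)
    for var, beta in coefs.items():
        if var in land.layers and beta != 0.0:
            layer = land.layers[var]
            if land.kinds[var] == "continuous":
                sd = layer.std()
                layer = (layer - layer.mean()) / sd if sd > 0 else layer * 0.0
            lp = lp + beta * layer
    return lp


def simulate_tracks(
    study: SyntheticStudy,
    duration_days: int = 60,
    start: dt.date = dt.date(2016, 6, 1),
    seed: int = 0,
    max_tries: int = 40,
    home_bias: float = 0.25,
) -> pd.DataFrame:
    """Simulate GPS tracks for every bear in the study.

    Returns a DataFrame with columns bear_id, timestamp (UTC), x, y,
    true_state, true_season, true_diel.  `home_bias` rotates proposed
    headings toward the home center with weight growing in distance,
    keeping home ranges bounded (the bias is part of the movement
    kernel, not of habitat selection).
    """
    if duration_days < 10:
        raise ConfigurationError("duration must be at least 10 days")
    land = study.landscape
    xmin, ymin, xmax, ymax = land.extent
    frames = []
    for b_idx, bear in enumerate(study.bears):
        if not land.in_bounds(*bear.home_center):
            raise ConfigurationError(f"{bear.bear_id} home center outside the landscape")
        rng = np.random.default_rng([seed, b_idx])
        truth = bear.hmm_truth
        tpm = np.asarray(truth.tpm)
        shapes = np.asarray(truth.step_means) ** 2 / np.asarray(truth.step_sds) ** 2
        scales = np.asarray(truth.step_sds) ** 2 / np.asarray(truth.step_means)

        # precompute standardized linear predictors per (season, diel)
        lp_grids: dict[tuple[str, str], np.ndarray] = {}
        for season in ("spring", "summer", "fall"):
            for diel in ("day", "night"):
                grid = _linear_predictor_grid(land, bear.coefficients_for(season, diel))
                lp_grids[(season, diel)] = grid - grid.max()  # acceptance = exp(lp - max)

        n_fix = int(duration_days * 24 * 60 / bear.fix_interval)
        times = pd.date_range(
            start=pd.Timestamp(start, tz=study.timezone),
            periods=n_fix,
            freq=f"{bear.fix_interval}min",
        )
        xs = np.empty(n_fix)
        ys = np.empty(n_fix)
        states = np.empty(n_fix, int)
        seasons = np.empty(n_fix, object)
        diels = np.empty(n_fix, object)

        x, y = bear.home_center
        heading = rng.uniform(-math.pi, math.pi)
        state = int(rng.choice(3, p=np.asarray(truth.initial)))
        for t in range(n_fix):
            local = times[t]
            date = local.date()
            season = study.season_calendar.season_of(date)
            hour = local.hour + local.minute / 60.0
            diel = "day" if study.day_start_hour <= hour < study.day_end_hour else "night"
            if bear.den_entry is None or bear.den_emergence is None:
                denning = False
            elif bear.den_entry < bear.den_emergence:  # one winter: entry then emergence
                denning = bear.den_entry <= date < bear.den_emergence
            else:  # dates bound the active period instead
                denning = not (bear.den_emergence <= date < bear.den_entry)
            if t == 0:
                xs[t], ys[t] = x, y
                states[t], seasons[t], diels[t] = state, season, diel
                continue
            if denning:
                dx, dy = rng.normal(0.0, 5.0, size=2)
                x, y = bear.home_center[0] + dx, bear.home_center[1] + dy
                xs[t], ys[t] = x, y
                states[t], seasons[t], diels[t] = 0, season, diel
                state = 0
                continue
            state = int(rng.choice(3, p=tpm[state]))
            lp = lp_grids[(season, diel)]
            for _ in range(max_tries):
                step = rng.gamma(shapes[state], scales[state])
                turn = rng.vonmises(truth.angle_means[state], truth.angle_kappas[state])
                cand_heading = heading + turn
                # mild centripetal bias toward home, stronger when far away
                to_home = math.atan2(bear.home_center[1] - y, bear.home_center[0] - x)
                dist_home = math.hypot(bear.home_center[0] - x, bear.home_center[1] - y)
                w = home_bias * min(1.0, dist_home / 2000.0)
                vx = (1 - w) * math.cos(cand_heading) + w * math.cos(to_home)
                vy = (1 - w) * math.sin(cand_heading) + w * math.sin(to_home)
                cand_heading = math.atan2(vy, vx)
                cx = x + step * math.cos(cand_heading)
                cy = y + step * math.sin(cand_heading)
                if not (xmin <= cx < xmax and ymin <= cy < ymax):
                    continue
                r, c = land.xy_to_rc(cx, cy)
                if rng.random() < math.exp(lp[r, c]):
                    x, y, heading = cx, cy, cand_heading
                    break
            xs[t], ys[t] = x, y
            states[t], seasons[t], diels[t] = state, season, diel

        frames.append(
            pd.DataFrame(
                {
                    "bear_id": bear.bear_id,
                    "timestamp": times.tz_convert("UTC"),
                    "x": xs,
                    "y": ys,
                    "true_state": states,
                    "true_season": seasons,
                    "true_diel": diels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def expected_removal_fraction(rates: dict[str, float], pdop_median: float = 2.5, pdop_sigma: float = 0.8) -> float:
    """Analytic expected fraction removed by the PDOP/class filter.

    PDOP is lognormal(log(pdop_median), pdop_sigma) independent of class.
    Unresolved fixes are always removed; QFP-uncertain and 2D fixes are
    removed when PDOP > 5; QFP-certain and 3D when PDOP > 20.
    """
    dist = stats.lognorm(s=pdop_sigma, scale=pdop_median)
    p_unres = rates.get("unresolved", 0.0)
    p_weak = rates.get("qfp_uncertain", 0.0) + rates.get("two_d", 0.0)
    p_strong = 1.0 - p_unres - p_weak
    return p_unres + p_weak * dist.sf(5.0) + p_strong * dist.sf(20.0)


def inject_fix_errors(
    tracks: pd.DataFrame,
    rates: dict[str, float] | None = None,
    seed: int = 0,
    pdop_median: float = 2.5,
    pdop_sigma: float = 0.8,
) -> pd.DataFrame:
    """Annotate tracks with PDOP and fix-class; drop fixes to create gaps.

    `rates` keys: unresolved, qfp_uncertain, qfp_certain, two_d (class
    probabilities; remainder is three_d) and dropped (probability a fix
    is missing entirely, creating schedule gaps).  Truth columns are
    retained so tests can audit the filter.
    """
    # defaults give an expected quality-filter loss of ~3.9%, the few-percent
    # scale typical of wildlife GPS collar screens
    rates = dict(rates or {"unresolved": 0.012, "qfp_uncertain": 0.05, "two_d": 0.07, "dropped": 0.01})
    class_keys = ("unresolved", "qfp_uncertain", "qfp_certain", "two_d")
    p = {k: rates.get(k, 0.0) for k in class_keys}
    if any(v < 0 or v > 1 for v in list(p.values()) + [rates.get("dropped", 0.0)]):
        raise ConfigurationError("rates must lie in [0, 1]")
    p_rest = 1.0 - sum(p.values())
    if p_rest < 0:
        raise ConfigurationError("fix-class rates sum to more than 1")

    rng = np.random.default_rng(seed)
    out = tracks.copy()
    n = len(out)
    classes = rng.choice(
        np.array(class_keys + ("three_d",), object),
        size=n,
        p=[p[k] for k in class_keys] + [p_rest],
    )
    out["fix_class"] = classes
    out["pdop"] = np.round(rng.lognormal(math.log(pdop_median), pdop_sigma, size=n), 2)
    keep = rng.random(n) >= rates.get("dropped", 0.0)
    return out.loc[keep].reset_index(drop=True)


def simulate_matched_pairs(
    n: int, beta: np.ndarray, seed: int = 0, variable_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched used/available covariate pairs from a known selection vector.

    Each stratum offers two candidate covariate vectors drawn iid
    N(0, I); the used one is chosen with probability
    exp(beta'x1) / (exp(beta'x1) + exp(beta'x2)), the discrete-choice
    model the paired conditional logit assumes.  Returns (used, avail)
    DataFrames for recovery and stepwise-consistency checks.
    """
    beta = np.asarray(beta, float)
    k = beta.size
    names = variable_names or [f"v{i + 1}" for i in range(k)]
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=(n, k))
    x2 = rng.normal(size=(n, k))
    p1 = 1.0 / (1.0 + np.exp(-(x1 - x2) @ beta))
    take1 = rng.random(n) < p1
    used = np.where(take1[:, None], x1, x2)
    avail = np.where(take1[:, None], x2, x1)
    return pd.DataFrame(used, columns=names), pd.DataFrame(avail, columns=names)


def simulate_scale_design(
    avail_by_scale: dict[float, pd.DataFrame],
    sigma_gen: float,
    variable: str,
    beta: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Used covariates generated by selection against one availability scale.

    Given availability extractions of `variable` at several scales (from
    a real landscape, so the cross-scale correlation is realistic), the
    used value for each stratum is a_gen +/- e with the matched-pair
    logit P(+) = sigmoid(beta * e / sd(a_gen)) — i.e. the availability
    at `sigma_gen` literally generates selection.  Models at other
    scales see the same used values against mismeasured availability and
    are penalized by errors-in-variables attenuation, which is what
    makes the characteristic scale recoverable.
    """
    rng = np.random.default_rng(seed)
    a_gen = avail_by_scale[sigma_gen][variable].to_numpy()
    sd = a_gen.std()
    if sd <= 0:
        raise ConfigurationError("generating-scale availability has zero spread")
    e = rng.normal(0.0, sd, a_gen.size)
    p = 1.0 / (1.0 + np.exp(-beta * e / sd))
    sign = np.where(rng.random(a_gen.size) < p, 1.0, -1.0)
    return pd.DataFrame({variable: a_gen + sign * e}, index=avail_by_scale[sigma_gen].index)


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    out = tracks.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    out = pd.read_csv(path)
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    return out
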