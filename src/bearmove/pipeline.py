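"""End-to-end pipeline: synthesize -> preprocess -> HMM -> seasons ->
diel summaries -> SSF -> HRHD -> surfaces.

Stages hand data off through flat files (CSV, ASCII grids, YAML/JSON) so
any stage can be rerun or inspected in isolation; a manifest records
seeds, input hashes and outputs for reproducibility checks.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dielsel, hmm, hrhd, preprocess, seasons, simulate, ssf, surfaces
from .calendars import DEFAULT_CALENDAR, SeasonCalendar
from .landscape import LandscapeStack

log = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "hmm", "seasons", "diel", "ssf", "hrhd", "surfaces")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to YAML."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_bears: int = 5
    duration_days: int = 60
    start_date: str = "2016-06-01"
    landscape_shape: tuple[int, int] = (200, 200)
    fix_interval: int = 45
    site_latitude: float = 42.38
    site_longitude: float = -72.52
    timezone: str = "America/New_York"
    season_mode: str = "default"  # "default" calendar or "cluster"
    scales: list[float] | None = None  # override; default recomputed from steps
    scale_horizons: tuple[int, ...] = ssf.DEFAULT_HORIZONS
    n_boot: int = 500
    hmm_restarts: int = 4
    hrhd_min_bears: int = 8
    n_holdout_bears: int = 8
    n_holdout_points: int = 2000
    stages: tuple[str, ...] = STAGES
    split_season_diel: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("landscape_shape", "scale_horizons", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage names: {sorted(bad)}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    bad = set(config.stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage names: {sorted(bad)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "started": dt.datetime.now(dt.timezone.utc).isoformat()}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files if f.exists()},
            "seconds": round(time.time() - t0, 2),
        }

    start = dt.date.fromisoformat(config.start_date)
    enabled = [s for s in STAGES if s in config.stages]

    # ---- synth ------------------------------------------------------
    if "synth" in enabled:
        t0 = time.time()
        study = simulate.default_study(
            n_bears=config.n_bears, seed=config.seed, shape=tuple(config.landscape_shape),
            fix_interval=config.fix_interval,
        )
        tracks = simulate.simulate_tracks(study, duration_days=config.duration_days, start=start, seed=config.seed)
        tracks = simulate.inject_fix_errors(tracks, seed=config.seed + 1)
        raster_dir = out / "rasters"
        study.landscape.write_ascii_grids(raster_dir)
        simulate.write_tracks_csv(tracks, out / "tracks.csv")
        truth = {
            "hrhd_curve": asdict(study.hrhd_curve),
            "bears": {
                b.bear_id: {
                    "home_center": list(b.home_center),
                    "impervious_beta_by_context": {
                        f"{s}/{d}": b.coefficients_for(s, d).get("percent_impervious")
                        for s in ("spring", "summer", "fall") for d in ("day", "night")
                    },
                }
                for b in study.bears
            },
        }
        (out / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
        record("synth", [out / "tracks.csv", out / "ground_truth.yaml"] + sorted(raster_dir.glob("*.asc")), t0)

    land = LandscapeStack.read_ascii_grids(out / "rasters")

    # ---- preprocess -------------------------------------------------
    if "preprocess" in enabled:
        t0 = time.time()
        fixes = simulate.read_tracks_csv(out / "tracks.csv")
        kept, report = preprocess.filter_fixes(fixes)
        den_dates: dict[str, tuple] = {}
        for bear, grp in kept.groupby("bear_id"):
            span = (grp["timestamp"].max() - grp["timestamp"].min()).days
            if span >= 60:
                try:
                    den_dates[bear] = preprocess.detect_den_period(grp, timezone=config.timezone)
                except ValueError:
                    den_dates[bear] = None
            else:
                den_dates[bear] = None
        kept = preprocess.exclude_den_fixes(kept, den_dates, config.timezone)
        steps = preprocess.build_steps(kept, nominal_interval=config.fix_interval)
        steps = preprocess.assign_diel(steps, config.site_latitude, config.site_longitude, config.timezone)
        steps = preprocess.assign_season(steps, DEFAULT_CALENDAR, den_dates, config.timezone)
        report.to_csv(out / "removal_report.csv", index=False)
        steps.to_csv(out / "steps.csv", index=False)
        kept.to_csv(out / "fixes_clean.csv", index=False)
        with open(out / "den_dates.json", "w") as fh:
            json.dump({b: ([str(d) for d in v] if v else None) for b, v in den_dates.items()}, fh, indent=1)
        record("preprocess", [out / "removal_report.csv", out / "steps.csv", out / "fixes_clean.csv"], t0)

    def load_steps(name="steps_labeled.csv", fallback="steps.csv"):
        path = out / name
        if not path.exists():
            path = out / fallback
        t = pd.read_csv(path)
        for col in ("start_time", "end_time"):
            t[col] = pd.to_datetime(t[col], utc=True)
        return t

    # ---- hmm --------------------------------------------------------
    if "hmm" in enabled:
        t0 = time.time()
        steps = load_steps("steps.csv")
        labeled, rows = [], []
        for bear, grp in steps.groupby("bear_id", sort=True):
            g = grp.reset_index(drop=True)
            fit = hmm.fit_hmm(
                g["length"].to_numpy(), g["turning_angle"].to_numpy(),
                n_restarts=config.hmm_restarts, seed=config.seed,
            )
            labeled.append(hmm.label_behavior(fit, g))
            rows.append({
                "bear_id": bear, "log_likelihood": fit.log_likelihood, "aic": fit.aic,
                "converged": fit.converged,
                **{f"mean_{s}": m for s, m in zip(hmm.STATE_NAMES, fit.step_means)},
                **{f"sd_{s}": m for s, m in zip(hmm.STATE_NAMES, fit.step_sds)},
                **{f"kappa_{s}": m for s, m in zip(hmm.STATE_NAMES, fit.angle_kappas)},
            })
        steps_labeled = pd.concat(labeled, ignore_index=True)
        steps_labeled.to_csv(out / "steps_labeled.csv", index=False)
        pd.DataFrame(rows).to_csv(out / "hmm_summary.csv", index=False)
        record("hmm", [out / "steps_labeled.csv", out / "hmm_summary.csv"], t0)

    # ---- seasons ----------------------------------------------------
    if "seasons" in enabled:
        t0 = time.time()
        steps = load_steps()
        calendar = DEFAULT_CALENDAR
        files = [out / "season_calendar.txt"]
        if config.season_mode == "cluster":
            cov = seasons.point_covariates(steps, land)
            feats = seasons.build_season_features(cov, timezone=config.timezone)
            feat_cols = [c for c in feats.columns if c not in ("date", "bear_year")]
            k, gap_table = seasons.choose_k_gap(feats[feat_cols].to_numpy(), seed=config.seed)
            labels = seasons.cluster_days(feats, k, seed=config.seed)
            calendar = seasons.derive_season_dates(labels)
            gap_table.to_csv(out / "gap_curve.csv", index=False)
            files.append(out / "gap_curve.csv")
            steps = steps.drop(columns=["season"])
            steps = preprocess.assign_season(steps, calendar, None, config.timezone)
            steps.to_csv(out / "steps_labeled.csv", index=False)
        calendar.to_file(out / "season_calendar.txt")
        record("seasons", files, t0)

    # ---- diel -------------------------------------------------------
    home_ranges: dict[tuple[str, str], dielsel.HomeRange] = {}

    def build_home_ranges(steps: pd.DataFrame) -> None:
        if home_ranges:
            return
        for bear, grp in steps.groupby("bear_id", sort=True):
            for season_name, sg in [("all", grp)] + list(grp.groupby("season")):
                if len(sg) >= 30:
                    try:
                        home_ranges[(bear, season_name)] = dielsel.estimate_kde_home_range(
                            sg.rename(columns={"x1": "x1", "y1": "y1"}), land, bear, season_name
                        )
                    except ValueError:
                        pass

    if "diel" in enabled:
        t0 = time.time()
        steps = load_steps()
        movement = steps[steps.get("behavior_state", pd.Series("movement", index=steps.index)) == "movement"]
        build_home_ranges(steps)
        lengths = dielsel.bootstrap_step_lengths(movement, n_boot=config.n_boot, seed=config.seed, timezone=config.timezone)
        ratios = dielsel.selection_ratio_by_bin(
            movement, home_ranges, land, n_boot=config.n_boot, seed=config.seed, timezone=config.timezone
        )
        lengths.to_csv(out / "diel_step_lengths.csv", index=False)
        ratios.to_csv(out / "diel_selection_ratios.csv", index=False)
        record("diel", [out / "diel_step_lengths.csv", out / "diel_selection_ratios.csv"], t0)

    # ---- ssf --------------------------------------------------------
    if "ssf" in enabled:
        t0 = time.time()
        steps = load_steps()
        movement = steps[steps["behavior_state"] == "movement"] if "behavior_state" in steps else steps
        scales = list(config.scales) if config.scales else ssf.compute_scales(
            movement, horizons=config.scale_horizons, fix_interval=config.fix_interval
        )
        # availability kernels must fit the landscape: truncation at 3 sigma
        # within half the smaller extent, else edge renormalization biases the
        # scale screen toward the largest sigma
        xmin, ymin, xmax, ymax = land.extent
        sigma_cap = min(xmax - xmin, ymax - ymin) / 6.0
        capped = [s for s in scales if s <= sigma_cap]
        if capped and len(capped) < len(scales):
            log.info("ssf: dropping scales above %.0f m (landscape too small)", sigma_cap)
            scales = capped
        variables = [v for v in land.layers if v != "housing_density"]
        models = []
        for bear, grp in movement.groupby("bear_id", sort=True):
            models.append(ssf.fit_ssf(grp, land, scales, variables, bear_id=bear))
            if config.split_season_diel:
                for (season_name, diel), sg in grp.groupby(["season", "diel"]):
                    models.append(
                        ssf.fit_ssf(sg, land, scales, variables, bear_id=bear, season=season_name, diel=diel)
                    )
        table = ssf.models_to_frame(models)
        table.to_csv(out / "ssf_models.csv", index=False)
        pd.DataFrame({"scale_m": scales}).to_csv(out / "scales.csv", index=False)
        record("ssf", [out / "ssf_models.csv", out / "scales.csv"], t0)

    # ---- hrhd -------------------------------------------------------
    if "hrhd" in enabled:
        t0 = time.time()
        steps = load_steps()
        build_home_ranges(steps)
        models = ssf.models_from_frame(pd.read_csv(out / "ssf_models.csv"))
        table = hrhd.hrhd_table(models, home_ranges, land, season="all")
        table.to_csv(out / "hrhd_table.csv", index=False)
        files = [out / "hrhd_table.csv"]
        if len(table) >= config.hrhd_min_bears:
            fit = hrhd.fit_coefficient_curves(table, min_bears=config.hrhd_min_bears, seed=config.seed)
            summary = {"aicc": fit.aicc, "best": fit.best, "params": fit.params}
            (out / "hrhd_fit.json").write_text(json.dumps(summary, indent=1, default=float))
            files.append(out / "hrhd_fit.json")
        else:
            log.info("hrhd: only %d qualifying bears (< %d); curve fits skipped", len(table), config.hrhd_min_bears)
        record("hrhd", files, t0)

    # ---- surfaces ---------------------------------------------------
    if "surfaces" in enabled:
        t0 = time.time()
        steps = load_steps()
        build_home_ranges(steps)
        models = ssf.models_from_frame(pd.read_csv(out / "ssf_models.csv"))
        pooled = [m for m in models if m.season == "all" and m.diel == "all" and m.variables]
        per_bear = {m.bear_id: surfaces.predict_bear_surface(m, land) for m in pooled}
        centroids = {
            b: home_ranges[(b, "all")].centroid for b in per_bear if (b, "all") in home_ranges
        }
        usable = [surfaces.rescale_minmax(s) for b, s in per_bear.items() if b in centroids]
        combined = surfaces.weight_and_combine(usable, centroids, land)
        np.savetxt(out / "combined_surface.asc.txt", combined.values, fmt="%.6g")

        # hold-out bears: same landscape and generative population, new
        # individuals (fresh home centers and coefficient noise)
        hold = simulate.default_study(n_bears=config.n_holdout_bears, seed=config.seed + 99, landscape=land)
        hold_tracks = simulate.simulate_tracks(hold, duration_days=10, start=start, seed=config.seed + 99)
        pts = hold_tracks.rename(columns={"x": "x", "y": "y"})[["x", "y"]]
        if len(pts) > config.n_holdout_points:
            pts = pts.sample(config.n_holdout_points, random_state=config.seed)
        boyce = surfaces.boyce_index(combined, pts, land)
        pd.DataFrame({"bin_rank": boyce.bin_rank, "f_ratio": boyce.f_ratio}).to_csv(out / "boyce_bins.csv", index=False)
        (out / "boyce.json").write_text(json.dumps({"spearman": boyce.spearman, "n_bins": boyce.n_bins}))
        record("surfaces", [out / "combined_surface.asc.txt", out / "boyce.json", out / "boyce_bins.csv"], t0)

    manifest["finished"] = dt.datetime.now(dt.timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
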