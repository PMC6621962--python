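"""Home-range KDE, diel step-length bootstrap, selection ratios."""

import numpy as np
import pandas as pd
import pytest

from bearmove import dielsel
from bearmove.landscape import make_landscape


@pytest.fixture(scope="module")
def hr_land():
    return make_landscape(shape=(120, 120), seed=6)


def _fix_cloud(n, center, spread, seed, land):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "x": rng.normal(center[0], spread, n),
            "y": rng.normal(center[1], spread, n),
        }
    )


class TestHomeRange:
    def test_isopleth_mass_just_above_level(self, hr_land):
        fixes = _fix_cloud(500, (1800, 1800), 300, 1, hr_land)
        hr = dielsel.estimate_kde_home_range(fixes, hr_land, "b1")
        mass = hr.density[hr.isopleth_mask].sum()
        assert 0.95 <= mass <= 0.96

    def test_ring_of_fixes_centroid_at_center(self, hr_land):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        fixes = pd.DataFrame(
            {"x": 1800 + 400 * np.cos(theta), "y": 1800 + 400 * np.sin(theta)}
        )
        hr = dielsel.estimate_kde_home_range(fixes, hr_land, "b1")
        assert hr.centroid[0] == pytest.approx(1800, abs=hr_land.res)
        assert hr.centroid[1] == pytest.approx(1800, abs=hr_land.res)

    def test_two_clusters_union_proportions(self, hr_land):
        a = _fix_cloud(300, (1200, 1200), 150, 2, hr_land)
        b = _fix_cloud(300, (2600, 2600), 150, 3, hr_land)
        hr = dielsel.estimate_kde_home_range(pd.concat([a, b]), hr_land, "b1")
        assert 0.95 <= hr.density[hr.isopleth_mask].sum() <= 0.97
        for p in hr.availability.values():
            assert 0.0 <= p <= 1.0

    def test_identical_fixes_rejected(self, hr_land):
        fixes = pd.DataFrame({"x": [1800.0] * 40, "y": [1800.0] * 40})
        with pytest.raises(ValueError):
            dielsel.estimate_kde_home_range(fixes, hr_land)

    def test_too_few_fixes_rejected(self, hr_land):
        with pytest.raises(ValueError):
            dielsel.estimate_kde_home_range(_fix_cloud(10, (1800, 1800), 100, 0, hr_land), hr_land)


def _steps(n, bear="b1", length=200.0, start="2016-07-01", seed=0, land=None, inside=None):
    rng = np.random.default_rng(seed)
    times = pd.date_range(start, periods=n, freq="45min", tz="UTC")
    if inside is not None:
        rows, cols = np.nonzero(inside)
        pick = rng.integers(0, rows.size, n)
        x0, y0 = land.rc_to_xy(rows[pick], cols[pick])
    else:
        x0 = rng.uniform(500, 3000, n)
        y0 = rng.uniform(500, 3000, n)
    h = rng.uniform(-np.pi, np.pi, n)
    return pd.DataFrame(
        {
            "bear_id": bear,
            "start_time": times,
            "x0": x0,
            "y0": y0,
            "x1": x0 + length * np.cos(h),
            "y1": y0 + length * np.sin(h),
            "length": length,
            "season": "summer",
        }
    )


class TestStepLengthBootstrap:
    def test_equal_lengths_zero_width_ci(self):
        steps = pd.concat([_steps(64, bear=b, length=200.0) for b in ("b1", "b2", "b3")])
        out = dielsel.bootstrap_step_lengths(steps, n_boot=200, seed=0)
        assert np.allclose(out["mean_length"], 200.0)
        assert np.allclose(out["ci_low"], 200.0)
        assert np.allclose(out["ci_high"], 200.0)

    def test_fixed_seed_reproducible(self):
        steps = pd.concat([_steps(64, bear=b, seed=i) for i, b in enumerate(("b1", "b2", "b3"))])
        steps["length"] = np.random.default_rng(5).gamma(2, 100, len(steps))
        a = dielsel.bootstrap_step_lengths(steps, n_boot=300, seed=4)
        b = dielsel.bootstrap_step_lengths(steps, n_boot=300, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_mean_tracks_point_estimate(self):
        rng = np.random.default_rng(3)
        steps = pd.concat([_steps(960, bear=f"b{i}", seed=i) for i in range(6)])
        steps["length"] = rng.gamma(2.0, 150.0, len(steps))
        out = dielsel.bootstrap_step_lengths(steps, n_boot=2000, seed=1)
        # the mean of bootstrap means is within 1% of the point estimate
        assert np.all(np.abs(out["boot_mean"] - out["mean_length"]) / out["mean_length"] < 0.01)
        assert (out["ci_low"] <= out["mean_length"] + 1e-9).all()
        assert (out["mean_length"] <= out["ci_high"] + 1e-9).all()

    def test_single_bear_bin_flagged(self):
        out = dielsel.bootstrap_step_lengths(_steps(64), n_boot=100, seed=0)
        assert out["ci_flagged"].all()
        assert out["n_bears"].eq(1).all()

    def test_32_bins_cover_day(self):
        steps = _steps(300, seed=2)
        out = dielsel.bootstrap_step_lengths(steps, n_boot=50, seed=0)
        assert out["bin"].between(0, 31).all()


class TestSelectionRatio:
    def test_category_covering_everything_gives_ratio_one(self, hr_land):
        land = make_landscape(shape=(120, 120), seed=1, constant_layers={"everywhere": 1.0})
        land.kinds["everywhere"] = "categorical"
        fixes = _fix_cloud(400, (1800, 1800), 400, 4, land)
        hr = dielsel.estimate_kde_home_range(fixes, land, "b1", "summer", categories={"everywhere": ("everywhere",)})
        steps = _steps(100, seed=5)
        out = dielsel.selection_ratio_by_bin(
            steps, {("b1", "summer"): hr}, land, categories={"everywhere": ("everywhere",)}, n_boot=50
        )
        assert np.allclose(out["mean_ratio"], 1.0)

    def test_half_in_category_quarter_available_gives_two(self):
        """A step half inside agriculture against availability 0.25 yields 2.0."""
        land = make_landscape(shape=(120, 120), seed=1, constant_layers={"band": 0.0})
        arr = np.zeros(land.shape)
        arr[:, 60:] = 1.0  # eastern half is the category
        land.layers["band"] = arr
        land.kinds["band"] = "categorical"
        hr = dielsel.HomeRange(
            bear_id="b1", season="summer", density=np.ones(land.shape) / arr.size,
            isopleth_mask=np.ones(land.shape, bool), centroid=(1800, 1800),
            availability={"band": 0.25}, housing_density=0.0,
        )
        boundary_x = land.x0 + 60 * land.res
        steps = pd.DataFrame(
            {
                "bear_id": "b1",
                "start_time": [pd.Timestamp("2016-07-01 12:00", tz="UTC")],
                "x0": boundary_x - 300.0, "y0": 1800.0,
                "x1": boundary_x + 300.0, "y1": 1800.0,
                "length": 600.0, "season": "summer",
            }
        )
        out = dielsel.selection_ratio_by_bin(steps, {("b1", "summer"): hr}, land,
                                             categories={"band": ("band",)}, n_boot=10)
        assert out["mean_ratio"].iloc[0] == pytest.approx(0.5 / 0.25, rel=0.05)

    def test_uniform_use_of_home_range_ratio_near_one(self, hr_land):
        """Steps sampled uniformly within the isopleth give mean ratio ~1."""
        fixes = _fix_cloud(600, (1800, 1800), 400, 7, hr_land)
        hr = dielsel.estimate_kde_home_range(fixes, hr_land, "b1", "summer")
        steps = _steps(2000, seed=8, length=30.0, land=hr_land, inside=hr.isopleth_mask)
        out = dielsel.selection_ratio_by_bin(steps, {("b1", "summer"): hr}, hr_land, n_boot=10)
        pooled = out.groupby("category")["mean_ratio"].mean()
        n = 2000
        for cat, ratio in pooled.items():
            avail = hr.availability[cat]
            if avail <= 0:
                continue
            # binomial sampling error of the used fraction, on the ratio scale
            se = np.sqrt(avail * (1 - avail) / n) / avail
            assert abs(ratio - 1.0) <= max(0.05, 3 * se)

    def test_ratios_scale_free_in_step_length(self, hr_land):
        fixes = _fix_cloud(500, (1800, 1800), 400, 9, hr_land)
        hr = dielsel.estimate_kde_home_range(fixes, hr_land, "b1", "summer")
        steps = _steps(300, seed=10)
        doubled = steps.copy()
        doubled["x1"] = doubled["x0"] + 2 * (doubled["x1"] - doubled["x0"])
        doubled["y1"] = doubled["y0"] + 2 * (doubled["y1"] - doubled["y0"])
        a = dielsel.selection_ratio_by_bin(steps, {("b1", "summer"): hr}, hr_land, n_boot=10, seed=0)
        b = dielsel.selection_ratio_by_bin(doubled, {("b1", "summer"): hr}, hr_land, n_boot=10, seed=0)
        # doubling lengths changes sampled paths, but ratios stay close
        merged = a.merge(b, on=["season", "bin", "category"], suffixes=("_a", "_b"))
        assert np.corrcoef(merged["mean_ratio_a"], merged["mean_ratio_b"])[0, 1] > 0.8

    def test_zero_availability_excluded_with_warning(self, hr_land):
        fixes = _fix_cloud(400, (1800, 1800), 300, 11, hr_land)
        hr = dielsel.estimate_kde_home_range(fixes, hr_land, "b1", "summer")
        hr.availability["forest"] = 0.0
        steps = _steps(50, seed=12)
        with pytest.warns(UserWarning):
            out = dielsel.selection_ratio_by_bin(steps, {("b1", "summer"): hr}, hr_land, n_boot=10)
        assert not (out["category"] == "forest").any()
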