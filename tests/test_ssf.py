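"""Step-selection machinery: extraction oracles, conditional logit,
scale selection, pruning, stepwise building."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from bearmove import simulate, ssf
from bearmove.landscape import LandscapeStack, make_landscape


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def brute_force_buffer_mean(land, step, var, buffer_m=30.0):
    """Oracle: loop over every cell, keep centers within the shapely buffer."""
    seg = LineString([(step["x0"], step["y0"]), (step["x1"], step["y1"])])
    vals = []
    nr, nc = land.shape
    for r in range(nr):
        for c in range(nc):
            x, y = land.rc_to_xy(r, c)
            if seg.distance(Point(x, y)) <= buffer_m:
                vals.append(land.layers[var][r, c])
    return np.mean(vals)


def brute_force_kernel_mean(land, cx, cy, var, sigma):
    """Oracle: explicit double loop over the 3-sigma square window."""
    r0, c0 = land.xy_to_rc(cx, cy)
    R = int(math.floor(3.0 * sigma / land.res))
    nr, nc = land.shape
    num = den = 0.0
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < nr and 0 <= c < nc:
                w = math.exp(-((dr * land.res) ** 2 + (dc * land.res) ** 2) / (2 * sigma**2))
                num += w * land.layers[var][r, c]
                den += w
    return num / den


@pytest.fixture(scope="module")
def toy_land():
    return make_landscape(shape=(64, 64), seed=4)


class TestExtractUsed:
    def test_matches_cell_enumeration_oracle(self, toy_land):
        steps = pd.DataFrame(
            {"x0": [400.0, 900.0], "y0": [500.0, 300.0], "x1": [700.0, 900.0], "y1": [650.0, 800.0]}
        )
        out = ssf.extract_used(steps, toy_land, ["deciduous_forest", "slope"])
        for i in steps.index:
            for var in ("deciduous_forest", "slope"):
                oracle = brute_force_buffer_mean(toy_land, steps.loc[i], var)
                assert out.loc[i, var] == pytest.approx(oracle, abs=1e-9)

    def test_constant_layer_returns_constant(self):
        land = make_landscape(shape=(64, 64), seed=0, constant_layers={"flat": 7.5})
        steps = pd.DataFrame({"x0": [500.0], "y0": [500.0], "x1": [800.0], "y1": [700.0]})
        out = ssf.extract_used(steps, land, ["flat"])
        assert out["flat"].iloc[0] == pytest.approx(7.5)

    def test_step_inside_wide_patch_has_proportion_one(self):
        land = make_landscape(shape=(64, 64), seed=0, constant_layers={"patch": 0.0})
        arr = np.zeros(land.shape)
        arr[20:40, 20:40] = 1.0  # 600 m square patch
        land.layers["patch"] = arr
        land.kinds["patch"] = "categorical"
        x0, y0 = land.rc_to_xy(30, 25)
        x1, y1 = land.rc_to_xy(30, 34)
        steps = pd.DataFrame({"x0": [x0], "y0": [y0], "x1": [x1], "y1": [y1]})
        out = ssf.extract_used(steps, land, ["patch"])
        assert out["patch"].iloc[0] == pytest.approx(1.0)

    def test_off_raster_step_dropped_and_counted(self, toy_land):
        steps = pd.DataFrame({"x0": [1e6], "y0": [1e6], "x1": [1e6 + 10], "y1": [1e6]})
        out = ssf.extract_used(steps, toy_land, ["slope"])
        assert out.empty
        assert out.attrs["n_dropped"] == 1


class TestExtractAvailable:
    def test_matches_brute_force_oracle(self, toy_land):
        steps = pd.DataFrame({"x0": [700.0], "y0": [600.0], "x1": [760.0], "y1": [660.0]})
        sigma = toy_land.res  # one cell
        out = ssf.extract_available(steps, toy_land, sigma, ["deciduous_forest", "slope"])
        cx, cy = 730.0, 630.0
        for var in ("deciduous_forest", "slope"):
            oracle = brute_force_kernel_mean(toy_land, cx, cy, var, sigma)
            assert out[var].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_constant_layer_any_sigma(self):
        land = make_landscape(shape=(64, 64), seed=0, constant_layers={"flat": 3.25})
        steps = pd.DataFrame({"x0": [900.0], "y0": [900.0], "x1": [950.0], "y1": [950.0]})
        for sigma in (30.0, 360.0, 900.0):
            out = ssf.extract_available(steps, land, sigma, ["flat"])
            assert out["flat"].iloc[0] == pytest.approx(3.25)

    def test_large_sigma_approaches_global_mean(self, toy_land):
        steps = pd.DataFrame({"x0": [960.0], "y0": [960.0], "x1": [960.0], "y1": [960.0]})
        out = ssf.extract_available(steps, toy_land, 5000.0, ["deciduous_forest"])
        global_mean = toy_land.layers["deciduous_forest"].mean()
        assert out["deciduous_forest"].iloc[0] == pytest.approx(global_mean, abs=0.02)


class TestComputeScales:
    def _straight_track(self, speed=8.0, interval=45, n=200):
        t = pd.date_range("2016-07-01", periods=n, freq=f"{interval}min", tz="UTC")
        x = np.arange(n) * speed * interval
        steps = pd.DataFrame(
            {
                "bear_id": "b1",
                "start_time": t[:-1],
                "end_time": t[1:],
                "x0": x[:-1], "y0": 0.0, "x1": x[1:], "y1": 0.0,
                "duration": float(interval),
            }
        )
        return steps

    def test_constant_speed_straight_line(self):
        """8 m/min for 45 min is a 360 m displacement; longer horizons scale
        linearly on a straight path."""
        steps = self._straight_track()
        scales = ssf.compute_scales(steps, horizons=(45, 90, 180))
        assert scales == pytest.approx([360.0, 720.0, 1440.0])

    def test_reference_scale_override_list(self):
        assert list(ssf.REFERENCE_SCALES) == [360.0, 650.0, 837.0, 1007.0, 1288.0, 1523.0]

    def test_random_walk_displacement_diffusive(self):
        rng = np.random.default_rng(0)
        n = 4000
        t = pd.date_range("2016-07-01", periods=n, freq="45min", tz="UTC")
        xy = np.cumsum(rng.normal(0, 200, size=(n, 2)), axis=0)
        steps = pd.DataFrame(
            {
                "bear_id": "b1",
                "start_time": t[:-1], "end_time": t[1:],
                "x0": xy[:-1, 0], "y0": xy[:-1, 1], "x1": xy[1:, 0], "y1": xy[1:, 1],
                "duration": 45.0,
            }
        )
        s45, s180 = ssf.compute_scales(steps, horizons=(45, 180))
        # sqrt scaling: 4 steps -> 2x mean displacement
        assert s180 / s45 == pytest.approx(2.0, rel=0.1)

    def test_horizon_below_interval_rejected(self):
        with pytest.raises(ValueError):
            ssf.compute_scales(self._straight_track(), horizons=(15,))

    def test_gap_breaks_runs(self):
        steps = self._straight_track(n=50)
        steps = steps.drop(index=25).reset_index(drop=True)
        scales = ssf.compute_scales(steps, horizons=(45, 90))
        assert scales == pytest.approx([360.0, 720.0])


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        used, avail = simulate.simulate_matched_pairs(200, [0.5, -0.5], seed=0)
        u, a, consts = ssf.standardize_pair(used, avail)
        pooled = pd.concat([u, a])
        assert np.allclose(pooled.mean(), 0.0, atol=1e-12)
        assert np.allclose(pooled.std(ddof=0), 1.0, atol=1e-12)

    def test_affine_transform_leaves_standardized_beta_unchanged(self):
        used, avail = simulate.simulate_matched_pairs(2000, [0.8], seed=1)
        u1, a1, _ = ssf.standardize_pair(used, avail)
        fit1 = ssf.fit_conditional_logit((u1 - a1).to_numpy())
        used2, avail2 = used * 13.0 + 5.0, avail * 13.0 + 5.0
        u2, a2, _ = ssf.standardize_pair(used2, avail2)
        fit2 = ssf.fit_conditional_logit((u2 - a2).to_numpy())
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-8)

    def test_constants_roundtrip(self):
        used, avail = simulate.simulate_matched_pairs(100, [0.5], seed=2)
        u, a, consts = ssf.standardize_pair(used, avail)
        m, sd = consts["v1"]
        np.testing.assert_allclose(u["v1"] * sd + m, used["v1"], atol=1e-9)

    def test_zero_spread_covariate_dropped(self):
        used = pd.DataFrame({"v1": [1.0, 2.0], "flat": [3.0, 3.0]})
        avail = pd.DataFrame({"v1": [0.5, 1.5], "flat": [3.0, 3.0]})
        u, a, consts = ssf.standardize_pair(used, avail)
        assert "flat" not in u.columns and "flat" not in consts


class TestConditionalLogit:
    def brute_force_mle(self, d, grid):
        """Oracle: dense grid search of the paired likelihood."""
        best = None
        for b in grid:
            ll = np.sum(-np.logaddexp(0.0, -(d * b)))
            if best is None or ll > best[1]:
                best = (b, ll)
        return best

    def test_three_stratum_toy_matches_grid_search(self):
        d = np.array([0.8, -0.2, 0.5])
        fit = ssf.fit_conditional_logit(d[:, None])
        b_star, ll_star = self.brute_force_mle(d, np.arange(-10, 10, 1e-4))
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(ll_star, abs=1e-4)

    def test_recovery_within_three_se_at_5000_strata(self):
        used, avail = simulate.simulate_matched_pairs(5000, [0.8], seed=3)
        d = (used - avail).to_numpy()
        fit = ssf.fit_conditional_logit(d)
        p = 1.0 / (1.0 + np.exp(-(d @ fit.beta)))
        se = 1.0 / np.sqrt(((d[:, 0] ** 2) * p * (1 - p)).sum())
        assert abs(fit.beta[0] - 0.8) <= 3 * se

    def test_identical_used_available_gives_null(self):
        d = np.zeros((40, 1))
        fit = ssf.fit_conditional_logit(d)
        assert fit.beta[0] == 0.0
        assert fit.log_likelihood == pytest.approx(40 * math.log(0.5))

    def test_label_swap_negates_beta(self):
        used, avail = simulate.simulate_matched_pairs(1000, [0.6, -0.4], seed=4)
        d = (used - avail).to_numpy()
        fit = ssf.fit_conditional_logit(d)
        swapped = ssf.fit_conditional_logit(-d)
        np.testing.assert_allclose(swapped.beta, -fit.beta, atol=1e-8)

    def test_complete_separation_flagged(self):
        d = np.abs(np.random.default_rng(0).normal(1.0, 0.2, (50, 1)))  # all positive
        fit = ssf.fit_conditional_logit(d)
        assert fit.separated
        assert not np.isfinite(fit.beta[0])


class TestAICc:
    def test_closed_form_value(self):
        assert ssf.aicc(-10.0, 2, 20) == pytest.approx(24.70588, abs=1e-5)

    def test_zero_parameters_is_minus_two_loglik(self):
        assert ssf.aicc(-7.0, 0, 50) == pytest.approx(14.0)

    def test_aicc_at_least_aic(self):
        for k, n in [(1, 10), (3, 30), (5, 200)]:
            assert ssf.aicc(-5.0, k, n) >= -2 * (-5.0) + 2 * k - 1e-12

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ssf.aicc(-5.0, 5, 6)


class TestScaleSelection:
    def test_identical_covariates_tie_goes_to_smallest_sigma(self):
        used, avail = simulate.simulate_matched_pairs(100, [0.5], seed=5)
        avail_by_scale = {300.0: avail, 600.0: avail.copy(), 900.0: avail.copy()}
        chosen, _ = ssf.select_characteristic_scales(used, avail_by_scale)
        assert chosen["v1"] == 300.0

    def test_single_scale_returned(self):
        used, avail = simulate.simulate_matched_pairs(100, [0.5], seed=6)
        chosen, _ = ssf.select_characteristic_scales(used, {650.0: avail})
        assert chosen == {"v1": 650.0}

    def test_generating_scale_recovered(self, wide_land):
        """Availability at 650 m generating selection is recovered as the
        characteristic scale (errors-in-variables penalty at other scales)."""
        xmin, ymin, xmax, ymax = wide_land.extent
        margin = 3 * 1523.0
        rng = np.random.default_rng(42)
        cx = rng.uniform(xmin + margin, xmax - margin, 1000)
        cy = rng.uniform(ymin + margin, ymax - margin, 1000)
        pool = pd.DataFrame({"x0": cx, "y0": cy, "x1": cx, "y1": cy})
        avail = {
            s: ssf.extract_available(pool, wide_land, s, ["percent_impervious"])
            for s in ssf.REFERENCE_SCALES
        }
        hits = 0
        for rep in range(10):
            used = simulate.simulate_scale_design(avail, 650.0, "percent_impervious", beta=1.0, seed=rep)
            chosen, _ = ssf.select_characteristic_scales(used, avail)
            hits += chosen.get("percent_impervious") == 650.0
        assert hits >= 8


class TestPruneAndStepwise:
    def test_duplicated_variable_pruned(self):
        used, avail = simulate.simulate_matched_pairs(300, [0.8], seed=7)
        used["copy"] = used["v1"]
        avail["copy"] = avail["v1"]
        kept = ssf.prune_correlated(used, avail, {"v1": 10.0, "copy": 11.0})
        assert kept == ["v1"]

    def test_uncorrelated_set_unchanged(self):
        used, avail = simulate.simulate_matched_pairs(500, [0.5, -0.5, 0.0], seed=8)
        kept = ssf.prune_correlated(used, avail, {"v1": 1.0, "v2": 2.0, "v3": 3.0})
        assert kept == ["v1", "v2", "v3"]

    def test_correlation_exactly_at_threshold_keeps_both(self):
        rng = np.random.default_rng(9)
        n = 2000
        a = rng.normal(size=2 * n)
        b_target = 0.7
        noise = rng.normal(size=2 * n)
        noise -= np.polyfit(a, noise, 1)[0] * a  # orthogonalize
        b = b_target * (a - a.mean()) / a.std(ddof=0) + math.sqrt(1 - b_target**2) * (
            noise - noise.mean()
        ) / noise.std(ddof=0)
        used = pd.DataFrame({"a": a[:n], "b": b[:n]})
        avail = pd.DataFrame({"a": a[n:], "b": b[n:]})
        pooled_r = abs(pd.concat([used, avail]).corr().loc["a", "b"])
        assert pooled_r == pytest.approx(0.7, abs=1e-6)
        # the rule is strict: a pair at exactly the threshold is kept
        kept = ssf.prune_correlated(used, avail, {"a": 1.0, "b": 2.0}, threshold=pooled_r)
        assert set(kept) == {"a", "b"}
        kept = ssf.prune_correlated(used, avail, {"a": 1.0, "b": 2.0}, threshold=pooled_r - 1e-9)
        assert kept == ["a"]

    def test_stepwise_keeps_true_drops_noise(self):
        beta = [1.0, -1.0, 0.0, 0.0, 0.0]
        used, avail = simulate.simulate_matched_pairs(2000, beta, seed=10)
        u, a, _ = ssf.standardize_pair(used, avail)
        sel, fit, crit = ssf.stepwise_select(u, a, list(u.columns))
        assert {"v1", "v2"} <= set(sel)

    def test_single_weak_candidate_vs_null(self):
        used, avail = simulate.simulate_matched_pairs(200, [0.0], seed=11)
        u, a, _ = ssf.standardize_pair(used, avail)
        sel, fit, crit = ssf.stepwise_select(u, a, ["v1"])
        assert sel == ()  # pure noise does not beat the null by AICc
        assert crit == pytest.approx(-2 * 200 * math.log(0.5))

    def test_stepwise_deterministic(self):
        used, avail = simulate.simulate_matched_pairs(500, [0.7, 0.0, -0.3], seed=12)
        u, a, _ = ssf.standardize_pair(used, avail)
        r1 = ssf.stepwise_select(u, a, list(u.columns))
        r2 = ssf.stepwise_select(u, a, list(u.columns))
        assert r1[0] == r2[0] and r1[2] == r2[2]


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(5, 40), st.integers(1, 3)),
            elements=st.floats(-3, 3, allow_nan=False),
        )
    )
    def test_label_swap_symmetry_property(d):
        """Swapping used/available labels negates the fitted coefficients
        (or keeps the separation flag) for arbitrary difference designs."""
        fit = ssf.fit_conditional_logit(d)
        swapped = ssf.fit_conditional_logit(-d)
        assert fit.separated == swapped.separated
        if not fit.separated and fit.converged and swapped.converged:
            np.testing.assert_allclose(swapped.beta, -fit.beta, atol=1e-6)

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_full_ssf_final_model_has_no_high_correlations(study, tracks):
    from bearmove import preprocess

    steps = preprocess.build_steps(tracks)
    one = steps[steps["bear_id"] == "bear01"]
    land = study.landscape
    model = ssf.fit_ssf(one, land, [200.0, 500.0], bear_id="bear01")
    assert model is not None
    if len(model.variables) >= 2:
        used = ssf.extract_used(one, land, list(model.variables))
        avail = pd.DataFrame(
            {
                v: ssf.extract_available(one, land, model.scales[v], [v])[v]
                for v in model.variables
            }
        )
        pooled = pd.concat([used.loc[avail.index], avail])
        corr = pooled.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7 + 1e-9
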