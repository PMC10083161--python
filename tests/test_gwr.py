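"""The estimator core: kernel, bandwidth, local WLS, full fits and CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwtrend import (
    SyntheticConfig, adaptive_bandwidth, assign_panels, bisquare_weight,
    center_by_station, cv_score, fit_gwr, generate_network, local_wls,
    select_bandwidth, simulate_observations, TrendSurface, ScalarField,
)
from gwtrend.errors import ConfigurationError, DegenerateDataError, StateError, ValidationError
from gwtrend.gwr import _Workspace
from gwtrend.table import ObservationTable, ScaleState


# ---------------------------------------------------------------------- kernel

class TestAdaptiveBandwidth:
    def test_kth_distance(self):
        obs = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        assert adaptive_bandwidth([0.0, 0.0], obs, 3) == 2.0

    def test_k_equals_n_gives_max(self):
        obs = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        assert adaptive_bandwidth([0.0, 0.0], obs, 4) == 3.0

    def test_colocated_observations_yield_zero(self):
        obs = np.zeros((3, 2))
        assert adaptive_bandwidth([0.0, 0.0], obs, 3) == 0.0  # degenerate, flagged downstream

    def test_k_out_of_range(self):
        obs = np.zeros((5, 2))
        with pytest.raises(ConfigurationError):
            adaptive_bandwidth([0.0, 0.0], obs, 2)
        with pytest.raises(ConfigurationError):
            adaptive_bandwidth([0.0, 0.0], obs, 6)


class TestBisquareWeight:
    @pytest.mark.parametrize("d,b,expected", [
        (0.0, 1.0, 1.0),
        (1.0, 1.0, 0.0),       # strict at the boundary
        (0.5, 1.0, 0.5625),    # (1 - 0.25)^2
        (2.0, 1.0, 0.0),
    ])
    def test_closed_form(self, d, b, expected):
        assert bisquare_weight(d, b) == pytest.approx(expected, abs=1e-15)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValidationError):
            bisquare_weight(1.0, 0.0)

    def test_shape_on_grid(self):
        d = np.linspace(0, 2, 201)
        w = bisquare_weight(d, 1.0)
        assert np.all((w >= 0) & (w <= 1))
        assert np.all(np.diff(w) <= 1e-15)          # nonincreasing
        assert np.all(w[d >= 1.0] == 0.0)
        assert np.max(np.abs(np.diff(w))) < 0.05    # continuous on this grid


# ------------------------------------------------------------------- local WLS

class TestLocalWLS:
    def test_two_point_interpolation(self):
        fit = local_wls([0.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)
        assert fit.slope == pytest.approx(1.0, abs=1e-14)
        assert fit.local_r2 == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_equal_ols(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 10, 25)
        y = 0.3 * t + rng.normal(0, 1, 25)
        fit = local_wls(t, y, np.ones(25))
        slope_ols, icpt_ols = np.polyfit(t, y, 1)
        assert fit.slope == pytest.approx(slope_ols, abs=1e-10)
        assert fit.intercept == pytest.approx(icpt_ols, abs=1e-10)

    def test_zero_weight_observation_inert(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 10, 10)
        y = rng.normal(0, 1, 10)
        w = rng.uniform(0.1, 1.0, 10)
        base = local_wls(t, y, w)
        t2 = np.append(t, 99.0)
        y2 = np.append(y, 1e6)
        w2 = np.append(w, 0.0)
        spiked = local_wls(t2, y2, w2)
        assert spiked.slope == pytest.approx(base.slope, abs=1e-12)
        assert spiked.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_matches_bruteforce_grid_minimizer(self):
        # independent check: refine a coarse (a, b) grid around the optimum
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 5, 12)
        y = 1.0 + 0.4 * t + rng.normal(0, 0.3, 12)
        w = rng.uniform(0.2, 1.0, 12)
        fit = local_wls(t, y, w)

        def loss(a, b):
            return float(w @ (y - a - b * t) ** 2)

        a0, b0, half = 1.0, 0.4, 2.0
        for _ in range(12):
            a_grid = np.linspace(a0 - half, a0 + half, 21)
            b_grid = np.linspace(b0 - half, b0 + half, 21)
            losses = [[loss(a, b) for b in b_grid] for a in a_grid]
            ia, ib = np.unravel_index(np.argmin(losses), (21, 21))
            a0, b0 = a_grid[ia], b_grid[ib]
            half /= 5.0
        assert fit.intercept == pytest.approx(a0, abs=1e-5)
        assert fit.slope == pytest.approx(b0, abs=1e-5)

    def test_singular_designs_rejected(self):
        with pytest.raises(DegenerateDataError):
            local_wls([1.0, 1.0, 2.0], [0.0, 1.0, 2.0], [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateDataError):
            local_wls([1.0, 2.0], [0.0, 1.0], [1.0, 0.0])


# -------------------------------------------------------------------- fit_gwr

def _constant_slope_study(n_panels, seed=5, slope=0.01, n_stations=60):
    config = SyntheticConfig(
        n_stations=n_stations, n_panels=n_panels, noise_sd_log10=0.0, seed=seed
    )
    surface = TrendSurface(ScalarField(constant=1.0), ScalarField(constant=slope))
    stations = generate_network(config)
    table = simulate_observations(assign_panels(stations, config), stations, surface, config)
    return table, config


class TestFitGWR:
    def test_noise_free_single_panel_centered_exact(self):
        table, _ = _constant_slope_study(n_panels=1)
        res = fit_gwr(center_by_station(table), k=30)
        np.testing.assert_allclose(res.fits["slope"], 0.01, atol=1e-10)
        np.testing.assert_allclose(res.fits["local_r2"], 1.0, atol=1e-10)

    def test_noise_free_rotating_panels_uncentered_exact(self):
        # constant intercept field: the uncentered model is exactly linear
        table, _ = _constant_slope_study(n_panels=6)
        res = fit_gwr(table, k=30, allow_uncentered=True)
        np.testing.assert_allclose(res.fits["slope"], 0.01, atol=1e-10)

    def test_uniform_kernel_k_n_equals_global_ols(self, tiny_centered_table):
        res = fit_gwr(tiny_centered_table, k=tiny_centered_table.n_obs, kernel="uniform")
        ws = _Workspace(tiny_centered_table)
        slope_ols, icpt_ols = np.polyfit(ws.t, ws.y, 1)
        np.testing.assert_allclose(res.fits["slope"], slope_ols, atol=1e-10)
        np.testing.assert_allclose(res.fits["intercept"], icpt_ols, atol=1e-10)

    def test_requires_centered_scale(self, tiny_log10_table):
        with pytest.raises(StateError):
            fit_gwr(tiny_log10_table, k=10)
        fit_gwr(tiny_log10_table, k=10, allow_uncentered=True)  # flag opens the door

    def test_rejects_single_observation_stations(self, tiny_log10_table):
        df = tiny_log10_table.df.iloc[:-2]  # last station keeps one row
        crippled = ObservationTable(df, ScaleState.LOG10_CENTERED, validate=False)
        with pytest.raises(ValidationError):
            fit_gwr(crippled, k=10)

    def test_k_below_three_rejected(self, tiny_centered_table):
        with pytest.raises(ConfigurationError):
            fit_gwr(tiny_centered_table, k=2)

    def test_result_bookkeeping(self, tiny_centered_table):
        res = fit_gwr(tiny_centered_table, k=12)
        assert len(res.fits) == tiny_centered_table.n_stations
        assert res.effective_df > 0
        assert res.rss >= 0
        valid = res.fits[res.fits["valid"]]
        assert ((valid["p_slope"] >= 0) & (valid["p_slope"] <= 1)).all()
        assert (valid["n_positive_weight"] <= 12).all()  # strict kernel: <= k


class TestExactInvariances:
    def test_per_station_constant_shift_absorbed_by_centering(self, tiny_log10_table):
        base = fit_gwr(center_by_station(tiny_log10_table), k=12)
        rng = np.random.default_rng(9)
        shifts = {sid: rng.uniform(-1, 1) for sid in tiny_log10_table.station_ids}
        shifted_vals = tiny_log10_table.df["value"].to_numpy() + \
            tiny_log10_table.df["station_id"].map(shifts).to_numpy()
        shifted = tiny_log10_table.with_values(shifted_vals, ScaleState.LOG10)
        res = fit_gwr(center_by_station(shifted), k=12)
        np.testing.assert_allclose(res.fits["slope"], base.fits["slope"], atol=1e-12)

    def test_year_translation_leaves_slopes_unchanged(self, tiny_centered_table):
        base = fit_gwr(tiny_centered_table, k=12)
        df = tiny_centered_table.df.copy()
        df["year"] = df["year"] + 1000
        moved = ObservationTable(df, ScaleState.LOG10_CENTERED, validate=False)
        res = fit_gwr(moved, k=12)
        np.testing.assert_allclose(res.fits["slope"], base.fits["slope"], atol=1e-12)


# ------------------------------------------------------------------- cv_score

class TestCVScore:
    def test_matches_bruteforce_refits(self, tiny_centered_table):
        # 30-observation instance, leave each observation out and refit
        table = tiny_centered_table
        k = 12
        sc = cv_score(table, k)
        ws = _Workspace(table)
        b = ws.bandwidths(k)
        u = ws.D / b[:, None]
        W = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        total, excluded = 0.0, 0
        X = np.column_stack([np.ones(ws.n), ws.t])
        for j in range(ws.n):
            w = W[ws.owner[j]].copy()
            w[j] = 0.0
            pos = w > 0
            if pos.sum() < 2 or np.ptp(ws.t[pos]) == 0:
                excluded += 1
                continue
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], ws.y * sw, rcond=None)
            total += (ws.y[j] - (beta[0] + beta[1] * ws.t[j])) ** 2
        assert sc.score == pytest.approx(total, abs=1e-10)
        assert sc.n_excluded == excluded

    def test_uniform_kernel_k_n_matches_leverage_formula(self, tiny_centered_table):
        # classic closed form: LOO residual = residual / (1 - h_jj) for OLS
        table = tiny_centered_table
        sc = cv_score(table, table.n_obs, kernel="uniform")
        ws = _Workspace(table)
        X = np.column_stack([np.ones(ws.n), ws.t])
        beta, *_ = np.linalg.lstsq(X, ws.y, rcond=None)
        resid = ws.y - X @ beta
        h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
        assert sc.score == pytest.approx(float(((resid / (1 - h)) ** 2).sum()), rel=1e-10)

    def test_zero_noise_constant_slope_scores_zero(self):
        table, _ = _constant_slope_study(n_panels=1, n_stations=40)
        centered = center_by_station(table)
        for k in (10, 25, 40):
            assert cv_score(centered, k).score == pytest.approx(0.0, abs=1e-16)

    def test_leave_station_out_mode_runs(self, tiny_centered_table):
        a = cv_score(tiny_centered_table, 12, loo="obs")
        b = cv_score(tiny_centered_table, 12, loo="station")
        assert b.score >= 0 and a.score != b.score


class TestSelectBandwidth:
    def test_flat_spatial_structure_prefers_largest_k(self):
        # one global trend + i.i.d. noise: the smoothest candidate wins
        config = SyntheticConfig(n_stations=80, noise_sd_log10=0.1, seed=7)
        surface = TrendSurface(ScalarField(constant=1.0), ScalarField(constant=0.01))
        stations = generate_network(config)
        table = simulate_observations(assign_panels(stations, config), stations, surface, config)
        sel = select_bandwidth(center_by_station(table), [10, 50, 180])
        assert sel.selected_k == 180

    def test_single_element_grid(self, tiny_centered_table):
        sel = select_bandwidth(tiny_centered_table, [15])
        assert sel.selected_k == 15
        assert len(sel.cv_scores) == 1

    def test_scores_retained_for_reporting(self, tiny_centered_table):
        sel = select_bandwidth(tiny_centered_table, [10, 15, 20])
        assert len(sel.cv_scores) == 3
        assert sel.selected_k == sel.k_grid[int(np.argmin(sel.cv_scores))]


def test_slope_field_smoothness_nondecreasing_in_k(two_region_small):
    """Larger neighbourhoods smooth the slope field: its spatial variance
    must not increase with k (up to sampling jitter)."""
    centered, *_ = two_region_small
    variances = []
    for k in (30, 80, 200, 400):
        res = fit_gwr(centered, k)
        variances.append(float(res.fits["slope"].var()))
    v = np.array(variances)
    assert np.all(v[1:] <= v[:-1] * 1.05)
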