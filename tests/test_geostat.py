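"""Variogram estimation and fitting, kriging constraints, and sequential
Gaussian simulation."""

import numpy as np
import pandas as pd
import pytest

from lidarval.geostat import (Kriging, VariogramModel, back_transform_sqrt,
                              empirical_semivariogram, fit_best_variogram,
                              fit_variogram, ordinary_kriging,
                              sequential_gaussian_simulation, transform_sqrt)


class TestTransform:
    def test_forward_back_examples(self):
        assert transform_sqrt([25.0])[0] == 5.0
        assert back_transform_sqrt([5.0])[0] == 25.0
        assert transform_sqrt([0.0])[0] == 0.0

    def test_round_trip_identity(self, rng):
        v = rng.uniform(0, 60, 1000)
        assert np.max(np.abs(back_transform_sqrt(transform_sqrt(v)) - v)) \
            < 1e-10

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_sqrt([-1.0])


class TestEmpiricalVariogram:
    def test_two_point_definition(self):
        emp = empirical_semivariogram([0.0, 3.0], [0.0, 4.0], [1.0, 4.0],
                                      lag_width=10.0, max_lag=10.0)
        nonempty = emp[emp["n_pairs"] > 0]
        assert len(nonempty) == 1
        assert nonempty["gamma"].iloc[0] == pytest.approx(4.5)  # d^2 / 2

    def test_constant_field_zero(self, rng):
        emp = empirical_semivariogram(rng.uniform(0, 100, 80),
                                      rng.uniform(0, 100, 80),
                                      np.full(80, 3.0))
        assert np.nanmax(emp["gamma"].to_numpy()) == 0.0

    def test_white_noise_flat_at_sigma2(self, rng):
        """For spatially independent values, gamma(h) ~ sigma^2 at every
        lag within 3 standard errors; the standard error per bin comes
        from a Monte-Carlo replication oracle."""
        n = 400
        sigma2 = 4.0
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        reps = np.array([
            empirical_semivariogram(x, y, rng.normal(0, 2.0, n),
                                    lag_width=100.0)["gamma"].to_numpy()
            for _ in range(30)])
        se = reps.std(axis=0, ddof=1)
        emp = empirical_semivariogram(x, y, rng.normal(0, 2.0, n),
                                      lag_width=100.0)
        ok = emp["n_pairs"].to_numpy() > 100
        dev = np.abs(emp["gamma"].to_numpy()[ok] - sigma2)
        assert np.all(dev < 3 * se[ok])


class TestFit:
    def test_noise_free_exponential_recovery(self):
        """Refit of a noise-free exponential curve (nugget 0.147, sill
        0.60, range 369 m) recovers the parameters within 1%."""
        truth = VariogramModel("exponential", 0.147, 0.60, 369.0)
        h = np.linspace(10, 1100, 36)
        emp = pd.DataFrame({"lag": h, "gamma": truth.gamma(h),
                            "n_pairs": np.full(36, 50)})
        fit = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.147, rel=0.01)
        assert fit.sill == pytest.approx(0.60, rel=0.01)
        assert fit.range_ == pytest.approx(369.0, rel=0.01)
        assert fit.rss < 1e-10

    def test_pure_nugget(self):
        h = np.linspace(5, 400, 20)
        emp = pd.DataFrame({"lag": h, "gamma": np.full(20, 0.8),
                            "n_pairs": np.full(20, 40)})
        fit = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.8, abs=0.01)
        assert fit.sill - fit.nugget == pytest.approx(0.0, abs=0.01)

    def test_too_few_bins_rejected(self):
        emp = pd.DataFrame({"lag": [1.0, 2.0], "gamma": [0.5, 0.6],
                            "n_pairs": [5, 5]})
        with pytest.raises(ValueError, match="4 nonempty"):
            fit_variogram(emp)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            VariogramModel("cubic", 0.0, 1.0, 10.0)

    def test_nugget_to_sill_percent(self):
        m = VariogramModel("exponential", 0.147, 0.60, 369.0)
        assert m.nugget_to_sill_pct == pytest.approx(24.5, abs=0.1)


def _gp_samples(seed, n=150, dom=800.0, range_=100.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, dom, n)
    y = rng.uniform(0, dom, n)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    cov = np.exp(-d / range_)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return x, y, chol @ rng.standard_normal(n)


@pytest.fixture(scope="module")
def model():
    return VariogramModel("exponential", 0.0, 1.0, 100.0)


class TestKriging:
    def test_single_distinct_value_constant_field(self, model):
        krig = Kriging(model).fit([0.0, 10.0], [0.0, 0.0], [7.0, 7.0])
        est, _ = krig.predict([55.0, -20.0], [3.0, 40.0])
        np.testing.assert_allclose(est, 7.0, rtol=1e-9)

    def test_exact_interpolation_at_sample(self, model):
        x, y, v = _gp_samples(1, n=60)
        krig = Kriging(model).fit(x, y, v)
        est, var = krig.predict(x[:10], y[:10])
        np.testing.assert_allclose(est, krig.v_[
            [np.argmin(np.hypot(krig.x_ - a, krig.y_ - b))
             for a, b in zip(x[:10], y[:10])]], atol=1e-8)
        assert np.all(var[:10] < 1e-8)

    def test_weights_sum_to_one_everywhere(self, model, rng):
        x, y, v = _gp_samples(2, n=80)
        krig = Kriging(model).fit(x, y, v)
        for _ in range(100):
            w = krig.weights(float(rng.uniform(0, 800)),
                             float(rng.uniform(0, 800)))
            assert abs(w.sum() - 1.0) < 1e-8

    def test_variance_nonnegative(self, model):
        x, y, v = _gp_samples(3, n=60)
        est, var = ordinary_kriging(x, y, v, model,
                                    np.linspace(0, 800, 20),
                                    np.linspace(0, 800, 20))
        assert var.min() >= 0.0

    def test_duplicates_deduplicated_by_mean(self, model):
        krig = Kriging(model).fit([0.0, 0.0, 50.0], [0.0, 0.0, 0.0],
                                  [2.0, 4.0, 10.0])
        est, _ = krig.predict([0.0], [0.0])
        assert est[0] == pytest.approx(3.0, abs=1e-8)


@pytest.fixture(scope="module")
def setup():
    x, y, v = _gp_samples(5, n=40, dom=600.0)
    v = np.abs(v) * 10.0  # height-like, nonnegative
    model = VariogramModel("exponential", 0.0, 1.0, 100.0)
    grid = np.arange(15.0, 600.0, 30.0)
    return x, y, v, model, grid


class TestSGS:
    def test_conditioning_honored_every_realization(self, setup):
        x, y, v, model, grid = setup
        ens = sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                             n_realizations=5, seed=4)
        # nearest grid node of each sample must carry the (cell-averaged)
        # conditioning value in every realization
        tv = np.sqrt(v)
        ci = np.argmin(np.abs(grid[None, :] - x[:, None]), axis=1)
        cj = np.argmin(np.abs(grid[None, :] - y[:, None]), axis=1)
        cells = pd.DataFrame({"cell": cj * len(grid) + ci, "tv": tv})
        expected = cells.groupby("cell")["tv"].mean()
        for r in range(5):
            flat = ens.realizations[r].ravel()
            for cell, val in expected.items():
                assert flat[cell] == pytest.approx(val ** 2, rel=1e-9)

    def test_seed_determinism(self, setup):
        x, y, v, model, grid = setup
        a = sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                           n_realizations=3, seed=11)
        b = sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                           n_realizations=3, seed=11)
        c = sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                           n_realizations=3, seed=12)
        np.testing.assert_array_equal(a.realizations, b.realizations)
        assert not np.array_equal(a.realizations, c.realizations)

    def test_far_field_mean_near_global_mean(self):
        """Ensemble mean far from all data approaches the global mean of
        the transformed samples (stationarity of simple kriging)."""
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, 30)
        y = rng.uniform(0, 100, 30)
        v = rng.uniform(5, 30, 30)
        model = VariogramModel("exponential", 0.0, 1.0, 50.0)
        grid = np.arange(10.0, 1200.0, 60.0)
        ens = sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                             n_realizations=50, seed=2)
        far = ens.realizations[:, -1, -1]  # ~1100 m from all data
        tmean = np.sqrt(v).mean()
        observed = np.sqrt(np.maximum(far, 0.0)).mean()
        se = np.sqrt(model.sill / 50)
        assert abs(observed - tmean) < 3 * se

    def test_uncertainty_grows_with_distance(self, setup):
        """Ensemble sd along a transect away from the data rises with
        distance (rank correlation > 0.8)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 120, 25)
        y = rng.uniform(0, 600, 25)
        v = rng.uniform(5, 25, 25)
        model = VariogramModel("exponential", 0.0, 1.0, 80.0)
        # transect spans the growth region; past ~3 ranges from the data
        # the sd saturates at the sill and the trend flattens
        gx = np.arange(15.0, 420.0, 30.0)
        gy = np.arange(15.0, 600.0, 30.0)
        ens = sequential_gaussian_simulation(x, y, v, model, gx, gy,
                                             n_realizations=40, seed=6)
        transect = ens.sd.mean(axis=0)  # mean sd per x-column
        rho = spearmanr(gx, transect).statistic
        assert rho > 0.8

    def test_bad_realization_count_rejected(self, setup):
        x, y, v, model, grid = setup
        with pytest.raises(ValueError):
            sequential_gaussian_simulation(x, y, v, model, grid, grid,
                                           n_realizations=0)


class TestModelSelection:
    def test_exponential_field_fit_sane(self):
        """On a single exponential-GP realization the exponential fit's
        range lands within a factor ~2 of truth (coarse sanity; the full
        25-seed study runs in the acceptance suite)."""
        x, y, v = _gp_samples(0, n=300, dom=1500.0, range_=100.0)
        emp = empirical_semivariogram(x, y, v)
        best, fits = fit_best_variogram(emp)
        fe = [f for f in fits if f.model == "exponential"][0]
        assert 30.0 < fe.range_ < 300.0


def test_mapping_validation_loop_self_consistency():
    """End-to-end mapping loop: footprint RH90 samples from a scene with
    stand-scale canopy structure, variogram fit + SGS in sqrt space,
    hold-out prediction. Self-consistency check: the interpolation
    explains a meaningful share of hold-out variance (R^2 > 0.3) with
    RMSE below the sample standard deviation."""
    from lidarval.accuracy import r_squared, rmse
    from lidarval.extraction import canopy_rh, make_buffer
    from lidarval.scene import SceneConfig, make_scene

    cfg = SceneConfig(seed=77, canopy_height_sd=4.0,
                      canopy_height_field_amplitude=6.0,
                      canopy_height_field_scale=200.0)
    scene = make_scene(cfg, (0, 0, 600, 600))
    rng = np.random.default_rng(5)
    pts = rng.uniform(30, 570, (120, 2))
    vals = []
    for x, y in pts:
        try:
            vals.append(canopy_rh(scene.chm,
                                  make_buffer((x, y), shape="circle"), 90))
        except ValueError:
            vals.append(np.nan)
    vals = np.array(vals)
    ok = np.isfinite(vals)
    pts, vals = pts[ok], vals[ok]
    n = len(vals)
    hold = rng.choice(n, n // 5, replace=False)
    train = np.setdiff1d(np.arange(n), hold)
    emp = empirical_semivariogram(pts[train, 0], pts[train, 1],
                                  transform_sqrt(vals[train]))
    best, _ = fit_best_variogram(emp)
    grid = np.arange(15.0, 600.0, 30.0)
    ens = sequential_gaussian_simulation(pts[train, 0], pts[train, 1],
                                         vals[train], best, grid, grid,
                                         n_realizations=25, seed=2)
    gi = np.clip((pts[hold, 0] // 30).astype(int), 0, len(grid) - 1)
    gj = np.clip((pts[hold, 1] // 30).astype(int), 0, len(grid) - 1)
    pred = ens.mean[gj, gi]
    assert r_squared(vals[hold], pred) > 0.3
    assert rmse(vals[hold], pred) < vals[hold].std(ddof=0) * 1.0
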