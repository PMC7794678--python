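import numpy as np
import pytest
from shapely.geometry import Polygon

from swardmap.fieldmap import (FieldMap, GeoSample, SurveySpec, VariogramModel,
                               empirical_variogram, fit_variogram,
                               gaussian_random_field, idw_map, krige_at_points,
                               krige_map, map_report, ordinary_kriging_weights,
                               simulate_survey, trigger_positions,
                               write_field_map, _serpentine_path)

SQUARE_1HA = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])


def _survey(seed=1, spacing=10.0, noise=0.0, field_kw=None):
    f = gaussian_random_field(**(field_kw or {"range_m": 30.0, "sd": 0.1,
                                              "mean": 0.4, "seed": 3}))
    spec = SurveySpec(SQUARE_1HA, track_spacing_m=spacing)
    return simulate_survey(spec, f, noise_sd=noise, seed=seed), f


class TestSurveyTrigger:
    def test_50m_track_rule_step_through(self):
        """>5 m rule at 1 m steps fires at 0, 6, 12, ..., 48."""
        path = np.stack([np.arange(0.0, 51.0), np.zeros(51)], axis=1)
        fired = trigger_positions(path, 5.0)
        assert fired == list(range(0, 49, 6))
        assert len(fired) == 9

    def test_serpentine_track_count(self):
        spec = SurveySpec(SQUARE_1HA, track_spacing_m=10.0)
        path = _serpentine_path(spec, np.random.default_rng(0))
        assert len(np.unique(np.round(path[:, 0], 6))) >= 10
        xs = {round(x, 6) for x in path[:, 0]}
        # 10 tracks plus intermediate turn points
        assert sum(1 for x in xs if (x - 5.0) % 10.0 == 0) == 10

    def test_samples_inside_boundary(self):
        samples, _ = _survey(spacing=(6.0, 12.0))
        assert all(0 <= s.easting <= 100 and 0 <= s.northing <= 100
                   for s in samples)

    def test_border_pass_adds_edge_samples(self):
        f = gaussian_random_field(seed=1)
        base = simulate_survey(SurveySpec(SQUARE_1HA, track_spacing_m=10.0),
                               f, seed=2)
        with_border = simulate_survey(
            SurveySpec(SQUARE_1HA, track_spacing_m=10.0, border_pass=True),
            f, seed=2)
        assert len(with_border) > len(base)

    def test_degenerate_boundary_rejected(self):
        line = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            SurveySpec(line)

    def test_noise_reproducible_under_seed(self):
        a, _ = _survey(seed=5, noise=0.05)
        b, _ = _survey(seed=5, noise=0.05)
        assert all(x.value == y.value for x, y in zip(a, b))


class TestVariogram:
    def test_constant_field_pure_nugget(self):
        rng = np.random.default_rng(0)
        samples = [GeoSample(e, n, 0.5) for e, n in rng.uniform(0, 100, (60, 2))]
        with pytest.warns(UserWarning, match="constant"):
            vg = fit_variogram(samples)
        assert vg.sill <= 1e-9

    def test_white_noise_has_no_spatial_structure(self):
        """i.i.d. values: semivariance is flat at the variance from the
        shortest lags on (all nugget / vanishing range)."""
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 100, (400, 2))
        z = rng.normal(0, 1, 400)
        samples = [GeoSample(e, n, v) for (e, n), v in zip(xy, z)]
        vg = fit_variogram(samples)
        var = z.var()
        h_small = 1.0
        assert vg(h_small) > 0.6 * var
        assert vg(60.0) < 1.4 * var

    def test_random_field_range_recovery(self):
        """Fitted range within a factor 2 of the generating 30 m range.

        Uses a 4-ha field: a 1-ha window of a 30 m-range process is often
        dominated by a single trend and cannot constrain the sill.
        """
        big = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
        ranges = []
        for seed in range(20):
            f = gaussian_random_field(range_m=30.0, sd=0.1, mean=0.4,
                                      seed=100 + seed)
            samples = simulate_survey(
                SurveySpec(big, track_spacing_m=(6.0, 12.0)), f,
                noise_sd=0.02, seed=seed)
            vg = fit_variogram(samples, family="gaussian")
            ranges.append(vg.range_m)
        ranges = np.asarray(ranges)
        assert (ranges > 15.0).all() and (ranges < 60.0).all()

    def test_too_few_samples_rejected(self):
        samples = [GeoSample(0, 0, 1.0)] * 10
        with pytest.raises(ValueError):
            fit_variogram(samples)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            VariogramModel("spherical", nugget=0.5, sill=0.1, range_m=10)
        with pytest.raises(ValueError):
            VariogramModel("banana", 0.0, 1.0, 10.0)(5.0)

    def test_empirical_variogram_of_linear_trend(self):
        xy = np.array([[float(i), 0.0] for i in range(50)])
        samples = [GeoSample(e, n, e) for e, n in xy]
        centers, gamma, counts = empirical_variogram(samples, n_lags=5)
        ok = counts > 0
        assert (np.diff(gamma[ok]) > 0).all()  # semivariance grows with lag


class TestKriging:
    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 50, (30, 2))
        vg = VariogramModel("spherical", 0.01, 0.2, 25.0)
        for target in rng.uniform(0, 50, (10, 2)):
            w, _ = ordinary_kriging_weights(xy, target, vg)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_exact_at_samples_with_zero_nugget(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 50, (25, 2))
        z = rng.uniform(0, 1, 25)
        samples = [GeoSample(e, n, v) for (e, n), v in zip(xy, z)]
        vg = VariogramModel("spherical", 0.0, 0.1, 30.0)
        pred = krige_at_points(samples, vg, xy)
        assert np.allclose(pred, z, atol=1e-8)

    def test_constant_samples_give_constant_map(self):
        rng = np.random.default_rng(4)
        samples = [GeoSample(e, n, 0.42) for e, n in rng.uniform(5, 95, (40, 2))]
        vg = VariogramModel("spherical", 0.0, 0.1, 30.0)
        fmap = krige_map(samples, vg, SQUARE_1HA)
        assert np.allclose(fmap.values[fmap.mask], 0.42, atol=1e-10)

    def test_five_sample_toy_matches_dense_solve(self):
        """Neighborhood kriging equals a brute-force full-system solve."""
        xy = np.array([[10.0, 10.0], [80.0, 15.0], [50.0, 55.0],
                       [20.0, 85.0], [90.0, 90.0]])
        z = np.array([0.2, 0.5, 0.35, 0.8, 0.6])
        vg = VariogramModel("exponential", 0.02, 0.3, 40.0)
        samples = [GeoSample(e, n, v) for (e, n), v in zip(xy, z)]
        targets = np.array([[33.0, 41.0], [70.0, 20.0], [5.0, 95.0]])
        pred = krige_at_points(samples, vg, targets, k_neighbors=5)
        for t, p in zip(targets, pred):
            # independent dense solve of the ordinary-kriging system
            k = len(z)
            A = np.ones((k + 1, k + 1))
            A[k, k] = 0.0
            for i in range(k):
                for j in range(k):
                    A[i, j] = vg(np.hypot(*(xy[i] - xy[j])))
            b = np.append([vg(np.hypot(*(xy[i] - t))) for i in range(k)], 1.0)
            lam = np.linalg.solve(A, b)[:k]
            assert p == pytest.approx(float(lam @ z), abs=1e-6)

    def test_masked_cells_inside_boundary_only(self):
        samples, _ = _survey(spacing=10.0)
        vg = fit_variogram(samples)
        tri = Polygon([(0, 0), (100, 0), (0, 100)])
        fmap = krige_map(samples, vg, tri)
        ee, nn = fmap.cell_centers()
        from shapely import contains_xy
        assert (contains_xy(tri, ee[fmap.mask], nn[fmap.mask])).all()
        assert np.isnan(fmap.values[~fmap.mask]).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            krige_map([GeoSample(0, 0, 1), GeoSample(1, 1, 2)],
                      VariogramModel("spherical", 0, 1, 10), SQUARE_1HA)

    def test_random_field_recovery(self):
        """Map error well below field variability at survey densities."""
        samples, truth = _survey(seed=7, spacing=(6.0, 12.0), noise=0.02)
        assert len(samples) >= 150
        vg = fit_variogram(samples, family="gaussian")
        fmap = krige_map(samples, vg, SQUARE_1HA)
        ee, nn = fmap.cell_centers()
        t = truth(ee[fmap.mask], nn[fmap.mask])
        pred = fmap.values[fmap.mask]
        rmse = np.sqrt(np.mean((pred - t) ** 2))
        sd = t.std()
        assert rmse < 0.5 * sd
        baseline = np.sqrt(np.mean((t.mean() - t) ** 2))
        assert rmse < baseline


class TestIdw:
    def test_single_sample_constant_map(self):
        fmap = idw_map([GeoSample(50, 50, 0.7)], SQUARE_1HA)
        assert np.allclose(fmap.values[fmap.mask], 0.7)

    def test_symmetric_midpoint_is_mean(self):
        samples = [GeoSample(0.0, 47.5, 0.2), GeoSample(95.0, 47.5, 0.8)]
        fmap = idw_map(samples, SQUARE_1HA)
        ee, nn = fmap.cell_centers()
        mid = np.isclose(ee, 47.5) & np.isclose(nn, 47.5)
        assert fmap.values[mid][0] == pytest.approx(0.5)

    def test_comparable_to_kriging_on_smooth_field(self):
        # 0.05 metric noise: per-image canopy-metric error is of the same
        # order as the calibration's leave-one-site-out MAE (~5 points)
        samples, truth = _survey(seed=9, spacing=(6.0, 12.0), noise=0.05)
        vg = fit_variogram(samples)
        km = krige_map(samples, vg, SQUARE_1HA)
        im = idw_map(samples, SQUARE_1HA)
        ee, nn = km.cell_centers()
        t = truth(ee[km.mask], nn[km.mask])
        rmse_k = np.sqrt(np.mean((km.values[km.mask] - t) ** 2))
        rmse_i = np.sqrt(np.mean((im.values[im.mask] - t) ** 2))
        assert abs(rmse_k - rmse_i) / max(rmse_k, rmse_i) < 0.25


class TestMapReport:
    def test_density_matches_hand_computation(self):
        samples, _ = _survey(spacing=10.0)
        vg = fit_variogram(samples)
        fmap = krige_map(samples, vg, SQUARE_1HA)
        rep = map_report(fmap, samples, SQUARE_1HA)
        assert rep["area_ha"] == pytest.approx(1.0)
        assert rep["density_per_ha"] == pytest.approx(len(samples))

    def test_constant_map_mean_is_constant(self):
        vals = np.full((4, 4), 0.3)
        mask = np.ones((4, 4), bool)
        fmap = FieldMap(vals, mask, (0.0, 0.0), 5.0, {"method": "test"})
        rep = map_report(fmap, [], Polygon([(0, 0), (20, 0), (20, 20), (0, 20)]))
        assert rep["mean"] == pytest.approx(0.3)
        assert rep["median"] == pytest.approx(0.3)

    def test_write_field_map_outputs(self, tmp_path):
        samples, _ = _survey(spacing=10.0)
        fmap = idw_map(samples, SQUARE_1HA)
        sidecar = write_field_map(fmap, tmp_path / "clover_map")
        import tifffile
        arr = tifffile.imread(tmp_path / "clover_map.tif")
        assert arr.shape == fmap.values.shape
        assert (tmp_path / "clover_map.json").exists()
        assert (tmp_path / "clover_map.png").exists()
        assert sidecar["cell_m"] == 5.0
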