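"""Synthetic-scene generator: terrain, canopy, point clouds, photon tracks,
and waveform footprints against their construction contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from lidarval.scene import (SceneConfig, generate_canopy,
                            generate_staircase_terrain, generate_terrain,
                            make_scene, sample_point_cloud,
                            simulate_gedi_footprints, simulate_icesat2_track)
from lidarval.types import (LAS_GROUND, PHOTON_CANOPY, PHOTON_GROUND,
                            PHOTON_NOISE, PHOTON_TOC)

EXTENT = (0.0, 0.0, 100.0, 100.0)


class TestTerrain:
    def test_flat_case_is_constant_plane(self):
        cfg = SceneConfig(mean_slope_deg=0, roughness_amplitude=0)
        scene = generate_terrain(cfg, EXTENT)
        assert np.allclose(scene.dem.data, scene.dem.data[0, 0])

    def test_ramp_relief_matches_trigonometry(self):
        cfg = SceneConfig(mean_slope_deg=20, roughness_amplitude=0)
        scene = generate_terrain(cfg, (0, 0, 300, 300))
        relief = scene.dem.data.max() - scene.dem.data.min()
        # cell centers span 299 m along the ramp axis
        assert relief == pytest.approx(299.0 * math.tan(math.radians(20)),
                                       rel=1e-9)

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(seed=5, roughness_amplitude=2.0)
        a = generate_terrain(cfg, EXTENT)
        b = generate_terrain(cfg, EXTENT)
        np.testing.assert_array_equal(a.dem.data, b.dem.data)

    def test_nonfinite_config_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            generate_terrain(SceneConfig(mean_slope_deg=float("nan")), EXTENT)

    def test_bad_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_terrain(SceneConfig(), (0, 0, 0, 100))
        with pytest.raises(ValueError, match="divide"):
            generate_terrain(SceneConfig(), (0, 0, 100.5, 100))

    def test_staircase_panels_have_requested_slopes(self):
        slopes = (2.5, 10.0, 20.0)
        scene = generate_staircase_terrain(slopes, 60.0, 30.0)
        z = scene.dem.data[0]
        x = scene.dem.x_centers()
        for k, s in enumerate(slopes):
            sel = (x > k * 60 + 1) & (x < (k + 1) * 60 - 1)
            grad = np.diff(z[sel]).mean()
            assert grad == pytest.approx(math.tan(math.radians(s)), rel=1e-6)
        assert np.all(np.diff(z) >= 0)  # continuous, nondecreasing


class TestCanopy:
    def test_zero_cover_all_zero(self):
        cfg = SceneConfig(canopy_cover_fraction=0.0)
        scene = make_scene(cfg, EXTENT)
        assert np.all(scene.chm.data == 0.0)

    def test_full_cover_constant_height(self):
        cfg = SceneConfig(canopy_cover_fraction=1.0, canopy_height_mean=20.0,
                          canopy_height_sd=0.0)
        scene = make_scene(cfg, EXTENT)
        assert np.all(scene.chm.data == 20.0)

    def test_cover_fraction_rejected_outside_unit_interval(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SceneConfig(canopy_cover_fraction=1.2).validate()

    def test_realized_cover_matches_request(self):
        """Monte-Carlo over 20 seeds on a 1 ha scene: mean realized cover
        within [0.55, 0.65] for a 0.6 request."""
        covers = []
        for seed in range(20):
            cfg = SceneConfig(seed=seed, canopy_cover_fraction=0.6)
            scene = make_scene(cfg, (0, 0, 100, 100))
            covers.append((scene.chm.data > 0).mean())
        assert 0.55 <= np.mean(covers) <= 0.65

    def test_chm_nonnegative(self, hilly_scene):
        assert hilly_scene.chm.data.min() >= 0.0


class TestPointCloud:
    def test_count_within_poisson_bound(self, hilly_scene, hilly_config):
        cloud = sample_point_cloud(hilly_scene, hilly_config)
        lam = 3.9 * hilly_scene.area
        assert abs(len(cloud) - lam) < 3 * math.sqrt(lam)

    def test_bare_scene_all_ground(self, flat_scene, flat_config):
        cloud = sample_point_cloud(flat_scene, flat_config)
        assert np.all(cloud.classification == LAS_GROUND)

    def test_noise_free_flat_ground_exact(self, flat_scene, flat_config):
        cloud = sample_point_cloud(flat_scene, flat_config)
        np.testing.assert_array_equal(cloud.z, 500.0)

    def test_physicality_bounds(self, hilly_scene, hilly_config):
        """Canopy points lie within [dem, dem+chm]; ground points within
        4 noise standard deviations of the terrain."""
        cloud = sample_point_cloud(hilly_scene, hilly_config)
        dem = hilly_scene.dem.sample(cloud.x, cloud.y)
        chm = hilly_scene.chm.sample(cloud.x, cloud.y)
        veg = cloud.classification != LAS_GROUND
        assert np.all(cloud.z[veg] >= dem[veg] - 1e-9)
        assert np.all(cloud.z[veg] <= dem[veg] + chm[veg] + 1e-9)
        tol = 4 * hilly_config.ground_z_noise_sd + 1e-9
        assert np.all(np.abs(cloud.z[~veg] - dem[~veg]) <= tol)

    def test_determinism(self, hilly_scene, hilly_config):
        a = sample_point_cloud(hilly_scene, hilly_config)
        b = sample_point_cloud(hilly_scene, hilly_config)
        np.testing.assert_array_equal(a.z, b.z)


@pytest.fixture(scope="module")
def track(hilly_scene, hilly_config):
    return simulate_icesat2_track(hilly_scene, azimuth=15.0,
                                  config=hilly_config)


class TestPhotonTrack:
    def test_linkage_roundtrip_recovers_every_class(self, track):
        """Applying the linkage index formula to the emitted records must
        recover every signal photon's class exactly (generator
        bookkeeping oracle)."""
        photons = track.photons
        rec = track.records
        global_idx = (rec["classed_pc_indx"] + rec["ph_index_beg"] - 1)
        recovered = photons.set_index("photon_index").loc[
            global_idx, "truth_class"].to_numpy()
        np.testing.assert_array_equal(recovered,
                                      rec["classification"].to_numpy())
        # every non-noise photon has exactly one record
        n_signal = (photons["truth_class"] != PHOTON_NOISE).sum()
        assert len(rec) == n_signal

    def test_bare_scene_no_canopy_photons(self, flat_scene, flat_config):
        t = simulate_icesat2_track(flat_scene, azimuth=0.0,
                                   config=flat_config)
        assert not np.isin(t.photons["truth_class"],
                           (PHOTON_CANOPY, PHOTON_TOC)).any()

    def test_segment_centers_evenly_spaced(self, track):
        d = np.diff(track.segments["t_center"].to_numpy())
        np.testing.assert_allclose(d, 100.0)

    def test_photon_physicality(self, track, hilly_scene, hilly_config):
        ph = track.photons
        sig = ph[ph["truth_class"] != PHOTON_NOISE]
        dem = hilly_scene.dem.sample(sig["x_true"].to_numpy(),
                                     sig["y_true"].to_numpy())
        chm = hilly_scene.chm.sample(sig["x_true"].to_numpy(),
                                     sig["y_true"].to_numpy())
        canopy = sig["truth_class"].isin((PHOTON_CANOPY, PHOTON_TOC)).to_numpy()
        z = sig["z"].to_numpy()
        assert np.all(z[canopy] >= dem[canopy] - 1e-9)
        assert np.all(z[canopy] <= (dem + chm)[canopy] + 1e-9)
        ground = sig["truth_class"].to_numpy() == PHOTON_GROUND
        tol = 4 * hilly_config.ground_z_noise_sd + 1e-9
        assert np.all(np.abs(z[ground] - dem[ground]) <= tol)

    def test_outside_track_rejected(self, hilly_scene, hilly_config):
        with pytest.raises(ValueError, match="outside"):
            simulate_icesat2_track(hilly_scene, azimuth=0.0,
                                   config=hilly_config, center=(1e4, 1e4))

    def test_determinism(self, hilly_scene, hilly_config):
        a = simulate_icesat2_track(hilly_scene, 15.0, config=hilly_config)
        b = simulate_icesat2_track(hilly_scene, 15.0, config=hilly_config)
        pd.testing.assert_frame_equal(a.photons, b.photons)


class TestFootprints:
    def test_zero_error_reported_equals_true(self, hilly_scene, hilly_cloud,
                                             hilly_config):
        cfg = SceneConfig(**{**hilly_config.__dict__,
                             "geolocation_error_sd": 0.0})
        fps = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 30.0,
                                       cfg)
        assert len(fps) >= 1
        for fp in fps:
            assert fp.true_offset == (0.0, 0.0)

    def test_offsets_stored_and_deterministic(self, hilly_scene, hilly_cloud,
                                              hilly_config):
        a = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 30.0,
                                     hilly_config)
        b = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 30.0,
                                     hilly_config)
        assert [fp.true_offset for fp in a] == [fp.true_offset for fp in b]
        assert any(fp.true_offset != (0.0, 0.0) for fp in a)

    def test_quality_failures_reproducible(self, hilly_scene, hilly_cloud,
                                           hilly_config):
        cfg = SceneConfig(**{**hilly_config.__dict__, "fail_fraction": 0.5})
        a = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 20.0,
                                     cfg)
        b = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 20.0,
                                     cfg)
        fails_a = [(fp.quality_flag, fp.degrade_flag, fp.rx_assess_flag,
                    round(fp.sensitivity, 12)) for fp in a]
        fails_b = [(fp.quality_flag, fp.degrade_flag, fp.rx_assess_flag,
                    round(fp.sensitivity, 12)) for fp in b]
        assert fails_a == fails_b

    def test_bad_spacing_rejected(self, hilly_scene, hilly_cloud,
                                  hilly_config):
        with pytest.raises(ValueError, match="spacing"):
            simulate_gedi_footprints(hilly_scene, hilly_cloud, 0.0, -5.0,
                                     hilly_config)

    def test_rh_levels_monotone(self, hilly_scene, hilly_cloud, hilly_config):
        fps = simulate_gedi_footprints(hilly_scene, hilly_cloud, 15.0, 30.0,
                                       hilly_config)
        for fp in fps:
            vals = [fp.rh[j] for j in sorted(fp.rh)]
            finite = [v for v in vals if np.isfinite(v)]
            assert all(a <= b + 1e-12 for a, b in zip(finite, finite[1:]))
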