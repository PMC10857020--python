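"""Forward-model and scene-generator behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from socspec.preprocess import continuum_removal
from socspec.synthdata import (
    HIGHRES, DeviceProfile, SceneParams, apply_field_disturbance,
    block_resample, generate_lab_spectra, generate_scene, generate_soc,
    noiseless, quiet_device,
)


class TestGenerateSoc:
    def test_default_sample_mean_near_target(self, default_params):
        soc = generate_soc(default_params)
        assert 18.0 <= soc.mean() <= 21.0

    def test_zero_sd_degenerates_to_mean(self):
        p = SceneParams(soc_sd=0.0, rng_seed=3)
        assert np.allclose(generate_soc(p), p.soc_mean)

    def test_large_sample_respects_truncation_range(self):
        p = SceneParams(n_locations=100_000, rng_seed=5)
        soc = generate_soc(p)
        assert soc.min() >= p.soc_range[0]
        assert soc.max() <= p.soc_range[1]

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SceneParams(soc_range=(20.0, 20.0))

    def test_deterministic_given_seed(self):
        p = SceneParams(rng_seed=11)
        assert np.array_equal(generate_soc(p), generate_soc(p))


class TestSceneParamsValidation:
    def test_negative_band_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            SceneParams(band_widths=(45.0, -30.0, 25.0, 30.0, 40.0))

    def test_mismatched_band_lists_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            SceneParams(band_centers=(560.0, 1330.0))

    def test_moisture_range_bounds(self):
        with pytest.raises(ValueError, match="moisture"):
            SceneParams(moisture_range=(-5.0, 20.0))


class TestLabForwardModel:
    def test_zero_gains_make_spectra_soc_independent(self, noiseless_params,
                                                     quiet_highres):
        p = replace(noiseless_params, band_gains=(0.0,) * 5, soc_spectral_sd=0.0,
                    artifact_band_count=0)
        dev = replace(quiet_highres, replicate_counts={"lab": 1, "field": 1})
        s, _ = generate_lab_spectra(np.array([14.0, 25.0]), dev, p)
        assert np.allclose(s.reflectance[0], s.reflectance[1])

    def test_noiseless_spectrum_is_function_of_soc(self, noiseless_params,
                                                   quiet_highres):
        p = replace(noiseless_params, artifact_band_count=0)
        dev = replace(quiet_highres, replicate_counts={"lab": 1, "field": 1})
        s, _ = generate_lab_spectra(np.array([18.0, 18.0, 21.0]), dev, p)
        assert np.allclose(s.reflectance[0], s.reflectance[1])
        assert not np.allclose(s.reflectance[0], s.reflectance[2])

    def test_continuum_removed_minima_near_band_centers(self, noiseless_params,
                                                        quiet_highres):
        p = replace(noiseless_params, artifact_band_count=0)
        dev = replace(quiet_highres, replicate_counts={"lab": 1, "field": 1})
        s, _ = generate_lab_spectra(np.array([22.0]), dev, p)
        cr = continuum_removal(s)
        wl, v = cr.wavelengths, cr.reflectance[0]
        for center in p.band_centers:
            win = np.flatnonzero(np.abs(wl - center) <= 30)
            located = wl[win[np.argmin(v[win])]]
            assert abs(located - center) <= 5.0

    def test_band_gain_monotonically_deepens_feature(self, noiseless_params,
                                                     quiet_highres):
        dev = replace(quiet_highres, replicate_counts={"lab": 1, "field": 1})
        p0 = replace(noiseless_params, artifact_band_count=0)
        gains = list(p0.band_gains)
        gains[2] *= 2.0
        p1 = replace(p0, band_gains=tuple(gains))
        s0, _ = generate_lab_spectra(np.array([20.0]), dev, p0)
        s1, _ = generate_lab_spectra(np.array([20.0]), dev, p1)
        c = p0.band_centers[2]
        at_band = np.argmin(np.abs(s0.wavelengths - c))
        depth0 = continuum_removal(s0).reflectance[0, at_band]
        depth1 = continuum_removal(s1).reflectance[0, at_band]
        assert depth1 < depth0

    def test_reflectance_within_unit_interval(self, small_scene):
        for s in (*small_scene.lab.values(), *small_scene.field.values(),
                  *small_scene.stream.values()):
            assert np.all(s.reflectance > 0) and np.all(s.reflectance < 1)
            assert np.isfinite(s.reflectance).all()

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            SceneParams(band_gains=(0.001, -0.001, 0.001, 0.001, 0.001))


class TestFieldDisturbance:
    def _noiseless_lab(self, params, device, soc):
        dev = replace(quiet_device(device), replicate_counts={"lab": 1, "field": 3})
        p = replace(noiseless(params), artifact_band_count=0)
        s, _ = generate_lab_spectra(soc, dev, p)
        return s, dev, p

    def test_identity_at_zero_disturbance(self, default_params):
        soc = np.array([16.0, 20.0, 24.0])
        lab, dev, p = self._noiseless_lab(default_params, HIGHRES, soc)
        p = replace(p, moisture_gain=0.0)
        fld = apply_field_disturbance(lab, np.zeros(3), dev, p)
        for i in range(3):
            rows = fld.reflectance[fld.meta["sample_id"] == lab.meta["sample_id"][i]]
            assert np.allclose(rows, lab.reflectance[i], atol=1e-12)

    def test_moisture_out_of_range_rejected(self, default_params):
        soc = np.array([16.0, 20.0])
        lab, dev, p = self._noiseless_lab(default_params, HIGHRES, soc)
        with pytest.raises(ValueError, match="moisture"):
            apply_field_disturbance(lab, np.array([50.0, 120.0]), dev, p)

    def test_lab_field_difference_concentrates_at_water_bands(self, default_params):
        soc = np.array([16.0, 20.0, 24.0])
        lab, dev, p = self._noiseless_lab(default_params, HIGHRES, soc)
        p = replace(p, field_soc_mismatch_sd=0.0)
        fld = apply_field_disturbance(lab, np.full(3, 20.0), dev, p)
        diff = np.abs(lab.reflectance.mean(axis=0) - fld.reflectance.mean(axis=0))
        peak_wl = lab.wavelengths[np.argmax(diff)]
        assert any(abs(peak_wl - c) <= 20 for c in p.moisture_band_centers)

    def test_noiseless_difference_matrix_is_low_rank(self, default_params):
        soc = np.linspace(15, 24, 8)
        lab, dev, p = self._noiseless_lab(default_params, HIGHRES, soc)
        p = replace(p, field_soc_mismatch_sd=0.0)
        fld = apply_field_disturbance(lab, np.linspace(15, 25, 8), dev, p)
        lab_avg = lab.reflectance
        fld_avg = np.vstack([
            fld.reflectance[fld.meta["sample_id"] == sid].mean(axis=0)
            for sid in lab.meta["sample_id"]])
        D = lab_avg - fld_avg
        D = D - D.mean(axis=0)
        sv = np.linalg.svd(D, compute_uv=False)
        modes = len(p.moisture_band_centers)
        assert (sv > sv[0] * 1e-9).sum() <= modes + 1


class TestDeviceConsistency:
    def test_lowres_equals_block_resampled_highres(self, noiseless_params):
        p = replace(noiseless_params, artifact_band_count=0)
        hr = DeviceProfile(name="hr", wavelength_start=350, wavelength_end=2200,
                           resolution=1.0, replicate_counts={"lab": 1, "field": 1})
        lr = DeviceProfile(name="lr", wavelength_start=350, wavelength_end=2200,
                           resolution=5.0, dead_bands=((1000.0, 1100.0),),
                           replicate_counts={"lab": 1, "field": 1})
        soc = np.array([17.0, 21.0])
        s_hr, _ = generate_lab_spectra(soc, hr, p)
        s_lr, _ = generate_lab_spectra(soc, lr, p)
        wl_b, refl_b = block_resample(s_hr.wavelengths, s_hr.reflectance, 5.0,
                                      lr.dead_bands)
        assert np.allclose(wl_b, s_lr.wavelengths)
        assert np.allclose(refl_b, s_lr.reflectance, atol=1e-12)

    def test_device_validation(self):
        with pytest.raises(ValueError):
            DeviceProfile(name="bad", wavelength_start=2500, wavelength_end=350,
                          resolution=1.0)
        with pytest.raises(ValueError):
            DeviceProfile(name="bad", wavelength_start=350, wavelength_end=2500,
                          resolution=1.0, splice_points=(3000.0,))


class TestSceneDeterminism:
    def test_bit_identical_regeneration(self):
        p = SceneParams(n_locations=10, rng_seed=42)
        a = generate_scene(p)
        b = generate_scene(p)
        assert np.array_equal(a.samples.soc, b.samples.soc)
        for k in a.lab:
            assert np.array_equal(a.lab[k].reflectance, b.lab[k].reflectance)
        for k in a.stream:
            assert np.array_equal(a.stream[k].reflectance, b.stream[k].reflectance)
            assert np.array_equal(a.stream[k].meta["x_m"], b.stream[k].meta["x_m"])

    def test_stream_covers_every_location(self, small_scene):
        stream = small_scene.stream["lowres"]
        coords = small_scene.samples.coords
        xy = stream.meta[["x_m", "y_m"]].to_numpy()
        p = small_scene.params
        for i in range(coords.shape[0]):
            d = np.hypot(xy[:, 0] - coords[i, 0], xy[:, 1] - coords[i, 1])
            assert (d <= p.stream_jitter_m + 1e-9).sum() >= 10

    def test_moisture_within_range(self, small_scene):
        lo, hi = small_scene.params.moisture_range
        assert np.all((small_scene.moisture >= lo) & (small_scene.moisture <= hi))
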