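"""The four preprocessing operators plus splice/trim/outlier preparation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from socspec.preprocess import (
    PreprocessSpec, adjusted_outlier_flags, apply_preprocessing,
    continuum_removal, gap_segment_derivative, msc, remove_outliers,
    savitzky_golay, splice_correct, trim_range, upper_hull_envelope,
)
from socspec.synthdata import DeviceProfile, generate_lab_spectra, noiseless

from conftest import make_spectrum_set


@pytest.fixture
def grid():
    return np.arange(400.0, 2201.0)


class TestSpliceCorrect:
    def test_identity_without_steps(self, grid):
        spec = 0.5 + 0.05 * np.sin(grid / 200.0)
        s = make_spectrum_set(grid, spec[None, :])
        out = splice_correct(s, [1000.0, 1800.0])
        assert np.allclose(out.reflectance, s.reflectance, atol=1e-12)

    def test_piecewise_constant_step_removed(self, grid):
        spec = np.where(grid <= 1000.0, 0.5, 0.6)
        s = make_spectrum_set(grid, spec[None, :])
        out = splice_correct(s, [1000.0])
        assert np.allclose(out.reflectance, 0.5, atol=1e-12)

    def test_injected_offsets_recovered(self, default_params):
        # noiseless generation with explicit per-segment offsets vs. without
        p = replace(noiseless(default_params), artifact_band_count=0)
        dev = DeviceProfile(name="hr", wavelength_start=400, wavelength_end=2200,
                            resolution=1.0, splice_points=(1000.0, 1800.0),
                            replicate_counts={"lab": 1, "field": 1})
        clean, _ = generate_lab_spectra(np.array([20.0]), dev, p)
        wl = clean.wavelengths
        offset = np.where(wl > 1800, -0.01, np.where(wl > 1000, 0.02, 0.0))
        stepped = make_spectrum_set(wl, clean.reflectance + offset)
        fixed = splice_correct(stepped, [1000.0, 1800.0])
        # recovery is exact up to the second-order error of the two-point
        # linear extrapolation (local curvature x step^2)
        assert np.max(np.abs(fixed.reflectance - clean.reflectance)) < 1e-4

    def test_splice_point_outside_grid_rejected(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.5))
        with pytest.raises(ValueError, match="outside grid"):
            splice_correct(s, [3000.0])


class TestTrimRange:
    def test_paper_range(self):
        wl = np.arange(350.0, 2501.0)
        s = make_spectrum_set(wl, np.full((1, wl.size), 0.5))
        out = trim_range(s, 400.0, 2200.0)
        assert out.wavelengths[0] == 400.0 and out.wavelengths[-1] == 2200.0

    def test_full_range_is_identity(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.5))
        out = trim_range(s, grid[0], grid[-1])
        assert np.array_equal(out.wavelengths, grid)

    def test_dead_band_removed(self):
        wl = np.arange(400.0, 2201.0, 5.0)
        s = make_spectrum_set(wl, np.full((1, wl.size), 0.5))
        out = trim_range(s, 400.0, 2200.0, dead_bands=((1000.0, 1100.0),))
        inside = (out.wavelengths > 1000.0) & (out.wavelengths < 1100.0)
        assert not inside.any()

    def test_empty_result_rejected(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.5))
        with pytest.raises(ValueError):
            trim_range(s, 3000.0, 4000.0)


class TestSavitzkyGolay:
    def test_exact_derivative_of_cubic(self, grid):
        y = 1e-9 * (grid - 1000.0) ** 3
        s = make_spectrum_set(grid, y[None, :])
        out = savitzky_golay(s, window=11, poly_order=3, derivative_order=1)
        expect = 3e-9 * (out.wavelengths - 1000.0) ** 2
        assert np.allclose(out.reflectance[0], expect, atol=1e-12)

    def test_constant_derivative_is_zero(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.42))
        out = savitzky_golay(s)
        assert np.allclose(out.reflectance, 0.0, atol=1e-15)

    def test_edge_dropping_matches_reduced_range(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.5))
        out = savitzky_golay(s, window=11)
        assert out.wavelengths[0] == 405.0 and out.wavelengths[-1] == 2195.0

    def test_additive_offset_invariance(self, grid):
        rng = np.random.Generator(np.random.PCG64(1))
        y = 0.5 + 0.1 * np.sin(grid / 100.0) + rng.normal(0, 0.01, grid.size)
        a = savitzky_golay(make_spectrum_set(grid, y[None, :]))
        b = savitzky_golay(make_spectrum_set(grid, y[None, :] + 0.2))
        assert np.allclose(a.reflectance, b.reflectance, atol=1e-12)

    def test_short_segment_rejected(self):
        wl = np.arange(400.0, 408.0)
        s = make_spectrum_set(wl, np.full((1, wl.size), 0.5))
        with pytest.raises(ValueError, match="window"):
            savitzky_golay(s, window=11)


class TestContinuumRemoval:
    def test_linear_spectrum_maps_to_ones(self, grid):
        y = 0.3 + 1e-4 * (grid - 400.0)
        out = continuum_removal(make_spectrum_set(grid, y[None, :]))
        assert np.allclose(out.reflectance, 1.0, atol=1e-12)

    def test_gaussian_dip_depth(self, grid):
        y = 0.5 - 0.1 * np.exp(-0.5 * ((grid - 1300.0) / 30.0) ** 2)
        out = continuum_removal(make_spectrum_set(grid, y[None, :]))
        at = np.argmin(np.abs(out.wavelengths - 1300.0))
        assert np.isclose(out.reflectance[0, at], 0.8, atol=1e-9)
        assert np.all(out.reflectance > 0) and np.all(out.reflectance <= 1)
        assert np.isclose(out.reflectance[0, 0], 1.0)
        assert np.isclose(out.reflectance[0, -1], 1.0)

    def test_hull_matches_quadratic_scan_oracle(self):
        rng = np.random.Generator(np.random.PCG64(7))
        x = np.sort(rng.uniform(0, 100, 60))
        for _ in range(100):
            y = rng.uniform(0.1, 1.0, x.size)
            fast = upper_hull_envelope(x, y)
            # O(n^2) oracle: the upper hull is the pointwise-minimal concave
            # envelope; its value at x_i is the max over all chords covering i
            slow = y.copy()
            for i in range(x.size):
                best = y[i]
                for a in range(x.size):
                    for b in range(a + 1, x.size):
                        if x[a] <= x[i] <= x[b]:
                            t = (x[i] - x[a]) / (x[b] - x[a])
                            best = max(best, y[a] + t * (y[b] - y[a]))
                slow[i] = best
            assert np.allclose(fast, slow, atol=1e-10)

    def test_non_positive_reflectance_rejected(self, grid):
        y = np.full(grid.size, 0.5)
        y[10] = 0.0
        with pytest.raises(ValueError, match="positive"):
            continuum_removal(make_spectrum_set(grid, y[None, :]))


class TestGapSegmentDerivative:
    def test_exact_on_affine(self, grid):
        y = 0.1 + 2e-4 * grid
        out = gap_segment_derivative(make_spectrum_set(grid, y[None, :]))
        assert np.allclose(out.reflectance, 2e-4, atol=1e-15)

    def test_zero_on_constant(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.7))
        out = gap_segment_derivative(s)
        assert np.allclose(out.reflectance, 0.0, atol=1e-12)

    def test_edge_dropping_matches_reduced_range(self, grid):
        s = make_spectrum_set(grid, np.full((1, grid.size), 0.5))
        out = gap_segment_derivative(s, w=11, s_seg=10)
        assert out.wavelengths[0] == 415.0 and out.wavelengths[-1] == 2185.0


class TestMsc:
    @pytest.fixture
    def spectra(self):
        rng = np.random.Generator(np.random.PCG64(3))
        wl = np.arange(400.0, 800.0)
        base = 0.5 - 0.1 * np.exp(-0.5 * ((wl - 600.0) / 40.0) ** 2)
        rows = [s * base + o for s, o in
                zip(rng.uniform(0.8, 1.2, 8), rng.normal(0, 0.02, 8))]
        return make_spectrum_set(wl, np.vstack(rows))

    def test_reference_spectrum_unchanged(self, spectra):
        ref = spectra.reflectance.mean(axis=0)
        s = make_spectrum_set(spectra.wavelengths, ref[None, :])
        out, _ = msc(s, ref)
        assert np.allclose(out.reflectance[0], ref, atol=1e-10)

    def test_affine_distortion_removed_exactly(self, spectra):
        ref = spectra.reflectance.mean(axis=0)
        distorted = 0.1 + 2.0 * ref
        s = make_spectrum_set(spectra.wavelengths, distorted[None, :])
        out, _ = msc(s, ref)
        assert np.allclose(out.reflectance[0], ref, atol=1e-10)

    def test_idempotent_with_stored_reference(self, spectra):
        once, ref = msc(spectra)
        twice, _ = msc(once, ref)
        assert np.allclose(once.reflectance, twice.reflectance, atol=1e-10)

    def test_additive_offset_invariance(self, spectra):
        ref = spectra.reflectance.mean(axis=0)
        a, _ = msc(spectra, ref)
        shifted = make_spectrum_set(spectra.wavelengths, spectra.reflectance + 0.3)
        b, _ = msc(shifted, ref)
        assert np.allclose(a.reflectance, b.reflectance, atol=1e-9)


class TestOutlierRemoval:
    def _replicates(self, rng, n=18, shift=None):
        wl = np.arange(400.0, 1000.0, 5.0)
        truth = 0.5 - 0.1 * np.exp(-0.5 * ((wl - 700.0) / 50.0) ** 2)
        reps = truth + rng.normal(0, 0.004, (n, wl.size))
        if shift is not None:
            reps[shift] += 0.04  # 10x the noise sd
        return make_spectrum_set(wl, reps, sample_ids=["a"] * n,
                                 replicate_id=np.arange(n))

    def test_identical_replicates_kept(self):
        wl = np.arange(400.0, 500.0)
        s = make_spectrum_set(wl, np.tile(np.full(wl.size, 0.5), (10, 1)),
                              sample_ids=["a"] * 10, replicate_id=np.arange(10))
        out, report = remove_outliers(s)
        assert out.n_spectra == 10
        assert report["removed"].sum() == 0

    def test_single_shifted_replicate_removed(self):
        rng = np.random.Generator(np.random.PCG64(21))
        s = self._replicates(rng, n=18, shift=7)
        out, report = remove_outliers(s)
        assert report["removed"].sum() == 1
        assert 7 not in out.meta["replicate_id"].to_numpy()

    def test_small_groups_pass_through(self):
        wl = np.arange(400.0, 450.0)
        s = make_spectrum_set(wl, np.random.default_rng(0).uniform(0, 1, (2, wl.size)),
                              sample_ids=["a", "a"], replicate_id=[0, 1])
        out, report = remove_outliers(s)
        assert out.n_spectra == 2
        assert "too few" in report["note"].iloc[0]

    def test_flags_match_brute_force_definition(self):
        # independent re-implementation of the same distance/threshold
        # definitions, written directly from their description
        rng = np.random.Generator(np.random.PCG64(5))
        for trial in range(20):
            n, p = 15, 40
            X = rng.normal(0, 1, (n, p)) * 0.01 + 0.5
            if trial % 2:
                X[0] += 0.1
            got = adjusted_outlier_flags(X)
            assert np.array_equal(got, _oracle_flags(X))


def _oracle_flags(X, base_quantile=0.975):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    var = sv ** 2
    k = int(np.searchsorted(np.cumsum(var) / var.sum(), 0.99) + 1)
    k = max(1, min(k, n - 2))
    Z = U[:, :k] * sv[:k]
    h = (n + k + 1) // 2
    center = np.median(Z, axis=0)
    d2 = ((Z - center) ** 2).sum(axis=1)
    subset = np.argsort(d2, kind="stable")[:h]
    for _ in range(30):
        mu = Z[subset].mean(axis=0)
        cov = np.cov(Z[subset], rowvar=False).reshape(k, k)
        d2 = _maha(Z, mu, cov)
        new = np.argsort(d2, kind="stable")[:h]
        if np.array_equal(np.sort(new), np.sort(subset)):
            break
        subset = new
    med = np.median(d2)
    if med > 0:
        d2 = d2 * (stats.chi2.ppf(0.5, k) / med)
    w = d2 <= stats.chi2.ppf(0.975, k)
    if w.sum() >= k + 2:
        mu = Z[w].mean(axis=0)
        cov = np.cov(Z[w], rowvar=False).reshape(k, k)
        d2 = _maha(Z, mu, cov)
        med = np.median(d2)
        if med > 0:
            d2 = d2 * (stats.chi2.ppf(0.5, k) / med)
    delta = stats.chi2.ppf(base_quantile, k)
    if np.mean(d2 > delta) <= 1.0 - base_quantile:
        return np.zeros(n, dtype=bool)
    return d2 > delta


def _maha(Z, mu, cov):
    return np.einsum("ij,ji->i", (Z - mu) @ np.linalg.inv(cov), (Z - mu).T)


class TestPipelines:
    def test_sgcr_output_bounded(self, grid):
        rng = np.random.Generator(np.random.PCG64(4))
        y = 0.5 - 0.1 * np.exp(-0.5 * ((grid - 1300) / 40.0) ** 2) \
            + rng.normal(0, 0.002, grid.size)
        out = apply_preprocessing(make_spectrum_set(grid, y[None, :]),
                                  PreprocessSpec(method="SGCR"))
        assert np.all(out.reflectance > 0) and np.all(out.reflectance <= 1.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessSpec(method="SNV")

    def test_dead_band_never_bridged(self):
        wl = np.concatenate([np.arange(400.0, 1000.0, 5.0),
                             np.arange(1100.0, 2200.0, 5.0)])
        rng = np.random.Generator(np.random.PCG64(6))
        y = 0.5 + rng.normal(0, 0.01, wl.size)
        out = gap_segment_derivative(make_spectrum_set(wl, y[None, :]),
                                     w=5, s_seg=4)
        # output wavelengths keep clear of both sides of the gap
        assert not ((out.wavelengths > 970) & (out.wavelengths < 1130)).any()
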