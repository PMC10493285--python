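"""Unit tests for stimuli, kernels, encoders and rate-model projections."""

import numpy as np
import pytest

from ifatsim.rate_model import RateModelParams
from ifatsim.vision import (
    bar_stimulus,
    detect_boundaries,
    encode_kernel,
    encode_stimulus,
    gabor_patch,
    project_patch,
    synthetic_boundary_image,
    tuning_curve,
)


class TestGabor:
    def test_zero_mean(self):
        for theta in (0, 45, 90, 135):
            assert abs(gabor_patch(theta).sum()) < 1e-12

    def test_transpose_maps_0_to_90(self):
        assert np.allclose(gabor_patch(0.0).T, gabor_patch(90.0), atol=1e-9)

    def test_even_phase_180_symmetry(self):
        assert np.allclose(gabor_patch(30.0), gabor_patch(210.0), atol=1e-9)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            gabor_patch(0.0, size=14)


class TestBarStimulus:
    def test_periodicity(self):
        assert np.allclose(bar_stimulus(0.0), bar_stimulus(180.0), atol=1e-9)

    def test_center_pixel_maximal(self):
        for theta in range(0, 180, 15):
            b = bar_stimulus(float(theta))
            assert b[7, 7] == b.max()

    def test_total_intensity_orientation_invariant(self):
        masses = [bar_stimulus(float(t)).sum() for t in range(0, 180, 5)]
        assert max(masses) <= 1.05 * min(masses)


class TestEncoders:
    def test_intensity_code_range(self):
        stim = bar_stimulus(0.0)
        rates = encode_stimulus(stim)
        assert rates.min() == 0.0                    # darkest -> code 0
        assert rates.max() == pytest.approx(63 * 31.25)  # brightest -> code 63

    def test_all_zero_stimulus(self):
        assert np.all(encode_stimulus(np.zeros((15, 15))) == 0.0)

    def test_kernel_codes_bounded_and_signed(self):
        w = encode_kernel(gabor_patch(45.0))
        assert np.abs(w).max() == 160                # 2 * w_nom mid-scale
        assert w.min() < 0 < w.max()

    def test_uniform_stimulus_cancels_on_zero_mean_kernel(self):
        from ifatsim.vision import _effective_drive
        rates = encode_stimulus(np.full((15, 15), 200.0), max_intensity=200.0)
        w = encode_kernel(gabor_patch(0.0))
        d = _effective_drive(rates, w, 80)
        assert abs(d.f_ext_eff - d.f_inh_eff) <= 0.02 * d.f_ext_eff

    def test_contrast_doubling_doubles_drive(self):
        from ifatsim.vision import _effective_drive
        # intensities on the exact code grid so rounding commutes
        codes = np.clip(np.rint(bar_stimulus(30.0) / 255.0 * 31), 0, 31)
        stim = codes * (255.0 / 63.0)
        w = encode_kernel(gabor_patch(30.0))
        d1 = _effective_drive(encode_stimulus(stim, max_intensity=255.0), w, 80)
        d2 = _effective_drive(encode_stimulus(2 * stim, max_intensity=255.0), w, 80)
        assert d2.f_ext_eff == pytest.approx(2 * d1.f_ext_eff, rel=1e-9)
        assert d2.f_inh_eff == pytest.approx(2 * d1.f_inh_eff, rel=1e-9)


class TestProjection:
    def test_orthogonal_bar_is_near_zero(self):
        p = RateModelParams(G_wnom=1.0)
        k = encode_kernel(gabor_patch(0.0))
        aligned = project_patch(encode_stimulus(bar_stimulus(0.0)), k, rm_params=p)
        ortho = project_patch(encode_stimulus(bar_stimulus(90.0)), k, rm_params=p)
        assert ortho <= 0.01 * aligned

    def test_aligned_bar_is_peak_over_sweep(self):
        k = encode_kernel(gabor_patch(45.0))
        outs = {
            th: project_patch(encode_stimulus(bar_stimulus(float(th))), k)
            for th in range(0, 180, 15)
        }
        assert max(outs, key=outs.get) == 45

    def test_uniform_times_zero_mean_kernel_is_null(self):
        rates = encode_stimulus(np.full((15, 15), 100.0), max_intensity=100.0)
        k = encode_kernel(gabor_patch(90.0))
        aligned = project_patch(encode_stimulus(bar_stimulus(90.0)), k)
        assert project_patch(rates, k) <= 0.01 * aligned

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_patch(np.zeros((15, 15)), np.zeros((13, 13)))


class TestTuningCurveRateModel:
    def test_peak_at_kernel_orientation(self):
        for theta in (0.0, 45.0, 90.0, 135.0):
            tc = tuning_curve(theta, trials=1, mode="rate_model")
            # peak within one 5-degree step (curves are 180-periodic)
            d = abs(tc.peak_angle() - theta) % 180.0
            assert min(d, 180.0 - d) <= 5.0

    def test_curve_is_180_periodic(self):
        tc = tuning_curve(45.0, trials=1, mode="rate_model")
        assert tc.mean_rate[0] == pytest.approx(tc.mean_rate[-1], rel=1e-9)

    def test_zero_contrast_stimulus_is_flat_zero(self):
        k = encode_kernel(gabor_patch(0.0))
        out = project_patch(encode_stimulus(np.zeros((15, 15))), k)
        assert out == 0.0


class TestBoundaryMapsRateModel:
    def test_constant_image_gives_zero_maps(self):
        maps = detect_boundaries(np.full((20, 20), 128.0), normalize=False)
        for m in maps:
            assert np.allclose(m, 0.0, atol=1e-6)

    def test_vertical_step_edge_peaks_near_edge_column(self):
        img = np.zeros((25, 25))
        img[:, 13:] = 255.0
        maps = detect_boundaries(img, normalize=False)
        vertical = maps[2]   # 90-degree kernel: stripes along the vertical edge
        # the vertically oriented kernel dominates the other three on a
        # vertical edge
        assert vertical.max() > 3 * max(maps[0].max(), maps[1].max(), maps[3].max())
        # edge sits at image column 12.5 -> map column 5.5 after the 7-pixel
        # valid margin; an even-phase kernel peaks up to a quarter wavelength
        # (2.5 px) to either side of a step edge
        peak_cols = np.argmax(vertical, axis=1)
        assert np.all(np.abs(peak_cols - 5.5) <= 3.0)

    def test_rot90_equivariance(self):
        img = synthetic_boundary_image(24, 24)
        maps = detect_boundaries(img.astype(float), normalize=False)
        maps_rot = detect_boundaries(np.rot90(img).astype(float), normalize=False)
        # rotating the image by 90 degrees swaps the roles of the 0- and
        # 90-degree kernels (up to encoder rounding)
        a = maps_rot[2]
        b = np.rot90(maps[0])
        denom = max(b.max(), 1.0)
        assert np.max(np.abs(a - b)) / denom < 0.05

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError):
            detect_boundaries(np.zeros((10, 10)))

    def test_normalized_maps_span_0_255(self):
        img = synthetic_boundary_image(24, 24)
        maps = detect_boundaries(img.astype(float), normalize=True)
        assert max(m.max() for m in maps) == pytest.approx(255.0)
        assert min(m.min() for m in maps) >= 0.0
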