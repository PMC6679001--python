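"""Preprocessing, triangle thresholding, midline tracing and normal refinement."""

import dataclasses
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from flagbeat.synthetic import WaveformParams, constant, generate_waveform, render_movie
from flagbeat.trace import (
    QUALITY_FIT_FAILED,
    TraceFailure,
    TraceSettings,
    _gaussian_center_fit,
    preprocess_frame,
    read_trace_csv,
    refine_normals,
    trace_frame,
    trace_midline,
    trace_movie,
    triangle_threshold,
    write_trace_csv,
)
from conftest import gt_to_movie_px


def gaussian_ridge(shape, y_center, sigma=1.5, peak=1000.0):
    """Horizontal ridge image with Gaussian cross-section."""
    yy = np.arange(shape[0])[:, None].astype(float)
    return np.tile(peak * np.exp(-((yy - y_center) ** 2) / (2 * sigma**2)), (1, shape[1]))


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess_frame(np.full((32, 32), 117.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_ridge_preserved_background_removed(self):
        """A narrow bright ridge on a pedestal survives; the pedestal does not."""
        img = gaussian_ridge((40, 60), y_center=20.0, sigma=1.0, peak=1000.0) + 500.0
        out = preprocess_frame(img)
        ridge_peak = out[20, 30]
        assert ridge_peak > 0.9 * 1000.0 * 0.8  # blur spreads a little too
        background = out[5, :].max()
        assert background < 0.01 * ridge_peak

    def test_delta_impulse_blur_matches_gaussian_kernel(self):
        """The blur stage reproduces the sampled, normalized Gaussian kernel."""
        img = np.zeros((41, 41))
        img[20, 20] = 10000.0
        out = preprocess_frame(img, TraceSettings(bg_radius_px=15.0))
        sigma = 0.5
        ii = np.arange(-2, 3)
        k1 = np.exp(-(ii**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = 10000.0 * np.outer(k1, k1)
        np.testing.assert_allclose(out[18:23, 18:23], expected, atol=0.02 * expected.max())

    def test_non_2d_input_raises(self):
        with pytest.raises(ValueError, match="2-D"):
            preprocess_frame(np.zeros((3, 4, 5)))


class TestTriangleThreshold:
    def test_matches_brute_force_scan(self):
        """Independent per-bin scan over the peak-to-tail span finds the same bin."""
        hist = np.zeros(101)
        hist[10] = 1000.0
        hist[11:100] = np.linspace(900.0, 10.0, 89) ** 1.5 / 30  # convex decay
        res = triangle_threshold(hist)
        assert not res.degenerate

        peak, far = 10, 99
        best, best_d = None, -1.0
        for b in range(peak, far + 1):
            x = (b - peak) / (far - peak)
            y = (hist[b] - hist[far]) / (hist[peak] - hist[far])
            d = (1.0 - x - y) / math.sqrt(2.0)
            if d > best_d:
                best, best_d = b, d
        assert res.threshold == best

    def test_two_bin_histogram_degenerate(self):
        res = triangle_threshold([5.0, 3.0])
        assert res.degenerate and res.threshold == 0

    def test_flat_histogram_degenerate(self):
        res = triangle_threshold([4.0, 4.0, 4.0, 4.0])
        assert res.degenerate

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError):
            triangle_threshold([])
        with pytest.raises(ValueError):
            triangle_threshold([0.0, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 1000), min_size=5, max_size=60),
        pad=st.integers(1, 30),
    )
    def test_trailing_empty_bins_do_not_change_result(self, counts, pad):
        hist = np.asarray(counts, dtype=float)
        if not (hist > 0).any():
            return
        padded = np.concatenate([hist, np.zeros(pad)])
        assert triangle_threshold(hist) == triangle_threshold(padded)

    def test_agrees_with_skimage_on_smooth_histogram(self):
        """Sanity cross-check against the scikit-image triangle implementation."""
        from skimage.filters import threshold_triangle

        rng = np.random.default_rng(0)
        img = rng.normal(50, 8, size=(256, 256)).clip(0, 255)
        img[100:110, :] = rng.normal(200, 10, size=(10, 256)).clip(0, 255)
        img = img.astype(np.uint8)
        counts = np.bincount(img.ravel(), minlength=256)
        ours = triangle_threshold(counts).threshold
        theirs = threshold_triangle(img, nbins=256)
        assert abs(ours - theirs) <= 5


class TestTraceMidline:
    def test_straight_flagellum_subhalfpixel(self):
        p = WaveformParams(n_frames=2, noise_sd=0.0, amp_envelope=constant(0.0))
        truth = generate_waveform(p)
        movie = render_movie(truth)
        f = trace_frame(movie.stack[0], pixel_size_um=p.pixel_size_um,
                        head_xy_px=tuple(movie.meta["head_xy_px"]))
        gt_px = gt_to_movie_px(truth, movie, 0)
        pts = np.column_stack([f.x_um, f.y_um]) / p.pixel_size_um
        d, _ = cKDTree(gt_px).query(pts)
        assert np.sqrt((d**2).mean()) < 0.5

    def test_quarter_circle_arc_length(self):
        """Arc length of a rendered R = 50 µm quarter circle within 2 %."""
        R = 50.0
        p = WaveformParams(
            length_um=R * math.pi / 2, n_frames=2, noise_sd=0.0,
            amp_envelope=constant(0.0), asym_offset=lambda s: np.asarray(s) / R,
        )
        movie = render_movie(generate_waveform(p))
        f = trace_frame(movie.stack[0], pixel_size_um=p.pixel_size_um,
                        head_xy_px=tuple(movie.meta["head_xy_px"]))
        assert f.length_um == pytest.approx(R * math.pi / 2, rel=0.02)

    def test_blank_frame_fails(self):
        with pytest.raises(TraceFailure):
            trace_midline(np.zeros((50, 50)))

    def test_head_end_found_by_brightness(self, beat_movie, beat_truth):
        """Without a tether hint, the bright head blob anchors the ordering."""
        f = trace_frame(beat_movie.stack[0], pixel_size_um=beat_movie.pixel_size_um)
        head_px = np.array(beat_movie.meta["head_xy_px"])
        start = np.array([f.x_um[0], f.y_um[0]]) / beat_movie.pixel_size_um
        end = np.array([f.x_um[-1], f.y_um[-1]]) / beat_movie.pixel_size_um
        assert np.linalg.norm(start - head_px) < np.linalg.norm(end - head_px)


class TestRefineNormals:
    def _displaced_ridge_setup(self, offset=0.8):
        img = gaussian_ridge((30, 80), y_center=15.0 + offset, sigma=1.5, peak=1000.0)
        pts = np.column_stack([np.linspace(5, 75, 60), np.full(60, 15.0)])
        s = TraceSettings(exclude_head_from_correction=False)
        return img, pts, s

    def test_displaced_ridge_recentered(self):
        img, pts, s = self._displaced_ridge_setup(0.8)
        out, width, quality = refine_normals(pts, img, s, pixel_size_um=0.65)
        interior = slice(5, -5)
        np.testing.assert_allclose(out[interior, 1], 15.8, atol=0.1)
        assert np.all(quality[interior] == 0)

    def test_centered_ridge_not_moved(self):
        img, pts, s = self._displaced_ridge_setup(0.0)
        out, _, _ = refine_normals(pts, img, s, pixel_size_um=0.65)
        np.testing.assert_allclose(out[5:-5, 1], 15.0, atol=0.02)

    def test_fit_width_recovers_ridge_sigma(self):
        img, pts, s = self._displaced_ridge_setup(0.0)
        _, width_um, _ = refine_normals(pts, img, s, pixel_size_um=0.65)
        np.testing.assert_allclose(width_um[5:-5], 1.5 * 0.65, rtol=0.05)

    def test_smoothing_reduces_width_variance(self):
        rng = np.random.default_rng(4)
        img = gaussian_ridge((30, 80), 15.0, sigma=1.5, peak=1000.0)
        img = img + rng.normal(0, 60, img.shape)
        pts = np.column_stack([np.linspace(5, 75, 60), np.full(60, 15.0)])
        s = TraceSettings(exclude_head_from_correction=False)
        # raw per-point widths, before the smoothing stage
        from scipy import ndimage

        u = np.arange(-s.normal_radius_um / 0.65, s.normal_radius_um / 0.65 + 1e-9, 0.25)
        prof = ndimage.map_coordinates(
            img,
            [np.add.outer(pts[:, 1], u).ravel(), np.repeat(pts[:, 0], len(u))],
            order=1,
        ).reshape(len(pts), len(u))
        _, sig_raw, ok = _gaussian_center_fit(prof, u)
        _, width_um, _ = refine_normals(pts, img, s, pixel_size_um=0.65)
        assert np.nanvar(width_um[5:-5]) < np.nanvar(sig_raw[5:-5] * 0.65)

    def test_failed_fit_keeps_point_and_flags(self):
        img = np.zeros((30, 80))  # nothing to fit anywhere
        pts = np.column_stack([np.linspace(5, 75, 40), np.full(40, 15.0)])
        s = TraceSettings(exclude_head_from_correction=False)
        out, width, quality = refine_normals(pts, img, s, pixel_size_um=0.65)
        np.testing.assert_allclose(out, pts, atol=1e-9)
        assert np.all(quality == QUALITY_FIT_FAILED)


class TestTraceInvariants:
    def test_retrace_of_own_ridge_is_idempotent(self, beat_movie, beat_truth):
        """Rendering a traced midline and re-tracing reproduces it within 0.2 px."""
        p = beat_truth.params
        f1 = trace_frame(beat_movie.stack[0], pixel_size_um=p.pixel_size_um,
                         head_xy_px=tuple(beat_movie.meta["head_xy_px"]))
        pts1_um = np.column_stack([f1.x_um, f1.y_um])
        truth2 = dataclasses.replace(
            beat_truth,
            xy_um=pts1_um[None, :, :],
            t_s=np.array([0.0]),
            params=dataclasses.replace(p, n_frames=1, noise_sd=0.0),
        )
        movie2 = render_movie(truth2)
        f2 = trace_frame(movie2.stack[0], pixel_size_um=p.pixel_size_um,
                         head_xy_px=tuple(movie2.meta["head_xy_px"]))
        origin2 = np.array(movie2.meta["origin_px"]) * p.pixel_size_um
        pts2_um = np.column_stack([f2.x_um, f2.y_um]) + origin2
        span = (f2.arclen_um > 0.05 * f2.arclen_um[-1]) & (f2.arclen_um < 0.95 * f2.arclen_um[-1])
        d, _ = cKDTree(pts1_um).query(pts2_um[span])
        assert np.sqrt((d**2).mean()) / p.pixel_size_um < 0.2

    def test_length_stable_across_beat(self, beat_trace):
        lens = np.array([f.length_um for f in beat_trace.frames if f.ok])
        assert lens.std() < 0.03 * lens.mean()

    def test_unify_start_points_pins_head(self, beat_movie):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = trace_movie(beat_movie, TraceSettings(unify_start_points=True))
        heads = np.array([[f.x_um[0], f.y_um[0]] for f in tr.frames if f.ok])
        assert np.ptp(heads, axis=0).max() == 0.0
        assert all(f.arclen_um[0] == 0.0 for f in tr.frames if f.ok)

    def test_csv_roundtrip_exact(self, beat_trace, tmp_path):
        path = tmp_path / "trace.csv"
        write_trace_csv(beat_trace, path)
        back = read_trace_csv(path, beat_trace.pixel_size_um, beat_trace.frame_rate_hz)
        assert back.n_frames == beat_trace.n_ok
        f0 = next(f for f in beat_trace.frames if f.ok)
        b0 = back.frames[0]
        np.testing.assert_array_equal(b0.x_um, f0.x_um)
        np.testing.assert_array_equal(b0.arclen_um, f0.arclen_um)
        np.testing.assert_array_equal(b0.quality, f0.quality)
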