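"""Background, bleaching, stationary-object and segmentation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exospot import preprocess
from exospot.movie import CellMask, Movie

from conftest import make_movie


def _mask_like(movie, inside):
    m = np.zeros(movie.frame_shape, dtype=bool)
    m[inside] = True
    return CellMask(m, movie.pixel_size)


class TestSubtractBackground:
    def test_constant_offset_cancels_uniform_frame(self):
        movie = make_movie(np.full((2, 8, 8), 10.0))
        out = preprocess.subtract_background(movie, "constant", 10.0)
        assert np.array_equal(out.data, np.zeros_like(movie.data))

    def test_zero_offset_is_identity(self):
        movie = make_movie(np.full((2, 8, 8), 10.0))
        out = preprocess.subtract_background(movie, "constant", 0.0)
        assert np.array_equal(out.data, movie.data)

    def test_percentile_uses_outside_pixels(self):
        # inside pixels 20, outside pixels all 7 -> inside reduced by 7
        data = np.full((3, 10, 10), 7.0)
        data[:, 3:7, 3:7] = 20.0
        movie = make_movie(data)
        mask = _mask_like(movie, (slice(3, 7), slice(3, 7)))
        out = preprocess.subtract_background(movie, "percentile", 50.0, mask)
        assert np.allclose(out.data[:, 3:7, 3:7], 13.0)

    def test_full_mask_raises(self):
        movie = make_movie(np.ones((2, 4, 4)))
        mask = CellMask(np.ones((4, 4), dtype=bool), 0.1)
        with pytest.raises(ValueError, match="outside"):
            preprocess.subtract_background(movie, "percentile", 50.0, mask)

    def test_output_clipped_nonnegative(self):
        movie = make_movie(np.full((2, 4, 4), 3.0))
        out = preprocess.subtract_background(movie, "constant", 10.0)
        assert (out.data >= 0).all()


class TestHistogramMatch:
    def test_identical_frames_unchanged(self):
        rng = np.random.default_rng(0)
        frame = rng.random((32, 32)) * 50
        movie = make_movie(np.stack([frame] * 4))
        out = preprocess.histogram_match_to_first(movie)
        assert np.allclose(out.data, movie.data, atol=1e-9)

    def test_bleached_movie_distribution_restored(self):
        rng = np.random.default_rng(1)
        frame0 = rng.random((64, 64)) * 100 + 10
        data = np.stack([frame0 * 0.9**t for t in range(8)])
        out = preprocess.histogram_match_to_first(make_movie(data))
        span = np.ptp(frame0)
        for t in range(1, 8):
            assert np.allclose(np.sort(out.data[t].ravel()),
                               np.sort(frame0.ravel()), atol=1e-3 * span)

    def test_restores_per_frame_mean_within_one_percent(self):
        rng = np.random.default_rng(2)
        frame0 = rng.random((64, 64)) * 100 + 10
        data = np.stack([frame0 * 0.9**t for t in range(10)])
        out = preprocess.histogram_match_to_first(make_movie(data))
        ref_mean = out.data[0].mean()
        assert np.allclose(out.data.mean(axis=(1, 2)), ref_mean,
                           rtol=0.01)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        data = np.stack([rng.random((20, 20)) * (20 - t) for t in range(5)])
        out = preprocess.histogram_match_to_first(make_movie(data))
        for t in range(5):
            src = data[t].ravel()
            dst = out.data[t].ravel()
            order = np.argsort(src)
            assert (np.diff(dst[order]) >= -1e-12).all()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        data = np.stack([rng.random((128, 128)) * 80 * 0.95**t
                         for t in range(6)])
        once = preprocess.histogram_match_to_first(make_movie(data))
        twice = preprocess.histogram_match_to_first(once)
        # finite-sample quantile interpolation leaves a small residual
        tol = 2e-4 * np.ptp(once.data)
        assert np.allclose(twice.data, once.data, atol=tol)

    def test_constant_reference_frame_raises(self):
        data = np.ones((3, 8, 8))
        data[1:] *= 0.5
        with pytest.raises(ValueError, match="dynamic range"):
            preprocess.histogram_match_to_first(make_movie(data))


class TestRollingMedian:
    def test_constant_movie_zeroed(self):
        movie = make_movie(np.full((10, 6, 6), 4.2))
        out = preprocess.rolling_median_subtract(movie, window=5)
        assert np.array_equal(out.data[1:], np.zeros_like(out.data[1:]))
        assert np.array_equal(out.data[0], movie.data[0])

    def test_single_frame_spike_preserved_exactly(self):
        data = np.full((20, 8, 8), 3.0)
        data[10, 4, 4] += 7.5
        out = preprocess.rolling_median_subtract(make_movie(data), window=5)
        assert out.data[10, 4, 4] == pytest.approx(7.5)
        assert out.data[10].sum() == pytest.approx(7.5)

    def test_persistent_punctum_removed(self):
        rng = np.random.default_rng(5)
        data = np.full((15, 16, 16), 2.0)
        data[:, 8, 8] = 50.0  # punctum in every frame
        movie = make_movie(data)
        out = preprocess.rolling_median_subtract(movie, window=5)
        assert np.allclose(out.data[5:, 8, 8], 0.0)
        # brute-force pixelwise median oracle on random data
        noisy = rng.random((12, 5, 5))
        res = preprocess.rolling_median_subtract(make_movie(noisy), window=5)
        for t in range(5, 12):
            expect = np.clip(noisy[t] - np.median(noisy[t - 5:t], axis=0),
                             0, None)
            assert np.allclose(res.data[t], expect)

    @settings(deadline=None, max_examples=20)
    @given(offset=st.floats(min_value=0.0, max_value=100.0))
    def test_invariant_to_global_offset(self, offset):
        rng = np.random.default_rng(6)
        data = rng.random((9, 6, 6)) * 10 + 5
        base = preprocess.rolling_median_subtract(make_movie(data), window=3)
        shifted = preprocess.rolling_median_subtract(
            make_movie(data + offset), window=3)
        assert np.allclose(shifted.data[3:], base.data[3:], atol=1e-9)

    def test_too_short_movie_raises(self):
        with pytest.raises(ValueError, match="window"):
            preprocess.rolling_median_subtract(make_movie(np.ones((4, 4, 4))),
                                               window=5)


class TestBleedthrough:
    def test_zero_coefficient_identity(self):
        rng = np.random.default_rng(7)
        target = make_movie(rng.random((3, 8, 8)))
        source = make_movie(rng.random((3, 8, 8)))
        out = preprocess.bleedthrough_correct(target, source, 0.0)
        assert np.array_equal(out.data, target.data)

    def test_exact_bleed_removed(self):
        rng = np.random.default_rng(8)
        source = make_movie(rng.random((3, 8, 8)) * 100)
        target = make_movie(0.08 * source.data)
        out = preprocess.bleedthrough_correct(target, source, 0.08)
        assert np.allclose(out.data, 0.0)

    def test_true_signal_survives_bleed_removal(self):
        # a genuine event in the target plus 8% bleed of a source event
        yy, xx = np.mgrid[0:32, 0:32]
        src_spot = 200 * np.exp(-((xx - 10) ** 2 + (yy - 10) ** 2) / 8.0)
        true_spot = 80 * np.exp(-((xx - 22) ** 2 + (yy - 22) ** 2) / 8.0)
        source = make_movie(np.stack([src_spot] * 2))
        target = make_movie(np.stack([true_spot + 0.08 * src_spot] * 2))
        out = preprocess.bleedthrough_correct(target, source, 0.08)
        assert out.data[0, 22, 22] == pytest.approx(80.0, rel=1e-6)
        assert out.data[0, 10, 10] == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            preprocess.bleedthrough_correct(make_movie(np.ones((2, 4, 4))),
                                            make_movie(np.ones((2, 5, 5))))


class TestSegmentation:
    def test_disk_recovered_with_high_jaccard(self, disk_movie):
        mask = preprocess.segment_first_frame(disk_movie, blur_sigma=2.0)
        yy, xx = np.mgrid[0:128, 0:128]
        true = (yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2
        inter = (mask.mask & true).sum()
        union = (mask.mask | true).sum()
        assert inter / union >= 0.95

    def test_manual_threshold_zero_gives_full_frame(self):
        movie = make_movie(np.ones((2, 16, 16)) + np.eye(16))
        mask = preprocess.segment_first_frame(
            movie, method="manual_threshold", manual_threshold=0.0,
            min_size=1)
        assert mask.mask.all()

    def test_flat_frame_raises(self):
        with pytest.raises(ValueError, match="dynamic range"):
            preprocess.segment_first_frame(make_movie(np.zeros((2, 8, 8))))


def test_all_preprocessing_outputs_nonnegative(square_mask):
    rng = np.random.default_rng(9)
    data = np.clip(rng.normal(10, 3, size=(8, 200, 200)), 0, None)
    movie = make_movie(data)
    for out in (
        preprocess.subtract_background(movie, "constant", 5.0),
        preprocess.subtract_background(movie, "percentile", 50.0,
                                       _mask_like(movie, (slice(50, 150),
                                                          slice(50, 150)))),
        preprocess.histogram_match_to_first(movie),
        preprocess.rolling_median_subtract(movie, 3),
    ):
        assert (out.data >= 0).all()
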