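"""Event evaluation: crops, Gaussian fits, drift, curve fits, classification."""

import math

import numpy as np
import pytest

from exospot import events, synth
from exospot.detect import CandidateRegion
from exospot.movie import Movie

from conftest import make_movie


def gauss2d(shape, amp, x0, y0, sigma, offset):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                        / (2 * sigma**2)) + offset


def plateau_decay_trace(times, level, plateau_idx, rate, baseline=0.0):
    t_p = times[plateau_idx]
    out = np.full_like(times, level, dtype=float)
    late = times > t_p
    out[late] = (level - baseline) * np.exp(-rate * (times[late] - t_p)) \
        + baseline
    return out


class TestCropSeries:
    def _movie(self, n_frames=40):
        return make_movie(np.zeros((n_frames, 64, 64)) + 5.0)

    def test_candidate_at_movie_start_flagged(self):
        cand = CandidateRegion((30, 30), t0=0, peak_value=1.0)
        series = events.crop_series(self._movie(), cand,
                                    events.EvaluationParams())
        assert series.insufficient_background

    def test_mid_movie_bookkeeping(self):
        params = events.EvaluationParams(frames_before=10, frames_after=15)
        cand = CandidateRegion((30, 30), t0=20, peak_value=1.0)
        series = events.crop_series(self._movie(), cand, params)
        assert series.crop.shape == (26, 25, 25)
        assert series.rel_frames[0] == -10 and series.rel_frames[-1] == 15
        assert not series.insufficient_background

    def test_truncated_at_movie_end_retained(self):
        params = events.EvaluationParams(frames_before=5, frames_after=15)
        cand = CandidateRegion((30, 30), t0=35, peak_value=1.0)
        series = events.crop_series(self._movie(40), cand, params)
        assert series.truncated_end
        assert series.rel_frames[-1] == 4  # movie ends at frame 39


class TestLocalBackground:
    def _series(self, pre_values, post_value=9.0):
        n_pre = len(pre_values)
        crop = np.stack([np.full((25, 25), v) for v in pre_values]
                        + [np.full((25, 25), post_value)] * 3)
        rel = np.arange(-n_pre, 3)
        return events.EventSeries(crop=crop, raw_crop=crop.copy(),
                                  rel_frames=rel)

    def test_difference_channel_zeroes_preevent(self):
        s = self._series([4.0, 4.0, 4.0, 4.0])  # rel -4..-1
        events.local_background(s, "difference")
        assert s.background_level == pytest.approx(4.0)
        assert np.allclose(s.crop[0], 0.0)
        assert np.allclose(s.crop[-1], 5.0)  # amplitude preserved

    def test_elevated_t_minus_1_excluded(self):
        s = self._series([4.0, 4.0, 4.0, 50.0])  # t=-1 elevated
        events.local_background(s, "difference")
        assert s.background_level == pytest.approx(4.0)

    def test_median_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        crop = rng.random((8, 25, 25))
        rel = np.arange(-5, 3)
        s = events.EventSeries(crop=crop.copy(), raw_crop=crop.copy(),
                               rel_frames=rel)
        events.local_background(s, "intensity")
        expect = np.empty((25, 25))
        for i in range(25):
            for j in range(25):
                expect[i, j] = np.median(crop[:4, i, j])  # rel -5..-2
        assert np.allclose(s.background_image, expect)
        # intensity channel leaves pixels untouched
        assert np.array_equal(s.crop, crop)


class TestGaussianFit:
    def test_exact_gaussian_recovered(self):
        img = gauss2d((25, 25), 100.0, 12.3, 11.7, 2.0, 5.0)
        fit = events.fit_gaussian_frame(img, gaussian_r2_min=0.6)
        assert fit.r2 > 0.999 and fit.valid
        assert fit.center_xy[0] == pytest.approx(12.3, abs=1e-3)
        assert fit.center_xy[1] == pytest.approx(11.7, abs=1e-3)
        assert fit.amplitude == pytest.approx(100.0, abs=1e-2)
        assert fit.sigma == pytest.approx(2.0, abs=1e-3)
        assert fit.offset == pytest.approx(5.0, abs=1e-3)

    def test_constant_image_invalid(self):
        fit = events.fit_gaussian_frame(np.full((25, 25), 3.0))
        assert fit.r2 == 0.0 and not fit.valid

    def test_noisy_gaussian_center_within_fifth_pixel(self):
        rng = np.random.default_rng(1)
        img = gauss2d((25, 25), 100.0, 13.4, 10.2, 2.0, 5.0)
        img = img + rng.normal(0, 5.0, img.shape)  # 5% of amplitude
        fit = events.fit_gaussian_frame(img, gaussian_r2_min=0.6)
        assert fit.valid
        assert np.hypot(fit.center_xy[0] - 13.4,
                        fit.center_xy[1] - 10.2) < 0.2


class TestDrift:
    def _fit(self, x, y, valid=True):
        return events.GaussianFrameFit((x, y), 10, 2, 0, 0.9 if valid else 0,
                                       valid)

    def test_single_valid_frame_zero(self):
        assert events.compute_drift([self._fit(3, 4)]) == 0.0

    def test_three_four_five(self):
        assert events.compute_drift(
            [self._fit(0, 0), self._fit(3, 4)]) == pytest.approx(5.0)

    def test_invalid_frames_excluded_bruteforce(self):
        fits = [self._fit(0, 0), self._fit(1, 0), self._fit(0, 2),
                self._fit(5, 5, valid=False)]
        valid_pts = [(0, 0), (1, 0), (0, 2)]
        expect = max(math.dist(a, b) for a in valid_pts for b in valid_pts)
        assert events.compute_drift(fits) == pytest.approx(expect)
        assert events.compute_drift(fits) == pytest.approx(2.2360679, abs=1e-6)

    def test_no_valid_fits_raises(self):
        with pytest.raises(ValueError):
            events.compute_drift([self._fit(0, 0, valid=False)])


class TestPlateauDecayFit:
    params = events.EvaluationParams()

    def test_pure_decay_noiseless(self):
        t = np.arange(20.0)
        fit = events.fit_plateau_decay(10 * np.exp(-0.5 * t), t, self.params)
        assert fit.plateau_frames == 0
        assert fit.decay_rate == pytest.approx(0.5, rel=0.01)
        assert fit.r2 > 0.999

    def test_plateau_then_decay_noiseless(self):
        t = np.arange(25.0)
        trace = plateau_decay_trace(t, 10.0, 5, 1.0)
        fit = events.fit_plateau_decay(trace, t, self.params)
        assert fit.plateau_frames == 5
        assert fit.decay_rate == pytest.approx(1.0, rel=0.01)
        assert fit.plateau_level == pytest.approx(10.0, rel=0.01)

    def test_half_life_identity(self):
        t = np.arange(15.0)
        fit = events.fit_plateau_decay(8 * np.exp(-math.log(2) * t), t,
                                       self.params)
        assert fit.half_life == pytest.approx(1.0, rel=0.01)
        assert fit.half_life * fit.decay_rate == pytest.approx(math.log(2),
                                                               abs=1e-12)

    def test_winning_plateau_never_worse_than_pure_decay(self):
        # argmax property: the selected plateau's r2 dominates the r2 of an
        # independent plateau-free exponential fit of the same trace
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(2)
        t = np.arange(20.0)
        for _ in range(5):
            trace = plateau_decay_trace(t, 10.0, int(rng.integers(0, 8)),
                                        0.7) + rng.normal(0, 0.5, t.size)
            best = events.fit_plateau_decay(trace, t, self.params)
            popt, _ = curve_fit(
                lambda x, a, k, b: a * np.exp(-k * x) + b, t, trace,
                p0=[trace[0], 0.5, 0.0], bounds=([0, 1e-9, 0], [np.inf] * 3),
                maxfev=5000)
            resid = trace - (popt[0] * np.exp(-popt[1] * t) + popt[2])
            r2_decay = 1 - (resid**2).sum() / ((trace - trace.mean())**2).sum()
            assert best.converged
            assert best.r2 >= r2_decay - 1e-9

    def test_baseline_floor_respected(self):
        t = np.arange(20.0)
        trace = plateau_decay_trace(t, 10.0, 0, 0.8, baseline=2.0)
        p = events.EvaluationParams(min_intensity_for_fit=1.5)
        fit = events.fit_plateau_decay(trace, t, p)
        assert fit.baseline >= 1.5
        assert fit.baseline == pytest.approx(2.0, rel=0.05)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            events.fit_plateau_decay(np.ones(3), np.arange(3.0), self.params)


class TestManualOverrides:
    def _records(self, n=4):
        recs = []
        for i in range(n):
            r = events.EventRecord(candidate=CandidateRegion((0, 0), 0, 1.0))
            r.event_id = i
            r.status = "rejected" if i % 2 else "true_event"
            recs.append(r)
        return recs

    def test_empty_overrides_identity(self):
        recs = self._records()
        before = [(r.status, r.flag) for r in recs]
        events.apply_manual_overrides(recs)
        assert [(r.status, r.flag) for r in recs] == before

    def test_include_flips_one_record(self):
        recs = self._records()
        events.apply_manual_overrides(recs, include_ids=[1])
        assert recs[1].status == "true_event" and recs[1].flag == "manual"
        assert recs[3].status == "rejected"

    def test_overlapping_ids_raise(self):
        with pytest.raises(ValueError, match="both"):
            events.apply_manual_overrides(self._records(), [1], [1])

    def test_unknown_id_raises_with_id_listed(self):
        with pytest.raises(ValueError, match="99"):
            events.apply_manual_overrides(self._records(), [99])


class TestFrequency:
    def test_arithmetic(self, square_mask):
        movie = make_movie(np.zeros((240, 4, 4)), frame_interval=0.5)
        # 240 frames x 0.5 s = 2 min; square mask 200x200 px at 0.1 um = 400 um2
        assert events.exocytic_frequency(10, square_mask, movie) == \
            pytest.approx(10 / (400 * 2))

    def test_zero_events(self, square_mask):
        movie = make_movie(np.zeros((10, 4, 4)))
        assert events.exocytic_frequency(0, square_mask, movie) == 0.0

    def test_spec_worked_example(self, square_mask):
        # 30 events over 150 frames at 0.1 s/frame = 0.25 min in 250 um2
        movie = make_movie(np.zeros((150, 4, 4)), frame_interval=0.1)
        area_scale = 250.0 / square_mask.area_um2
        freq = events.exocytic_frequency(30, square_mask, movie)
        assert freq / area_scale == pytest.approx(0.48)


class TestClassification:
    def test_rejections_carry_exactly_one_flag(self, benchmark):
        for r in benchmark["records"]:
            if r.status == "true_event":
                assert r.flag == "none"
            else:
                assert r.flag in events.FLAGS and r.flag != "none"

    def test_order_independent(self, benchmark):
        movie = benchmark["intensity_movie"]
        cands = list(reversed(benchmark["candidates"]))[:6]
        params = events.EvaluationParams()
        a = [events.evaluate_candidate(movie, c, params).status
             for c in cands]
        b = [events.evaluate_candidate(movie, c, params).status
             for c in reversed(cands)]
        assert a == list(reversed(b))

    def test_low_intensity_flag(self):
        # stationary burst at only ~3x background with fourfold required
        truth = synth.GroundTruth(noise_sd=0.5, bleach_rate=0.0, seed=3)
        truth.events.append(synth.PlantedEvent(
            x=32, y=32, t0=10, amplitude=2.0 * truth.background,
            plateau_frames=2, decay_rate=0.5))
        movie, mask, _ = synth.simulate_movie(truth, (30, 64, 64))
        cand = CandidateRegion((32, 32), 10, 1.0)
        rec = events.evaluate_candidate(movie, cand,
                                        events.EvaluationParams())
        assert rec.status == "rejected" and rec.flag == "low_intensity"

    def test_moving_vesicle_rejected_with_drift_flag(self):
        truth = synth.GroundTruth(noise_sd=0.5, bleach_rate=0.0, seed=4)
        truth.movers.append(synth.Mover(x=20, y=32, t_start=10, n_frames=12,
                                        velocity=(2.0, 0.0),
                                        amplitude=6.0 * truth.background))
        movie, mask, _ = synth.simulate_movie(truth, (40, 64, 64))
        cand = CandidateRegion((28, 32), 10, 1.0)
        rec = events.evaluate_candidate(movie, cand,
                                        events.EvaluationParams())
        assert rec.status == "rejected" and rec.flag == "drift"

    def test_clean_burst_accepted_with_recovered_kinetics(self):
        truth = synth.GroundTruth(noise_sd=0.5, bleach_rate=0.0, seed=5)
        truth.events.append(synth.PlantedEvent(
            x=32, y=32, t0=10, amplitude=8.0 * truth.background,
            plateau_frames=3, decay_rate=0.8))
        movie, mask, _ = synth.simulate_movie(truth, (40, 64, 64))
        cand = CandidateRegion((32, 32), 10, 1.0)
        rec = events.evaluate_candidate(movie, cand,
                                        events.EvaluationParams())
        assert rec.status == "true_event"
        assert rec.fit.plateau_frames == 3
        assert rec.fit.decay_rate == pytest.approx(0.8, rel=0.15)
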