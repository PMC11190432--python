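"""Per-candidate evaluation and classification of exocytic events.

A fusion event is the transient appearance of a Gaussian-profile spot that
stays put (minimal x-y drift) and decays exponentially.  Each candidate from
the detector is evaluated on a small cropped image series:

* crop 25×25 px around the seed, a few frames before/after detection,
  smoothed with a 1-px Gaussian;
* local background = pixelwise median of frames t <= -2 (t = -1 is excluded
  because it often already carries elevated fluorescence);
* an isotropic 2D Gaussian is fitted to every frame; frames whose fit R²
  clears a per-cell-type threshold are "valid", and drift is the maximum
  pairwise distance between valid-frame centers;
* the intensity trace from t = 0 is fitted with a plateau followed by an
  exponential decay, searching all plateau lengths and keeping the best R²;
  half-life = ln(2) / decay rate.

Candidates failing any rule are rejected with a single diagnostic flag so
that parameters can be tuned and failures audited; a manual override can
flip individual calls before downstream spatiotemporal analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .detect import CandidateRegion
from .movie import CellMask, Movie

FLAGS = ("none", "low_intensity", "drift", "short_duration",
         "poor_gaussian_fit", "poor_function_fit", "insufficient_background",
         "manual")


@dataclass
class EvaluationParams:
    """Tunable event-evaluation parameters (one set per cell type / dataset).

    Defaults follow the cortical-neuron settings: crop 25×25 px, 1-px
    smoothing, Gaussian-fit R² >= 0.6, function-fit R² >= 0.7, fourfold
    intensity above background, three frames above background.
    ``channel`` selects whether the trace that is fitted is background
    subtracted ("difference") or raw ("intensity"); ``intensity_measure``
    selects max vs mean over the central fitting region.  ``drift_min`` > 0
    can be used to reject zero-drift shot noise.
    """

    crop_size: int = 25
    frames_before: int = 10
    frames_after: int = 15
    smooth_sigma: float = 1.0
    channel: str = "difference"
    gaussian_r2_min: float = 0.6
    drift_min: float = 0.0
    drift_max: float = 2.0
    fit_r2_min: float = 0.7
    min_frames_above_background: int = 3
    fold_above_background: float = 4.0
    min_intensity_for_fit: float = 0.0
    intensity_measure: str = "maximum"

    def __post_init__(self) -> None:
        if self.crop_size < 7 or self.crop_size % 2 == 0:
            raise ValueError("crop_size must be odd and >= 7")
        if not (0 <= self.gaussian_r2_min <= 1 and 0 <= self.fit_r2_min <= 1):
            raise ValueError("R² thresholds must lie in [0, 1]")
        if self.drift_min < 0 or self.drift_max <= self.drift_min:
            raise ValueError("need 0 <= drift_min < drift_max")
        if not self.fold_above_background > 1:
            raise ValueError("fold_above_background must exceed 1")
        if self.channel not in ("intensity", "difference"):
            raise ValueError("channel must be 'intensity' or 'difference'")
        if self.intensity_measure not in ("maximum", "average"):
            raise ValueError("intensity_measure must be 'maximum' or 'average'")


@dataclass
class EventSeries:
    """Cropped, smoothed image series around one candidate."""

    crop: np.ndarray          # (n, crop, crop), smoothed; bg-subtracted if channel="difference"
    raw_crop: np.ndarray      # smoothed but never background-subtracted
    rel_frames: np.ndarray    # frame index relative to t0 (detection = 0)
    background_image: np.ndarray | None = None
    background_level: float = 0.0
    truncated_start: bool = False
    truncated_end: bool = False
    insufficient_background: bool = False


@dataclass
class GaussianFrameFit:
    center_xy: tuple[float, float]
    amplitude: float
    sigma: float
    offset: float
    r2: float
    valid: bool


@dataclass
class PlateauDecayFit:
    plateau_frames: int
    plateau_level: float
    decay_rate: float
    baseline: float
    r2: float
    half_life: float
    converged: bool = True


@dataclass
class EventRecord:
    """Full evaluation of one candidate, with status and diagnostic flag."""

    candidate: CandidateRegion
    series: EventSeries | None = None
    frame_fits: list[GaussianFrameFit] = field(default_factory=list)
    drift: float = float("nan")
    trace: np.ndarray | None = None
    raw_trace: np.ndarray | None = None
    fit: PlateauDecayFit | None = None
    status: str = "rejected"
    flag: str = "none"
    peak_intensity: float = float("nan")
    fold_above_background: float = float("nan")
    frames_above_background: int = 0
    duration_s: float = float("nan")
    event_id: int = -1


def central_slice(crop_size: int) -> slice:
    """Central fitting region: middle third of the crop window."""
    third = crop_size // 3
    lo = (crop_size - third) // 2
    return slice(lo, lo + third)


def crop_series(movie: Movie, candidate: CandidateRegion,
                params: EvaluationParams) -> EventSeries:
    """Crop and smooth a small series centered on the candidate seed.

    Frames t0-frames_before … t0+frames_after are taken (truncated at movie
    boundaries and the truncation recorded); each frame is smoothed with a
    `smooth_sigma`-px Gaussian.  Candidates near the movie start with fewer
    than two usable pre-detection frames (t <= -2) are flagged: no reliable
    local background can be established for them.
    """
    x, y = candidate.seed_xy
    half = params.crop_size // 2
    if not (half <= y < movie.data.shape[1] - half
            and half <= x < movie.data.shape[2] - half):
        raise ValueError("crop window does not fit inside the frame; "
                         "increase the detector border exclusion")
    t_lo = candidate.t0 - params.frames_before
    t_hi = candidate.t0 + params.frames_after
    truncated_start = t_lo < 0
    truncated_end = t_hi > movie.n_frames - 1
    t_lo = max(t_lo, 0)
    t_hi = min(t_hi, movie.n_frames - 1)
    block = movie.data[t_lo:t_hi + 1,
                       y - half:y + half + 1,
                       x - half:x + half + 1]
    crop = np.stack([ndimage.gaussian_filter(f, params.smooth_sigma)
                     for f in block])
    rel = np.arange(t_lo, t_hi + 1) - candidate.t0
    insufficient = int(np.sum(rel <= -2)) < 2
    return EventSeries(crop=crop, raw_crop=crop.copy(), rel_frames=rel,
                       truncated_start=truncated_start,
                       truncated_end=truncated_end,
                       insufficient_background=insufficient)


def local_background(series: EventSeries, channel: str = "difference") -> EventSeries:
    """Estimate and (for the difference channel) subtract local background.

    background_image is the pixelwise median over frames t <= -2; t = -1 is
    excluded because fluorescence is often already elevated there.
    background_level is the mean of background_image over the central
    fitting region.  The "intensity" channel keeps pixels unmodified but
    still records the level.
    """
    pre = series.rel_frames <= -2
    if int(pre.sum()) < 2:
        series.insufficient_background = True
        return series
    bg = np.median(series.raw_crop[pre], axis=0)
    c = central_slice(series.crop.shape[1])
    series.background_image = bg
    series.background_level = float(bg[c, c].mean())
    if channel == "difference":
        series.crop = series.raw_crop - bg[None]
    else:
        series.crop = series.raw_crop.copy()
    return series


def _gauss2d(coords, amplitude, x0, y0, sigma, offset):
    x, y = coords
    return (amplitude * np.exp(-((x - x0) ** 2 + (y - y0) ** 2)
                               / (2.0 * sigma**2)) + offset).ravel()


def fit_gaussian_frame(image: np.ndarray,
                       gaussian_r2_min: float = 0.6) -> GaussianFrameFit:
    """Least-squares isotropic 2D Gaussian fit to one cropped frame.

    Initialization at the brightest pixel; returns subpixel center,
    amplitude, sigma, constant offset and R².  Non-convergence or a
    structureless frame yields R² = 0 / invalid.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    flat = image.ravel()
    ss_tot = float(((flat - flat.mean()) ** 2).sum())
    invalid = GaussianFrameFit((np.nan, np.nan), 0.0, 0.0, 0.0, 0.0, False)
    if ss_tot == 0:
        return invalid
    iy, ix = np.unravel_index(np.argmax(image), image.shape)
    p0 = [image[iy, ix] - image.min(), float(ix), float(iy), 2.0,
          float(image.min())]
    bounds = ([0.0, -1.0, -1.0, 0.3, -np.inf],
              [np.inf, nx, ny, max(nx, ny), np.inf])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = optimize.curve_fit(_gauss2d, (xx, yy), flat, p0=p0,
                                     bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        return invalid
    resid = flat - _gauss2d((xx, yy), *popt)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    amplitude, x0, y0, sigma, offset = popt
    return GaussianFrameFit((float(x0), float(y0)), float(amplitude),
                            float(sigma), float(offset), r2,
                            r2 >= gaussian_r2_min)


def compute_drift(fits: list[GaussianFrameFit]) -> float:
    """Maximum pairwise distance between valid-frame Gaussian centers (px)."""
    centers = np.array([f.center_xy for f in fits if f.valid], dtype=float)
    if len(centers) == 0:
        raise ValueError("no valid Gaussian fits to compute drift from")
    if len(centers) == 1:
        return 0.0
    d = centers[:, None, :] - centers[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def _plateau_decay(t, level, baseline, rate, t_p):
    out = np.full_like(t, level, dtype=float)
    late = t > t_p
    out[late] = (level - baseline) * np.exp(-rate * (t[late] - t_p)) + baseline
    return out


def fit_plateau_decay(trace: np.ndarray, times: np.ndarray,
                      params: EvaluationParams) -> PlateauDecayFit:
    """Fit a constant plateau followed by an exponential decay.

    The plateau length is not known a priori: every plateau of p frames
    (decay starting after ``times[p]``) for p = 0 … n-2 is fitted by
    bounded least squares (level, baseline >= min_intensity_for_fit,
    rate > 0) and the plateau maximizing R² over the whole trace wins; exact
    ties go to the shorter plateau.  The decay need not reach zero — the
    baseline floor models residual membrane fluorescence.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.size < 4:
        raise ValueError("plateau+decay fit needs at least 4 points")
    ss_tot = float(((trace - trace.mean()) ** 2).sum())
    n = trace.size
    best: PlateauDecayFit | None = None
    span = max(times[-1] - times[0], 1e-9)
    bmin = params.min_intensity_for_fit
    for p in range(n - 1):
        t_p = times[p]
        level0 = float(trace[:p + 1].mean())
        base0 = max(float(trace[-1]), bmin)
        amp = level0 - base0
        rate0 = 3.0 / max(span - t_p, 1e-9) if amp > 0 else 1.0 / span

        def model(t, level, baseline, rate, t_p=t_p):
            return _plateau_decay(t, level, baseline, rate, t_p)

        try:
            popt, _ = optimize.curve_fit(
                model, times, trace,
                p0=[level0, max(base0, bmin), max(rate0, 1e-3)],
                bounds=([-np.inf, bmin, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        resid = trace - model(times, *popt)
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        if best is None or r2 > best.r2 + 1e-12:
            level, baseline, rate = (float(v) for v in popt)
            best = PlateauDecayFit(p, level, rate, baseline, r2,
                                   math.log(2.0) / rate)
    if best is None:
        return PlateauDecayFit(0, float("nan"), float("nan"), float("nan"),
                               0.0, float("nan"), converged=False)
    return best


def _frames_above_background(raw_trace: np.ndarray, rel: np.ndarray,
                             background_level: float) -> int:
    """Consecutive frames from t = 0 above background + 2 robust noise sd."""
    pre = rel <= -2
    pre_vals = raw_trace[pre]
    mad = np.median(np.abs(pre_vals - np.median(pre_vals)))
    noise_sd = 1.4826 * mad
    thr = background_level + 2.0 * noise_sd
    count = 0
    for v in raw_trace[rel >= 0]:
        if v > thr:
            count += 1
        else:
            break
    return count


def measure_trace(crop: np.ndarray, intensity_measure: str) -> np.ndarray:
    """Per-frame intensity measure over the central fitting region."""
    c = central_slice(crop.shape[1])
    block = crop[:, c, c]
    if intensity_measure == "maximum":
        return block.max(axis=(1, 2))
    return block.mean(axis=(1, 2))


def evaluate_candidate(movie: Movie, candidate: CandidateRegion,
                       params: EvaluationParams) -> EventRecord:
    """Run the full evaluation chain for one candidate and classify it.

    Rules are checked in a fixed precedence order, and the first failure
    becomes the record's flag: sufficient background frames, a valid
    Gaussian fit at t = 0, fold-above-background intensity, duration,
    drift bounds, and finally the plateau+decay goodness of fit.
    """
    record = EventRecord(candidate=candidate)
    series = crop_series(movie, candidate, params)
    record.series = series
    if series.insufficient_background:
        record.flag = "insufficient_background"
        return record
    local_background(series, params.channel)

    record.frame_fits = [fit_gaussian_frame(f, params.gaussian_r2_min)
                         for f in series.crop]
    i0 = int(np.flatnonzero(series.rel_frames == 0)[0])
    record.raw_trace = measure_trace(series.raw_crop, params.intensity_measure)
    record.trace = measure_trace(series.crop, params.intensity_measure)

    if not record.frame_fits[i0].valid:
        record.flag = "poor_gaussian_fit"
        return record

    event_sel = series.rel_frames >= 0
    record.peak_intensity = float(record.raw_trace[event_sel].max())
    bg = series.background_level
    record.fold_above_background = (record.peak_intensity / bg if bg > 0
                                    else float("inf"))
    if record.fold_above_background < params.fold_above_background:
        record.flag = "low_intensity"
        return record

    record.frames_above_background = _frames_above_background(
        record.raw_trace, series.rel_frames, series.background_level)
    if record.frames_above_background < params.min_frames_above_background:
        record.flag = "short_duration"
        return record

    # drift is measured over the event's own duration: once fluorescence has
    # returned to background the Gaussian center no longer tracks the event,
    # and an unrelated object entering the crop would corrupt the statistic
    window_end = max(record.frames_above_background - 1, 0)
    event_fits = [f for f, r in zip(record.frame_fits, series.rel_frames)
                  if 0 <= r <= window_end]
    record.drift = compute_drift(event_fits)
    if not params.drift_min <= record.drift <= params.drift_max:
        record.flag = "drift"
        return record

    times = series.rel_frames[event_sel] * movie.frame_interval
    record.fit = fit_plateau_decay(record.trace[event_sel], times, params)
    if not record.fit.converged or record.fit.r2 < params.fit_r2_min:
        record.flag = "poor_function_fit"
        return record

    record.status = "true_event"
    record.flag = "none"
    # duration: plateau dwell plus three decay half-lives, alongside the raw
    # frames-above-background count
    record.duration_s = (record.fit.plateau_frames * movie.frame_interval
                         + 3.0 * record.fit.half_life)
    return record


def evaluate_all(movie: Movie, candidates: list[CandidateRegion],
                 params: EvaluationParams) -> list[EventRecord]:
    """Evaluate every candidate independently (order has no effect)."""
    records = []
    for i, cand in enumerate(candidates):
        rec = evaluate_candidate(movie, cand, params)
        rec.event_id = i
        records.append(rec)
    return records


def apply_manual_overrides(records: list[EventRecord],
                           include_ids: list[int] = (),
                           exclude_ids: list[int] = ()) -> list[EventRecord]:
    """Flip individual automated calls; the curated list feeds downstream.

    `include_ids` force records to true_event, `exclude_ids` to rejected;
    both get the flag ``manual``.  Unknown or overlapping ids raise.
    """
    include, exclude = set(include_ids), set(exclude_ids)
    overlap = include & exclude
    if overlap:
        raise ValueError(f"ids in both include and exclude: {sorted(overlap)}")
    known = {r.event_id for r in records}
    unknown = (include | exclude) - known
    if unknown:
        raise ValueError(f"unknown event ids: {sorted(unknown)}")
    for rec in records:
        if rec.event_id in include:
            rec.status, rec.flag = "true_event", "manual"
        elif rec.event_id in exclude:
            rec.status, rec.flag = "rejected", "manual"
    return records


def exocytic_frequency(n_events: int, mask: CellMask, movie: Movie) -> float:
    """Event frequency in events / µm² / min."""
    duration_min = movie.duration_s / 60.0
    if mask.area_um2 <= 0 or duration_min <= 0:
        raise ValueError("mask area and movie duration must be positive")
    return n_events / (mask.area_um2 * duration_min)
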