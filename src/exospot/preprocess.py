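"""Movie preprocessing: background, photobleaching, stationary structure.

The goal of this stage is to leave only transient, localized fluorescence on
a near-zero background so that a band-pass detector can find candidate
fusion events.  Steps (each independently callable):

1. background subtraction (camera offset or diffuse extracellular signal),
2. photobleach correction by histogram matching every frame to frame 0,
3. removal of stationary bright structures by subtracting a rolling-window
   median projection of the preceding frames,
4. optional spectral bleed-through correction for dual-channel imaging,
5. cell segmentation on the first frame.

All outputs are floating point and clipped at zero — negative intensities
would make downstream fold-above-background criteria meaningless.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .movie import CellMask, Movie


def subtract_background(movie: Movie, mode: str = "percentile",
                        value: float = 50.0,
                        mask: CellMask | None = None) -> Movie:
    """Subtract a background offset from every frame, clipping at zero.

    Parameters
    ----------
    mode
        ``"constant"``: subtract `value` from every pixel.
        ``"percentile"``: per frame, subtract the `value`-th percentile of
        the pixels *outside* the cell mask (extracellular background).
    value
        Offset (``constant``) or percentile in (0, 100) (``percentile``).
    mask
        Required for percentile mode.
    """
    if mode == "constant":
        if value < 0:
            raise ValueError("constant offset must be >= 0")
        out = movie.data - value
    elif mode == "percentile":
        if not 0 < value < 100:
            raise ValueError("percentile must be in (0, 100)")
        if mask is None:
            raise ValueError("percentile mode needs a cell mask")
        outside = ~mask.mask
        if not outside.any():
            raise ValueError("mask covers the entire frame: no outside "
                             "pixels to estimate background from")
        offsets = np.percentile(movie.data[:, outside], value, axis=1)
        out = movie.data - offsets[:, None, None]
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return movie.with_data(np.clip(out, 0.0, None))


def histogram_match_to_first(movie: Movie, bins: int = 1024,
                             tail_quantile: float = 0.95) -> Movie:
    """Photobleach correction: match every frame's intensity histogram to frame 0.

    Implemented as monotone quantile mapping over `bins` quantile levels:
    frame t's empirical quantile function is mapped onto frame 0's, which
    preserves pixel rank order within each frame while restoring the global
    intensity distribution lost to bleaching.

    The mapping is estimated on quantiles up to `tail_quantile` and extended
    linearly above it.  The extreme tail is populated by transient bright
    spots whose number varies frame to frame; mapping it quantile-to-quantile
    would compress exactly the amplitudes the pipeline later quantifies,
    while the bulk of the distribution carries the bleaching signal.  For a
    purely rescaled frame the linear extension is exact.
    """
    if movie.n_frames < 2:
        raise ValueError("histogram matching needs at least 2 frames")
    if not 0 < tail_quantile <= 1:
        raise ValueError("tail_quantile must be in (0, 1]")
    ref = movie.data[0]
    if np.ptp(ref) == 0:
        raise ValueError("frame 0 has zero dynamic range; cannot serve as "
                         "histogram-matching reference")
    q = np.linspace(0.0, tail_quantile, bins)
    ref_q = np.quantile(ref, q)
    out = np.empty_like(movie.data)
    out[0] = ref
    for t in range(1, movie.n_frames):
        frame = movie.data[t]
        src_q = np.quantile(frame, q)
        mapped = np.interp(frame, src_q, ref_q)
        above = frame > src_q[-1]
        if above.any():
            # linear tail: slope estimated over a wide upper-quantile span
            # (adjacent empirical quantiles are far too noisy for a ratio)
            i = int(np.searchsorted(q, 0.9 * tail_quantile))
            i = min(max(i, 0), bins - 2)
            denom = src_q[-1] - src_q[i]
            slope = (ref_q[-1] - ref_q[i]) / denom if denom > 0 else 1.0
            mapped[above] = ref_q[-1] + slope * (frame[above] - src_q[-1])
        out[t] = mapped
    return movie.with_data(np.clip(out, 0.0, None))


def rolling_median_subtract(movie: Movie, window: int = 5) -> Movie:
    """Remove stationary bright objects by subtracting a trailing median.

    Frame t (t >= window) has the pixelwise median of frames t-window … t-1
    subtracted; early frames use whatever preceding frames exist, and frame 0
    passes through unmodified (it has no temporal reference).  Output is
    clipped at zero.  Persistent puncta and the static cell baseline vanish;
    transients survive because they are absent from their own recent past.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if movie.n_frames <= window:
        raise ValueError(f"movie must have more than window={window} frames")
    out = np.empty_like(movie.data)
    out[0] = movie.data[0]
    for t in range(1, movie.n_frames):
        lo = max(0, t - window)
        med = np.median(movie.data[lo:t], axis=0)
        out[t] = np.clip(movie.data[t] - med, 0.0, None)
    return movie.with_data(out)


def bleedthrough_correct(target: Movie, source: Movie,
                         coefficient: float = 0.08) -> Movie:
    """Subtract `coefficient` × source channel from the target channel.

    In dual-color imaging a fraction (~8% for sepHluorin into pHmScarlet) of
    one channel's signal leaks into the other; removing it prevents spurious
    cross-channel detections.
    """
    if target.data.shape != source.data.shape:
        raise ValueError("target and source movies must have the same shape, "
                         f"got {target.data.shape} vs {source.data.shape}")
    if not 0 <= coefficient < 1:
        raise ValueError("bleed-through coefficient must be in [0, 1)")
    out = np.clip(target.data - coefficient * source.data, 0.0, None)
    return target.with_data(out)


def segment_first_frame(movie: Movie, blur_sigma: float = 2.0,
                        method: str = "otsu",
                        manual_threshold: float | None = None,
                        min_size: int = 64) -> CellMask:
    """Segment the cell on frame 0 (movies are short; shape change is ignored).

    Frame 0 is Gaussian-blurred, thresholded (Otsu or a manual threshold),
    small components below `min_size` pixels are dropped, the largest
    connected component is kept and its holes are filled.  A user-supplied
    mask file always takes precedence over this convenience in the pipeline.
    """
    frame = movie.data[0]
    if np.ptp(frame) == 0:
        raise ValueError("frame 0 has zero dynamic range; supply a manual mask")
    blurred = ndimage.gaussian_filter(frame, blur_sigma)
    if method == "otsu":
        thr = threshold_otsu(blurred)
    elif method == "manual_threshold":
        if manual_threshold is None:
            raise ValueError("manual_threshold method requires a threshold value")
        thr = manual_threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    binary = blurred >= thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("segmentation produced an empty mask; "
                         "supply a manual mask instead")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    if keep.size == 0:
        raise ValueError("all segmented components are below min_size; "
                         "supply a manual mask instead")
    largest = keep[np.argmax(sizes[keep - 1])]
    mask = ndimage.binary_fill_holes(labels == largest)
    return CellMask(mask, movie.pixel_size)
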