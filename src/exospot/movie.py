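"""Core containers for calibrated timelapse movies and cell masks.

A :class:`Movie` is a (frames, rows, cols) floating-point stack with physical
calibration.  Intensities are kept as floats throughout the pipeline —
quantizing to integers destroys the dynamic range that threshold tuning and
fold-change criteria depend on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class Movie:
    """A single-channel fluorescence timelapse.

    Parameters
    ----------
    data
        Intensity stack, shape (frames, rows, cols).  Converted to float64
        on construction; integer camera counts are accepted but never kept.
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Time between frames in seconds.
    channel_name
        Free-text label (e.g. ``"sepHluorin"``).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("movie data must be a 3D (frames, rows, cols) array "
                             f"with at least one frame, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("movie contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (µm/pixel)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive (seconds)")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        """Total observation span in seconds."""
        return self.n_frames * self.frame_interval

    def with_data(self, data: np.ndarray) -> "Movie":
        """Copy of this movie with new pixel data, same calibration."""
        return replace(self, data=data)


@dataclass
class CellMask:
    """Boolean raster marking the segmented cell on one frame."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {m.shape}")
        if not m.any():
            raise ValueError("mask is empty: no interior pixels")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (µm/pixel)")
        self.mask = m

    @property
    def area_um2(self) -> float:
        """Mask area: pixel count × pixel_size²."""
        return float(self.mask.sum()) * self.pixel_size**2

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_movie(path, pixel_size: float, frame_interval: float,
               channel_name: str = "") -> Movie:
    """Load a multi-page TIFF stack as a calibrated float movie."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return Movie(arr, pixel_size, frame_interval, channel_name)


def write_movie(path, movie: Movie) -> None:
    """Write a movie as a floating-point (float32) multi-page TIFF."""
    tifffile.imwrite(path, movie.data.astype(np.float32))


def read_mask(path, pixel_size: float) -> CellMask:
    """Load a mask image (TIFF or PNG); nonzero pixels are inside."""
    import imageio.v3 as iio

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        arr = iio.imread(p)
    if arr.ndim == 3:  # RGB(A) PNG: any channel nonzero
        arr = arr.max(axis=-1)
    return CellMask(arr != 0, pixel_size)


def write_mask(path, mask: CellMask) -> None:
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
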