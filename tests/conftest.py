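"""Shared fixtures: synthetic movies and masks, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from exospot import detect, events, preprocess, spatial, synth
from exospot.movie import CellMask, Movie


@pytest.fixture(scope="session")
def benchmark():
    """The standard 200-frame benchmark movie run through the full chain.

    Expensive (simulation + preprocessing + DoG + evaluation), so computed
    once per session and shared by detection, classification and acceptance
    tests.
    """
    import time

    t_start = time.perf_counter()
    shape = (200, 256, 256)
    truth, mask = synth.default_benchmark_truth(shape, seed=7)
    movie, mask, truth = synth.simulate_movie(truth, shape, mask=mask)
    m = preprocess.subtract_background(movie, "percentile", 50, mask)
    m = preprocess.histogram_match_to_first(m)
    det_movie = preprocess.rolling_median_subtract(m, 5)
    dog = detect.compute_dog_trace(det_movie, mask,
                                   detect.DoGParams(sigma0=2.0,
                                                    threshold_scale=1.0))
    candidates = detect.extract_candidates(dog, mask)
    records = events.evaluate_all(m, candidates, events.EvaluationParams())
    elapsed = time.perf_counter() - t_start
    return {"truth": truth, "mask": mask, "movie": movie,
            "intensity_movie": m, "dog": dog, "candidates": candidates,
            "records": records, "elapsed_s": elapsed}


@pytest.fixture()
def square_mask():
    return CellMask(np.ones((200, 200), dtype=bool), pixel_size=0.1)


@pytest.fixture()
def disk_movie():
    """A 3-frame movie whose frame 0 is a bright disk on dark background."""
    yy, xx = np.mgrid[0:128, 0:128]
    disk = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2).astype(float) * 100.0
    data = np.stack([disk + 5.0] * 3)
    return Movie(data, pixel_size=0.1, frame_interval=0.5)


def make_movie(data, pixel_size=0.1, frame_interval=0.5):
    return Movie(np.asarray(data, dtype=float), pixel_size, frame_interval)
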