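"""Detect exocytic fusion events in a synthetic TIRF-like movie.

Builds a benchmark movie with 20 planted fusion events plus the classic
confounds (trafficking vesicles, persistent puncta, photobleaching), runs
the full detection/classification chain in memory and prints what it found.
"""

import numpy as np

from exospot import detect, events, preprocess, synth

shape = (200, 256, 256)
truth, mask = synth.default_benchmark_truth(shape, seed=1)
movie, mask, truth = synth.simulate_movie(truth, shape, mask=mask)

# preprocessing: extracellular background, bleaching, stationary structure
m = preprocess.subtract_background(movie, "percentile", 50, mask)
m = preprocess.histogram_match_to_first(m)
det_movie = preprocess.rolling_median_subtract(m, window=5)

# difference-of-Gaussians detection with a scaled-median threshold
dog = detect.compute_dog_trace(det_movie, mask,
                               detect.DoGParams(sigma0=2.0,
                                                threshold_scale=1.0))
candidates = detect.extract_candidates(dog, mask)

# per-candidate evaluation: Gaussian fits, drift, plateau+decay fit
records = events.evaluate_all(m, candidates, events.EvaluationParams())
accepted = [r for r in records if r.status == "true_event"]
freq = events.exocytic_frequency(len(accepted), mask, movie)
score = synth.score_benchmark(truth, records)

print(f"candidates flagged by the detector : {len(candidates)}")
print(f"classified as true fusion events   : {len(accepted)}")
print(f"recall / precision vs ground truth : "
      f"{score.recall:.2f} / {score.precision:.2f}")
print(f"exocytic frequency                 : {freq:.4f} events/um^2/min")
half_lives = [r.fit.half_life for r in accepted]
print(f"median fluorescence half-life      : {np.median(half_lives):.2f} s")
print()
print("Each accepted event is a stationary Gaussian spot, at least 4x its")
print("local background, that decays exponentially; trafficking vesicles")
print("are rejected by the drift rule and persistent puncta never produce")
print("candidates because the rolling-median projection removes them.")
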