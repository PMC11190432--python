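# Methods

## Signal model

An exocytic event is modeled as an isotropic 2D Gaussian spot of width
σ ≈ 2 px (the point-spread-function scale at high magnification) whose peak
amplitude is constant for a short plateau and then decays exponentially:

    I(t) = A                      for t0 ≤ t ≤ t0 + p·Δt
    I(t) = A · exp(−k (t − t_p))  for t > t_p ,   half-life = ln 2 / k

The plateau reflects the open fusion pore; the decay reflects reporter
diffusion in the membrane and/or reacidification. Everything else in the
movie is a confound: vesicles trafficking at roughly constant velocity,
persistent bright puncta, diffuse intensity fluctuations, shot noise and
global photobleaching.

## Pipeline and parameters

All computation is floating point; quantizing to integers destroys the
dynamic range the detection threshold and the fold-change rules rely on.

**Background subtraction** (`preprocess.subtract_background`): constant
offset, or per-frame percentile (default 50th) of pixels *outside* the
mask. The percentile mode estimates diffuse extracellular background;
constant mode suits a known camera offset. The mask-based default is a
choice this package makes: only pixels that cannot contain signal inform
the estimate.

**Photobleach correction** (`histogram_match_to_first`): monotone quantile
mapping of each frame's intensity distribution onto frame 0's, over 1024
quantiles. The mapping is estimated on quantiles up to 0.95 and extended
linearly above, with the tail slope taken over the 0.855–0.95 span.
Rationale: the extreme tail is populated by transient bright spots whose
number varies frame to frame; mapping it quantile-to-quantile compresses or
inflates exactly the amplitudes the pipeline later quantifies (on the
benchmark this destroyed half the detections), whereas the bulk of the
distribution carries the bleaching signal. For a purely rescaled frame the
extension is exact. Consequences: rank order is preserved, per-frame means
of a purely bleached movie are restored to within 1%, and re-applying the
correction is a no-op to ~1e−4 of the value range (finite-sample quantile
interpolation).

**Stationary-structure removal** (`rolling_median_subtract`): each frame
minus the pixelwise median of the preceding `window = 5` frames, clipped at
0. Frames earlier than the window use all available preceding frames;
frame 0 passes through unchanged (it has no temporal reference — the
detector therefore ignores frame 0 by default, `skip_initial = 1`).
Persistent puncta and the static cell baseline vanish; a transient spot
survives because it is absent from its own recent past.

**Bleed-through** (`bleedthrough_correct`): target − c × source, c ≈ 0.08
for sepHluorin into pHmScarlet, clipped at 0.

**Segmentation** (`segment_first_frame`): Otsu threshold of the blurred
first frame, largest connected component, holes filled. Movies are short
enough that shape change over the recording is ignored. A user-supplied
mask always takes precedence; the automated mask is a convenience.

**Detection** (`detect`): 13 blur rounds starting at `sigma0` (3 px for
VAMP2 cortical neurons, 1 px for melanoma cells, 8 px for oligodendrocytes
in the datasets the defaults come from), geometric schedule
σ_k = σ0 · 2^((k−1)/4). Quarter-octave steps are standard scale-space
practice; the median projection over the 12 adjacent differences makes the
result insensitive to the exact schedule, which is configurable. The
threshold is `median(max trace) × threshold_scale`; the scale (default 1.2,
0.7–1.5 across cell types) is the single most important tuning knob. In
high-activity movies, where most frames contain an event and the median
itself sits at event level, scales below 1 are appropriate — this is
exactly the regime of the synthetic benchmark, which uses 1.0. Detections
in consecutive frames within `link_radius = 12` px are merged into one
candidate (t0 = first frame, seed = brightest linked peak); peaks within
`exclude_border = 12` px of the frame edge are dropped so a full crop
always fits.

**Evaluation** (`events`): crop 25×25 px, `frames_before = 10`,
`frames_after = 15`, smoothing σ = 1 px. Local background = pixelwise
median of frames t ≤ −2; t = −1 is excluded because fluorescence is often
already elevated one frame before detection. The background level is the
mean of that image over the central third of the crop (the same region the
intensity trace is measured on — `maximum` by default, `average`
optional). Candidates with fewer than two usable pre-event frames are
flagged `insufficient_background`.

Classification applies rules in a fixed precedence, and the first failure
becomes the flag: background frames → valid t = 0 Gaussian fit
(R² ≥ `gaussian_r2_min`, default 0.6; 0.3–0.75 across cell types) → peak ≥
`fold_above_background = 4` × background level → at least
`min_frames_above_background = 3` consecutive frames above
background + 2 robust noise sd (1.4826 × MAD of the pre-event trace) →
drift within [`drift_min = 0`, `drift_max = 2`] px → function-fit R² ≥
`fit_r2_min` (default 0.7; 0.24–0.75 across cell types). The precedence
order is a design choice of this package; the flags themselves are what
matters for auditing. `drift_min > 0` rejects zero-drift shot noise in
noisy recordings.

Drift is the maximum pairwise distance between Gaussian centers of valid
frames *within the event's own duration* (detection frame through the end
of the frames-above-background run). Frames after the fluorescence has
returned to background carry no information about the event's position,
and an unrelated object wandering into the crop later would otherwise
corrupt the statistic; movers are still rejected because their run is long
and mobile. The fold-above-background ratio uses the raw (not
background-subtracted) peak over the background level — a ratio of a
background-subtracted peak to background would not be a "fold above
background".

The plateau+decay fit searches every plateau length p = 0 … n−2, fitting
(level, baseline ≥ `min_intensity_for_fit`, rate > 0) by bounded least
squares and keeping the best whole-trace R²; exact ties go to the shorter
plateau (parsimony). The baseline floor models residual membrane
fluorescence — the decay need not reach zero. Reported duration =
plateau time + 3 half-lives, alongside the raw frames-above-background
count.

## Spatial statistics

K̂(r) = A/(n(n−1)) Σ_{i≠j} 1[d_ij ≤ r], L = √(K̂/π), with the mask area A
and **no analytic edge correction**: the observed pattern is compared only
with uniform simulations on the same mask (default 25,000), so edge effects
cancel in the comparison. Points are sampled uniformly per mask pixel with
subpixel jitter. The Z-score divides (L − envelope median) by 1.4826 × MAD;
the consistency factor puts the MAD on the standard-deviation scale so that
|z| > 2 is the conventional two-sigma (p ≈ 0.05) criterion — without it,
"2" would correspond to only 1.35 sd and a CSR pattern would breach the
band at ~18% of radii instead of ~5%. Radii where no simulation produced a
pair (MAD = 0) are reported as z = 0 and flagged unusable. The default r
grid spans 0 to a quarter of the mask bounding-box diagonal in 50 steps.

## Temporal statistics

Sorted inter-event intervals are plotted against standard-exponential
quantiles at Hazen positions p_i = (i − 0.5)/n (keeps p < 1, symmetric in
rank; (i)/(n+1) available). The line is fitted by weighted least squares
with weights 1/Var(E_(i:n)), Var(E_(i:n)) = Σ_{j≤i} (n−j+1)^−2 — the upper
order statistics of an exponential sample are far noisier than the lower
ones and should not steer the fit. The envelope simulates `n_sims = 400`
samples of slope·Exp(1) + intercept (the intercept is retained to mirror
the fitted line); z is the residual from the fit line over 1.4826 × MAD.
All-equal intervals make the slope exactly 0 (flagged degenerate; no
envelope is possible). Per-cell z curves are interpolated onto a common
axis (default 100 points over the union of fitted ranges, no
extrapolation) for the mean ± s.e.m. aggregate.

Calibration, measured by `scripts/acceptance.py`: under Poisson timing
(rate 0.5/s, 150 s) the median fraction of in-band positions is ~100%, and
jittered-periodic and bursty trains are flagged in 100% of replicates. The
band is a MAD band, not an exact simultaneous 95% band: the probability
that *some* position of ~75 breaches it under the null is ~35%, driven by
the heavy-tailed extreme order statistics, so single-position excursions at
the ends of the Q-Q curve should be read with that in mind.

## Exclusion rule

Cells with fewer than 26 accepted events are excluded from aggregate
spatial and temporal curves — envelopes simulated from so few points are
too noisy to be meaningful. Per-cell results are still computed and
written for any n ≥ 2 so the user can adjust the criterion.

## Synthetic data

`synth.simulate_movie` renders events (the closed form above), movers
(constant-velocity Gaussian spots with a finite lifetime — vesicles
entering and leaving the evanescent field), persistent puncta, an
elliptical cell with in-cell baseline 20 and extracellular offset 2,
global bleaching (1 − rate)^t and additive Gaussian noise (Poisson shot
noise deliberately omitted for analytic tractability). The standard
benchmark (`default_benchmark_truth`) is 200 frames of 256×256 px at
0.1 µm/px and 0.5 s/frame: 20 events at 6× baseline (comfortably above the
4× rule) with plateaus of 1–4 frames and decay rates 0.4–1.0 s⁻¹, 5 movers
at 2 px/frame entering mid-movie, 3 puncta at 6× baseline, 0.2%/frame
bleaching, noise sd 2. Events are ≥ 26 px apart and mover paths keep
≥ 18 px from event sites: spatially coincident objects are a genuine
ambiguity no rule set resolves (that is what the manual override exists
for), so the benchmark does not manufacture them. Movers enter mid-movie
rather than existing from frame 0 so that the drift rule — not the
insufficient-background rule — is what rejects them, which is the behavior
worth testing.

The generators do **not** emulate: spatially varying background, uneven
illumination, camera gain/read-noise models, TIRF evanescent-depth decay,
stage drift, or overlapping events at one site. Passing tests demonstrate
the algorithmic contract under the stated model, not performance on any
particular microscope's data — the per-cell-type parameter tables exist
precisely because real data needs tuning.

Point patterns: uniform (CSR on mask pixels), Thomas clusters (uniform
parents, Gaussian offspring sd 0.5 µm, mask-rejected, exact n), hardcore
(sequential inhibition). Event times: Poisson (exponential gaps),
periodic with optional Gaussian jitter — strictly constant gaps are
degenerate for the Q-Q fit, and real trains always jitter at least by
frame discretization, so tests use period 3 s with 0.1 s jitter — and
bursty (two-state, rates 2.0/0.05 s⁻¹, mean dwell 10 s).

## Numerical choices

* Gaussian frame fits: Levenberg–Marquardt via bounded least squares,
  initialized at the brightest pixel, σ bounded to [0.3, crop size];
  non-convergence or a structureless frame returns R² = 0 / invalid.
* Plateau search granularity is one frame; r2 ties break to the shorter
  plateau; candidate-plateau fits that fail to converge are skipped, and if
  all fail the event is flagged `poor_function_fit`.
* Clipping at 0 after every subtraction keeps fold-change criteria
  meaningful; negatives carry no physical meaning here.
* All Monte-Carlo code takes an explicit seed; identical configs and seeds
  reproduce every output file bit-for-bit.
* Test and example simulation sizes (2,000 spatial simulations instead of
  25,000, 50 replicates) are chosen so the whole suite runs in a few
  minutes on one CPU; the statistical conclusions are unchanged at the
  production defaults.

## Known limitations

* The detector's scaled-median threshold assumes the max-intensity trace's
  median reflects background activity; in extremely active movies the scale
  must be set below 1 (and the package cannot choose it automatically).
* Two objects within a crop width of each other confuse both the drift
  rule and the curve fit; such calls need the manual override.
* Events at the very start of a movie (fewer than two usable background
  frames) are unrecoverable by design.
* Histogram matching corrects only global, spatially uniform bleaching.
* The temporal test assumes a stationary observation window; slow drifts
  in event rate masquerade as bursting.
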