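# exospot

Detection and spatiotemporal statistics of exocytic fusion events in
fluorescence timelapse movies.

## The problem

Vesicle fusion with the plasma membrane can be imaged with pH-sensitive
reporters (sepHluorin, pHmScarlet) fused to a vSNARE: the fluorophore is
quenched in the acidic vesicle lumen and lights up the instant the fusion
pore opens, then decays exponentially as the reporter diffuses away or the
vesicle reacidifies. A timelapse movie of a cell therefore contains short,
stationary, Gaussian-profile flashes — mixed in with everything that is not
exocytosis: vesicles trafficking through the evanescent field, long-lived
bright puncta, shot noise, diffuse fluctuations and global photobleaching.

`exospot` turns such movies (multi-page TIFF + optional mask + YAML config)
into a curated event table and per-cell statistics, for labs quantifying
exocytosis in neurons, oligodendrocytes, melanoma cells or any other
adherent cell under TIRF/HILO/widefield imaging.

## The method

1. **Preprocess** — floating-point throughout: background subtraction
   (constant or outside-mask percentile), photobleach correction by
   histogram matching every frame to frame 0, removal of stationary
   structure by subtracting a rolling median of the preceding 5 frames,
   optional ~8% spectral bleed-through correction for dual-channel data.
2. **Detect** — 13 rounds of increasingly large Gaussian blurs; adjacent
   blurs are subtracted and median-projected (a band-pass that keeps
   spot-scale structure). The per-frame maximum of this projection inside
   the mask is thresholded at `median × scale` (scale 0.7–1.5 depending on
   cell type) to flag candidate regions.
3. **Evaluate** — each candidate gets a 25×25 px crop, 1-px smoothing and a
   local background from the median of pre-event frames (t = −1 excluded).
   An isotropic 2D Gaussian is fitted per frame; drift is the maximum
   pairwise distance between valid-fit centers. The intensity trace is
   fitted with a plateau followed by an exponential decay, searching every
   plateau length and keeping the best R²; half-life = ln(2)/decay rate.
   Candidates failing intensity (≥ 4× background), duration, drift or
   goodness-of-fit rules are rejected with a single diagnostic flag, and a
   manual override CSV can flip calls.
4. **Spatial statistics** — Ripley's `L(r) = sqrt(K(r)/π)` of accepted
   events compared with 25,000 uniform simulations *on the same cell
   mask*; `z(r) = (L − median)/(1.4826·MAD)` flags clustering (z > 2) or
   dispersion (z < −2) with no edge correction needed.
5. **Temporal statistics** — sorted inter-event intervals against
   standard-exponential quantiles (Q-Q), a variance-weighted line fit, 400
   simulated envelopes, and the analogous Z-score; |z| > 2 anywhere means
   the timing is not Poisson.

Cells with fewer than 26 accepted events are excluded from aggregate
spatial/temporal curves (their envelopes are too noisy), and every result
is reproducible bit-for-bit from config + seed.

## Worked example

`examples/01_detect_events.py` builds a 200-frame synthetic benchmark movie
(20 planted fusion events, 5 trafficking vesicles at 2 px/frame, 3
persistent puncta, 0.2 %/frame photobleaching, additive noise) and runs the
full chain:

```
candidates flagged by the detector : 34
classified as true fusion events   : 20
recall / precision vs ground truth : 1.00 / 1.00
exocytic frequency                 : 0.0365 events/um^2/min
median fluorescence half-life      : 1.04 s
```

All 20 planted events are recovered; the extra candidates are the
trafficking vesicles (rejected with the `drift` flag) and re-detections of
decaying events (rejected as `low_intensity` against their own elevated
local background). The frequency is events / mask area (µm²) / movie
duration (min); the half-life describes the exponential tail of each flash.

Other examples: `02_spatial_statistics.py` (uniform vs clustered vs
dispersed patterns in a neuron-like mask), `03_temporal_statistics.py`
(Poisson vs periodic vs bursty timing), `04_full_pipeline_cli.py`
(file-based run with the YAML config). The same functionality is available
from the shell:

```bash
exospot simulate --out-dir demo --seed 1
exospot run config.yaml
exospot batch cell1.yaml cell2.yaml --aggregate-dir agg
exospot stats events.csv mask.tif --pixel-size 0.1 --frame-interval 0.5 \
        --n-frames 200 --out-dir stats
```

## Documentation

`docs/methods.md` describes the model, every tunable parameter with its
default, the synthetic-data generators, numerical choices and known
limitations.
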