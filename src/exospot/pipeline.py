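"""Single-cell and batch orchestration of the full analysis.

``run_cell`` executes preprocess → detect → evaluate → (spatial, temporal)
for one movie and writes the event table, QC traces, per-cell statistics
and a run log with the full effective configuration.  ``run_batch`` runs a
list of configs independently (one failure does not abort the rest) and
aggregates the per-cell Z curves and frequencies.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, events, preprocess, spatial, temporal
from .config import RunConfig
from .movie import CellMask, Movie, read_mask, read_movie, write_mask, write_movie


@dataclass
class CellResult:
    """Everything computed for one cell."""

    config: RunConfig
    movie: Movie
    mask: CellMask
    dog_trace: detect.DoGTrace
    records: list[events.EventRecord]
    frequency: float
    spatial_result: spatial.SpatialResult | None = None
    temporal_result: temporal.QQResult | None = None
    stats_excluded: bool = False
    timings: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[events.EventRecord]:
        return [r for r in self.records if r.status == "true_event"]


def preprocess_movie(movie: Movie, mask: CellMask,
                     cfg: RunConfig,
                     source: Movie | None = None) -> tuple[Movie, Movie]:
    """Apply the preprocessing chain.

    Returns ``(intensity_movie, detection_movie)``: the background- and
    bleach-corrected movie that event evaluation crops from, and the
    additionally rolling-median-subtracted movie the detector runs on.
    """
    pc = cfg.preprocess
    m = preprocess.subtract_background(movie, pc.background.mode,
                                       pc.background.value, mask)
    if source is not None and pc.bleedthrough_coefficient > 0:
        m = preprocess.bleedthrough_correct(m, source,
                                            pc.bleedthrough_coefficient)
    if pc.bleach_correction:
        m = preprocess.histogram_match_to_first(m, pc.histogram_bins)
    det = preprocess.rolling_median_subtract(m, pc.rolling_window)
    return m, det


def records_table(records: list[events.EventRecord]) -> pd.DataFrame:
    """One row per candidate, mirroring the per-event report table."""
    rows = []
    for r in records:
        fit = r.fit
        g0 = None
        if r.series is not None and r.frame_fits:
            i0 = int(np.flatnonzero(r.series.rel_frames == 0)[0])
            g0 = r.frame_fits[i0]
        rows.append({
            "event_id": r.event_id,
            "x": r.candidate.seed_xy[0],
            "y": r.candidate.seed_xy[1],
            "t0": r.candidate.t0,
            "status": r.status,
            "flag": r.flag,
            "drift_px": r.drift,
            "peak_intensity": r.peak_intensity,
            "fold_above_background": r.fold_above_background,
            "frames_above_background": r.frames_above_background,
            "plateau_frames": fit.plateau_frames if fit else np.nan,
            "decay_rate_per_s": fit.decay_rate if fit else np.nan,
            "half_life_s": fit.half_life if fit else np.nan,
            "function_r2": fit.r2 if fit else np.nan,
            "gaussian_r2_t0": g0.r2 if g0 else np.nan,
            "duration_s": r.duration_s,
        })
    return pd.DataFrame(rows)


def run_cell(config: RunConfig, write_outputs: bool = True) -> CellResult:
    """Full analysis of one movie; outputs under ``config.output_dir``."""
    t_start = time.perf_counter()
    timings: dict = {}
    cal = config.calibration
    movie = read_movie(config.movie_path, cal.pixel_size, cal.frame_interval)
    source = (read_movie(config.source_channel_path, cal.pixel_size,
                         cal.frame_interval)
              if config.source_channel_path else None)
    if config.mask_path:
        mask = read_mask(config.mask_path, cal.pixel_size)
    else:
        mask = preprocess.segment_first_frame(
            movie, config.preprocess.segmentation_blur_sigma,
            min_size=config.preprocess.segmentation_min_size)
    timings["load"] = time.perf_counter() - t_start

    t = time.perf_counter()
    intensity_movie, det_movie = preprocess_movie(movie, mask, config, source)
    timings["preprocess"] = time.perf_counter() - t

    t = time.perf_counter()
    dog_trace = detect.compute_dog_trace(det_movie, mask, config.dog_params())
    candidates = detect.extract_candidates(
        dog_trace, mask, config.detect.link_radius,
        config.detect.exclude_border)
    timings["detect"] = time.perf_counter() - t

    t = time.perf_counter()
    params = config.evaluation_params()
    records = events.evaluate_all(intensity_movie, candidates, params)
    if config.overrides_path:
        include, exclude = read_overrides(config.overrides_path)
        events.apply_manual_overrides(records, include, exclude)
    timings["events"] = time.perf_counter() - t

    accepted = [r for r in records if r.status == "true_event"]
    frequency = events.exocytic_frequency(len(accepted), mask, movie)

    result = CellResult(config=config, movie=movie, mask=mask,
                        dog_trace=dog_trace, records=records,
                        frequency=frequency, timings=timings)

    n_acc = len(accepted)
    excluded = n_acc < min(config.spatial.min_events,
                           config.temporal.min_events)
    result.stats_excluded = excluded
    t = time.perf_counter()
    if n_acc >= 2:
        pts_px = np.array([[r.candidate.seed_xy[0], r.candidate.seed_xy[1]]
                           for r in accepted], dtype=float)
        pattern = spatial.PointPattern(pts_px * cal.pixel_size, mask)
        r_grid = spatial.default_r_grid(mask, config.spatial.n_r_steps)
        result.spatial_result = spatial.analyze_pattern(
            pattern, r_grid, config.spatial.n_sims, config.seed)
        times_s = np.sort([r.candidate.t0 * cal.frame_interval
                           for r in accepted])
        if n_acc >= 3:
            et = temporal.EventTimes(times_s, movie.duration_s)
            result.temporal_result = temporal.analyze_times(
                et, config.temporal.n_sims, config.seed)
    timings["stats"] = time.perf_counter() - t

    if write_outputs:
        write_bundle(result)
    return result


def read_overrides(path) -> tuple[list[int], list[int]]:
    """Two-column CSV (event_id, action) with action include/exclude."""
    df = pd.read_csv(path)
    include = df.loc[df.iloc[:, 1].str.strip() == "include",
                     df.columns[0]].astype(int).tolist()
    exclude = df.loc[df.iloc[:, 1].str.strip() == "exclude",
                     df.columns[0]].astype(int).tolist()
    return include, exclude


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_bundle(result: CellResult) -> Path:
    """Write the per-cell output bundle (tables, QC trace, log, plot)."""
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records_table(result.records).to_csv(out / "events.csv", index=False)
    pd.DataFrame({
        "frame": np.arange(result.dog_trace.max_trace.size),
        "max_dog": result.dog_trace.max_trace,
        "threshold": result.dog_trace.threshold,
    }).to_csv(out / "max_trace.csv", index=False)
    write_mask(out / "mask.tif", result.mask)

    sr = result.spatial_result
    if sr is not None:
        pd.DataFrame({
            "r_um": sr.r_grid, "L_actual": sr.L_actual,
            "env_median": sr.env_median, "env_mad": sr.env_mad,
            "z": sr.z, "usable": sr.usable,
            "classification": spatial.classify_z(sr.z),
        }).to_csv(out / "spatial.csv", index=False)
    tr = result.temporal_result
    if tr is not None:
        pd.DataFrame({
            "delta_t_s": tr.delta_t_sorted, "p": tr.p,
            "q_theoretical": tr.q_theoretical,
            "env_median": tr.env_median, "env_mad": tr.env_mad, "z": tr.z,
            "usable": tr.usable,
        }).to_csv(out / "temporal.csv", index=False)

    log = {
        "config": result.config.model_dump(),
        "config_hash": _config_hash(result.config),
        "n_candidates": len(result.records),
        "n_accepted": len(result.accepted),
        "frequency_per_um2_min": result.frequency,
        "mask_area_um2": result.mask.area_um2,
        "stats_excluded": result.stats_excluded,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    _qc_plot(result, out / "qc_max_trace.png")
    return out


def _qc_plot(result: CellResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trace = result.dog_trace.max_trace
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace, lw=0.8, label="max DoG intensity")
    ax.axhline(result.dog_trace.threshold, color="r", lw=1,
               label="threshold")
    ax.set_xlabel("frame")
    ax.set_ylabel("max DoG intensity (masked)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class BatchResult:
    cells: list[CellResult]
    failures: list[tuple[str, str]]  # (movie_path, error text)
    spatial_mean: np.ndarray | None = None
    spatial_sem: np.ndarray | None = None
    temporal_axis: np.ndarray | None = None
    temporal_mean: np.ndarray | None = None
    temporal_sem: np.ndarray | None = None
    frequency_table: pd.DataFrame | None = None


def run_batch(configs: list[RunConfig], write_outputs: bool = True,
              aggregate_dir: str | None = None) -> BatchResult:
    """Run every config; aggregate Z curves over included (>= 26 event) cells."""
    if not configs:
        raise ValueError("no configs to run")
    cells: list[CellResult] = []
    failures: list[tuple[str, str]] = []
    for cfg in configs:
        try:
            cells.append(run_cell(cfg, write_outputs=write_outputs))
        except Exception:
            failures.append((cfg.movie_path, traceback.format_exc()))
    result = BatchResult(cells=cells, failures=failures)
    if cells:
        result.frequency_table = pd.DataFrame({
            "movie": [c.config.movie_path for c in cells],
            "n_accepted": [len(c.accepted) for c in cells],
            "area_um2": [c.mask.area_um2 for c in cells],
            "frequency_per_um2_min": [c.frequency for c in cells],
            "stats_excluded": [c.stats_excluded for c in cells],
        })
    included = [c for c in cells if not c.stats_excluded]
    sp = [c.spatial_result for c in included if c.spatial_result is not None]
    if sp:
        try:
            result.spatial_mean, result.spatial_sem = \
                spatial.aggregate_spatial(sp)
        except ValueError:
            pass
    tp = [c.temporal_result for c in included
          if c.temporal_result is not None and not c.temporal_result.degenerate]
    if tp:
        axis, mean, sem = temporal.aggregate_temporal(tp)
        result.temporal_axis, result.temporal_mean, result.temporal_sem = \
            axis, mean, sem
    if aggregate_dir is not None and cells:
        agg = Path(aggregate_dir)
        agg.mkdir(parents=True, exist_ok=True)
        result.frequency_table.to_csv(agg / "frequencies.csv", index=False)
        if result.spatial_mean is not None:
            grid = sp[0].r_grid
            pd.DataFrame({"r_um": grid, "mean_z": result.spatial_mean,
                          "sem_z": result.spatial_sem}).to_csv(
                agg / "spatial_aggregate.csv", index=False)
        if result.temporal_mean is not None:
            pd.DataFrame({"delta_t_s": result.temporal_axis,
                          "mean_z": result.temporal_mean,
                          "sem_z": result.temporal_sem}).to_csv(
                agg / "temporal_aggregate.csv", index=False)
    return result
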