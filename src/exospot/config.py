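"""Run configuration: schema-validated parameters for a whole analysis.

A :class:`RunConfig` collects paths, calibration and every tunable
parameter of the pipeline.  It is validated (unknown keys rejected) before
any computation starts, so a typo in a YAML file fails fast instead of
silently running with a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Strict):
    pixel_size: float = Field(gt=0, description="µm per pixel")
    frame_interval: float = Field(gt=0, description="seconds per frame")


class BackgroundConfig(_Strict):
    mode: str = "percentile"      # constant | percentile
    value: float = 50.0


class PreprocessConfig(_Strict):
    background: BackgroundConfig = BackgroundConfig()
    bleach_correction: bool = True
    histogram_bins: int = Field(default=1024, ge=2)
    rolling_window: int = Field(default=5, ge=1)
    bleedthrough_coefficient: float = Field(default=0.0, ge=0, lt=1)
    segmentation_blur_sigma: float = Field(default=2.0, gt=0)
    segmentation_min_size: int = Field(default=64, ge=1)


class DetectConfig(_Strict):
    sigma0: float = Field(default=3.0, gt=0)
    rounds: int = Field(default=13, ge=2)
    threshold_scale: float = Field(default=1.2, gt=0)
    link_radius: float = Field(default=12.0, gt=0)
    exclude_border: int = Field(default=12, ge=0)


class EventConfig(_Strict):
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


class SpatialConfig(_Strict):
    n_sims: int = Field(default=25000, ge=2)
    n_r_steps: int = Field(default=50, ge=2)
    min_events: int = Field(default=26, ge=2)


class TemporalConfig(_Strict):
    n_sims: int = Field(default=400, ge=2)
    min_events: int = Field(default=26, ge=2)


class RunConfig(_Strict):
    """Everything needed to analyze one movie, loadable from YAML/JSON."""

    movie_path: str
    output_dir: str
    mask_path: str | None = None
    overrides_path: str | None = None
    source_channel_path: str | None = None  # for bleed-through correction
    calibration: CalibrationConfig
    preprocess: PreprocessConfig = PreprocessConfig()
    detect: DetectConfig = DetectConfig()
    events: EventConfig = EventConfig()
    spatial: SpatialConfig = SpatialConfig()
    temporal: TemporalConfig = TemporalConfig()
    seed: int = 0

    @model_validator(mode="after")
    def _check_events(self) -> "RunConfig":
        # instantiating EvaluationParams enforces its own invariants early
        self.evaluation_params()
        return self

    def evaluation_params(self):
        from .events import EvaluationParams

        return EvaluationParams(**self.events.model_dump())

    def dog_params(self):
        from .detect import DoGParams

        d = self.detect
        return DoGParams(sigma0=d.sigma0, rounds=d.rounds,
                         threshold_scale=d.threshold_scale)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
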