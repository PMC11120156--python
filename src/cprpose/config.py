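"""YAML application configuration with validated defaults.

Every default is the system's stock constant: press-start excursion
15.5 px and return band 5 px, depth band 5–6 cm, rate band 100–120 /min,
elbow-straightness 165°, 30 presses per cycle, 5 cycles.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from pydantic import ValidationError as _PydanticValidationError

from .detector import DetectorConfig
from .keypoints import ValidationError
from .metrics import Calibration, FeedbackThresholds
from .phases import CycleConfig

__all__ = ["AppConfig", "load_config", "dump_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DetectorSettings(_Section):
    start_threshold_px: float = Field(15.5, gt=0)
    return_threshold_px: float = Field(5.0, gt=0)
    min_confidence: float = Field(0.3, ge=0, le=1)
    hysteresis_px: float = Field(1.0, ge=0)
    rest_timeout_s: float = Field(2.0, gt=0)
    smooth_window: int = Field(1, ge=1)
    refine_bottom: bool = True

    @model_validator(mode="after")
    def _ordered(self) -> "DetectorSettings":
        if self.start_threshold_px <= self.return_threshold_px:
            raise ValueError("detector.start_threshold_px must exceed detector.return_threshold_px")
        return self


class ThresholdSettings(_Section):
    depth_min_cm: float = Field(5.0, gt=0)
    depth_max_cm: float = Field(6.0, gt=0)
    freq_min_bpm: float = Field(100.0, gt=0)
    freq_max_bpm: float = Field(120.0, gt=0)
    posture_min_deg: float = Field(165.0, gt=0, le=180)

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdSettings":
        if self.depth_min_cm >= self.depth_max_cm:
            raise ValueError("thresholds.depth_min_cm must be < thresholds.depth_max_cm")
        if self.freq_min_bpm >= self.freq_max_bpm:
            raise ValueError("thresholds.freq_min_bpm must be < thresholds.freq_max_bpm")
        return self


class CycleSettings(_Section):
    presses_per_cycle: int = Field(30, ge=1)
    max_cycles: int = Field(5, ge=1)
    window_s: float = Field(1.0, gt=0)


class CalibrationSettings(_Section):
    px_per_cm: Optional[float] = Field(None, gt=0)


class AppConfig(_Section):
    """Full application configuration (all sections optional in YAML)."""

    detector: DetectorSettings = Field(default_factory=DetectorSettings)
    thresholds: ThresholdSettings = Field(default_factory=ThresholdSettings)
    cycle: CycleSettings = Field(default_factory=CycleSettings)
    calibration: CalibrationSettings = Field(default_factory=CalibrationSettings)
    freq_window_presses: int = Field(3, ge=1)
    log_level: str = "INFO"

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(**self.detector.model_dump())

    def feedback_thresholds(self) -> FeedbackThresholds:
        return FeedbackThresholds(**self.thresholds.model_dump())

    def cycle_config(self) -> CycleConfig:
        return CycleConfig(**self.cycle.model_dump())

    def calibration_obj(self) -> Optional[Calibration]:
        if self.calibration.px_per_cm is None:
            return None
        return Calibration(px_per_cm=self.calibration.px_per_cm, derived_from="config file")

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration, for logging."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> AppConfig:
    """Load YAML config; absent path or empty file yields full defaults."""
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AppConfig()
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    try:
        return AppConfig.model_validate(raw)
    except _PydanticValidationError as exc:
        raise ValidationError(f"{path}: invalid configuration: {exc}") from exc


def dump_config(cfg: AppConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
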