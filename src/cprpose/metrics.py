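"""Per-press compression metrics: depth, frequency, elbow angle, band checks.

The three quality dimensions of a chest compression are

* **depth** — wrist displacement at the press bottom divided by a
  pixel-to-centimetre calibration factor; the guideline band is 5–6 cm;
* **frequency** — ``60 / press_time`` in compressions per minute, where
  the press time is the bottom-to-bottom period of one compression
  cycle; the guideline band is 100–120 /min;
* **posture** — the interior elbow angle shoulder–elbow–wrist, computed
  by the law of cosines; both elbows must be nearly straight (> 165°).

Band comparisons treat the guideline intervals as closed: a press at
exactly 5.0 cm or exactly 120 /min is compliant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Optional, Sequence

from .keypoints import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .detector import PressEvent

__all__ = [
    "Calibration",
    "ElbowTriple",
    "FeedbackThresholds",
    "PressMetrics",
    "compression_depth",
    "compression_frequency",
    "press_period_s",
    "compressions_per_second",
    "elbow_angle",
    "classify_press",
]

Point = Sequence[float]

DepthBand = Literal["shallow", "ok", "deep"]
FreqBand = Literal["slow", "ok", "fast"]
Posture = Literal["normal", "abnormal"]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimetre conversion for wrist displacement.

    ``px_per_cm`` is the number of image pixels corresponding to one
    centimetre of vertical motion at the subject's depth in the scene.
    """

    px_per_cm: float
    derived_from: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.px_per_cm) and self.px_per_cm > 0):
            raise ValidationError(f"calibration px_per_cm must be finite and > 0, got {self.px_per_cm}")

    @classmethod
    def from_reference(cls, length_px: float, length_cm: float) -> "Calibration":
        """Derive calibration from a reference object of known size in frame."""
        if length_px <= 0 or length_cm <= 0:
            raise ValidationError("reference lengths must be positive")
        return cls(px_per_cm=length_px / length_cm,
                   derived_from=f"reference length {length_px} px = {length_cm} cm")


@dataclass(frozen=True)
class ElbowTriple:
    """Shoulder (A), elbow (B), wrist (C) of one arm, in pixels."""

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.A) == tuple(self.B) or tuple(self.B) == tuple(self.C):
            raise ValidationError("elbow angle undefined: coincident keypoints in arm triple")


@dataclass(frozen=True)
class FeedbackThresholds:
    """Compliance bands for depth (cm), frequency (/min) and elbow angle (deg)."""

    depth_min_cm: float = 5.0
    depth_max_cm: float = 6.0
    freq_min_bpm: float = 100.0
    freq_max_bpm: float = 120.0
    posture_min_deg: float = 165.0

    def __post_init__(self) -> None:
        if not self.depth_min_cm < self.depth_max_cm:
            raise ValidationError("depth_min_cm must be < depth_max_cm")
        if not self.freq_min_bpm < self.freq_max_bpm:
            raise ValidationError("freq_min_bpm must be < freq_max_bpm")
        if not (0.0 < self.posture_min_deg <= 180.0):
            raise ValidationError("posture_min_deg must be in (0, 180]")


@dataclass(frozen=True)
class PressMetrics:
    """Quality metrics of one detected compression."""

    depth_cm: float
    frequency_bpm: float
    left_elbow_deg: float
    right_elbow_deg: float
    depth_band: DepthBand
    freq_band: FreqBand
    posture: Posture
    bottom_time_s: float = float("nan")
    press_time_s: float = float("nan")


def compression_depth(bottom_y: float, initial_height: float, cal: Calibration) -> float:
    """Compression depth in cm: ``(bottom_y - initial_height) / px_per_cm``.

    ``bottom_y`` is the wrist pixel y at the press bottom and
    ``initial_height`` the resting wrist y before the press; with the
    y-down convention the bottom must not be above the resting height.
    """
    disp = bottom_y - initial_height
    if disp < 0:
        raise ValidationError(
            f"press bottom ({bottom_y}) above initial height ({initial_height}); "
            "negative depth is impossible under the y-down convention"
        )
    return disp / cal.px_per_cm


def compression_frequency(press_time_s: float) -> float:
    """Compression frequency in /min from one bottom-to-bottom press time."""
    if not (math.isfinite(press_time_s) and press_time_s > 0):
        raise ValidationError(f"press time must be finite and > 0 s, got {press_time_s}")
    return 60.0 / press_time_s


def press_period_s(rate_bpm: float) -> float:
    """Bottom-to-bottom period in seconds at a given rate (/min)."""
    if rate_bpm <= 0:
        raise ValidationError("rate must be > 0 /min")
    return 60.0 / rate_bpm


def compressions_per_second(rate_bpm: float) -> float:
    """Rate expressed in compressions per second."""
    if rate_bpm <= 0:
        raise ValidationError("rate must be > 0 /min")
    return rate_bpm / 60.0


def elbow_angle(tri: ElbowTriple) -> float:
    """Interior elbow angle at B in degrees, via the law of cosines.

    ``cos(phi) = (AB^2 + BC^2 - AC^2) / (2 * AB * BC)``; the ratio is
    clamped to [-1, 1] before the arccos so that collinear triples
    (straight arm) return exactly 180° despite rounding.
    """
    ax, ay = tri.A
    bx, by = tri.B
    cx, cy = tri.C
    ab = math.hypot(ax - bx, ay - by)
    bc = math.hypot(cx - bx, cy - by)
    ac = math.hypot(ax - cx, ay - cy)
    ratio = (ab * ab + bc * bc - ac * ac) / (2.0 * ab * bc)
    ratio = max(-1.0, min(1.0, ratio))
    return math.degrees(math.acos(ratio))


def classify_press(
    event: "PressEvent",
    tri_left: ElbowTriple,
    tri_right: ElbowTriple,
    cal: Calibration,
    thr: FeedbackThresholds | None = None,
) -> PressMetrics:
    """Compute all metrics and compliance bands for one detected press.

    Elbow triples are sampled at the press-bottom frame — the moment of
    maximal load.  Posture is normal only if *both* elbow angles exceed
    the posture threshold.
    """
    thr = thr or FeedbackThresholds()
    depth = compression_depth(event.bottom_y, event.initial_height, cal)
    bpm = compression_frequency(event.press_time)
    left = elbow_angle(tri_left)
    right = elbow_angle(tri_right)

    if depth < thr.depth_min_cm:
        depth_band: DepthBand = "shallow"
    elif depth > thr.depth_max_cm:
        depth_band = "deep"
    else:
        depth_band = "ok"

    if bpm < thr.freq_min_bpm:
        freq_band: FreqBand = "slow"
    elif bpm > thr.freq_max_bpm:
        freq_band = "fast"
    else:
        freq_band = "ok"

    posture: Posture = "normal" if (left > thr.posture_min_deg and right > thr.posture_min_deg) else "abnormal"

    return PressMetrics(
        depth_cm=depth,
        frequency_bpm=bpm,
        left_elbow_deg=left,
        right_elbow_deg=right,
        depth_band=depth_band,
        freq_band=freq_band,
        posture=posture,
        bottom_time_s=event.end_time,
        press_time_s=event.press_time,
    )
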