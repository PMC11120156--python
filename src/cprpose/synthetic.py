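"""Synthetic compression sessions with known ground truth.

The generator emits keypoint traces that emulate what a pose backend
would produce while filming CPR training: six upper-limb keypoints whose
vertical motion follows a raised-cosine compression waveform during
active (CPR) phases and rests at the initial height during pauses
(UNCPR).  A raised cosine rather than a pure sine is used so each phase
starts *at rest height* — the press machine's state 0 records the
resting height before any downward motion.

During a phase of ``n`` presses at rate ``f = rate_bpm / 60`` the lowest
wrist follows::

    y(t) = y0 + A * (1 - cos(2 pi f t)) / 2,   A = true_depth_cm * rate_px_per_cm

so the peak-to-trough excursion is exactly the true depth times the
calibration, and ground-truth press bottoms fall at ``t = (k + 1/2)/f``.
Gaussian pixel noise and keypoint dropout (confidence zeroed) are
applied *after* the geometry, emulating pose-model jitter; dropout never
alters coordinates.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .keypoints import (
    REQUIRED_KEYPOINTS,
    Keypoint,
    KeypointFrame,
    KeypointTrace,
    ValidationError,
)

__all__ = ["SyntheticSpec", "GroundTruth", "arm_geometry", "generate_session"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic training session.

    Defaults describe a guideline-compliant session: 5.5 cm depth,
    110 /min, near-straight elbows (175°), five phases of 30 presses
    separated by 5 s pauses, filmed at 30 fps with a 10 px/cm
    calibration.
    """

    true_depth_cm: float = 5.5
    rate_bpm: float = 110.0
    rate_px_per_cm: float = 10.0
    elbow_angle_deg: float = 175.0
    fps: float = 30.0
    n_phases: int = 5
    presses_per_phase: int = 30
    pause_s: float = 5.0
    noise_px_sd: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0
    lead_in_s: float = 1.0
    recoil_fraction: float = 1.0  # 1.0 = full chest recoil between presses
    segment_px: float = 100.0  # upper-arm / forearm length
    arm_tilt_deg: float = 10.0  # outward splay of each forearm from vertical
    initial_height_px: float = 400.0
    wrist_half_gap_px: float = 6.0  # stacked hands: small horizontal offset
    base_confidence: float = 0.95

    def __post_init__(self) -> None:
        checks = [
            (self.true_depth_cm > 0, "true_depth_cm must be > 0"),
            (self.rate_bpm > 0, "rate_bpm must be > 0"),
            (self.rate_px_per_cm > 0, "rate_px_per_cm must be > 0"),
            (0 < self.elbow_angle_deg <= 180, "elbow_angle_deg must be in (0, 180]"),
            (self.fps > 0, "fps must be > 0"),
            (self.n_phases >= 1, "n_phases must be >= 1"),
            (self.presses_per_phase >= 1, "presses_per_phase must be >= 1"),
            (self.pause_s >= 0, "pause_s must be >= 0"),
            (self.noise_px_sd >= 0, "noise_px_sd must be >= 0"),
            (0 <= self.dropout_prob < 1, "dropout_prob must be in [0, 1)"),
            (0 < self.recoil_fraction <= 1, "recoil_fraction must be in (0, 1]"),
            (self.segment_px > 0, "segment_px must be > 0"),
            (self.lead_in_s >= 0, "lead_in_s must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


@dataclass
class GroundTruth:
    """What the generator actually put into a trace."""

    press_bottom_times: np.ndarray  # seconds, one per press
    press_depth_cm: np.ndarray  # cm, one per press
    phase_intervals: list[tuple[float, float, str]]  # (start, end, "CPR"/"UNCPR")
    elbow_angles_deg: np.ndarray  # degrees, one per frame
    rate_bpm: float
    px_per_cm: float

    def phase_at(self, t: float) -> str:
        """Ground-truth phase label at time ``t`` ("UNCPR" outside all intervals)."""
        for start, end, label in self.phase_intervals:
            if start <= t < end:
                return label
        return "UNCPR"

    def to_dict(self) -> dict:
        return {
            "schema_version": "truth/1",
            "press_bottom_times": self.press_bottom_times.tolist(),
            "press_depth_cm": self.press_depth_cm.tolist(),
            "phase_intervals": [list(iv) for iv in self.phase_intervals],
            "rate_bpm": self.rate_bpm,
            "px_per_cm": self.px_per_cm,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _unit(theta_rad: float) -> np.ndarray:
    """Unit vector pointing 'up' (negative y) tilted by theta toward +x."""
    return np.array([math.sin(theta_rad), -math.cos(theta_rad)])


def arm_geometry(
    angle_deg: float,
    segment_px: float,
    wrist_anchor: Sequence[float],
    tilt_deg: float = 10.0,
    side: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place shoulder, elbow, wrist so the elbow angle equals ``angle_deg``.

    The forearm points upward from the wrist, splayed ``tilt_deg`` from
    vertical toward ``side`` (+1 right, -1 left); the upper arm bends a
    further ``180 - angle_deg`` in the same direction, which fixes the
    interior shoulder–elbow–wrist angle at exactly ``angle_deg``.
    """
    if not (0 < angle_deg <= 180):
        raise ValidationError("elbow angle must be in (0, 180] degrees")
    if segment_px <= 0:
        raise ValidationError("segment_px must be > 0")
    wrist = np.asarray(wrist_anchor, dtype=float)
    a = side * math.radians(tilt_deg)
    b = a + side * math.radians(180.0 - angle_deg)
    elbow = wrist + segment_px * _unit(a)
    shoulder = elbow + segment_px * _unit(b)
    return shoulder, elbow, wrist


def generate_session(spec: SyntheticSpec) -> tuple[KeypointTrace, GroundTruth]:
    """Generate one session trace plus its ground truth."""
    f = spec.rate_bpm / 60.0
    period = 1.0 / f
    amp = spec.true_depth_cm * spec.rate_px_per_cm
    phase_dur = spec.presses_per_phase * period
    y0 = spec.initial_height_px
    cx = 320.0

    phase_starts = [
        spec.lead_in_s + i * (phase_dur + spec.pause_s) for i in range(spec.n_phases)
    ]
    total = spec.lead_in_s + spec.n_phases * (phase_dur + spec.pause_s)
    n_frames = int(round(total * spec.fps)) + 1
    times = np.arange(n_frames) / spec.fps

    # vertical offset of the whole arm chain at each sample
    dy = np.zeros(n_frames)
    for s in phase_starts:
        mask = (times >= s) & (times < s + phase_dur)
        tau = times[mask] - s
        k = np.floor(tau * f)
        top = np.where(k == 0, 0.0, (1.0 - spec.recoil_fraction) * amp)
        dy[mask] = top + (amp - top) * (1.0 - np.cos(2.0 * math.pi * f * tau)) / 2.0

    # static geometry of both arms at rest
    base: dict[str, np.ndarray] = {}
    for side, prefix in ((1, "right"), (-1, "left")):
        wrist_anchor = (cx + side * spec.wrist_half_gap_px, y0)
        shoulder, elbow, wrist = arm_geometry(
            spec.elbow_angle_deg, spec.segment_px, wrist_anchor, spec.arm_tilt_deg, side
        )
        base[f"{prefix}_shoulder"] = shoulder
        base[f"{prefix}_elbow"] = elbow
        base[f"{prefix}_wrist"] = wrist

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_px_sd, size=(n_frames, len(REQUIRED_KEYPOINTS), 2)) \
        if spec.noise_px_sd > 0 else np.zeros((n_frames, len(REQUIRED_KEYPOINTS), 2))
    drop = rng.random(size=(n_frames, len(REQUIRED_KEYPOINTS))) < spec.dropout_prob

    frames: list[KeypointFrame] = []
    for i, t in enumerate(times):
        kps: dict[str, Keypoint] = {}
        for j, name in enumerate(REQUIRED_KEYPOINTS):
            x = base[name][0] + noise[i, j, 0]
            y = base[name][1] + dy[i] + noise[i, j, 1]
            conf = 0.0 if drop[i, j] else spec.base_confidence
            kps[name] = Keypoint(name=name, x=float(x), y=float(y), confidence=conf)
        frames.append(KeypointFrame(t=float(t), keypoints=kps))

    trace = KeypointTrace(
        frames=frames,
        metadata={
            "source": "synthetic",
            "fps": spec.fps,
            "px_per_cm": spec.rate_px_per_cm,
            "seed": spec.seed,
        },
    )

    bottoms = np.concatenate(
        [s + (np.arange(spec.presses_per_phase) + 0.5) * period for s in phase_starts]
    )
    depths = np.full(bottoms.shape, spec.true_depth_cm)
    intervals: list[tuple[float, float, str]] = [(0.0, spec.lead_in_s, "UNCPR")]
    for s in phase_starts:
        intervals.append((s, s + phase_dur, "CPR"))
        intervals.append((s + phase_dur, s + phase_dur + spec.pause_s, "UNCPR"))
    truth = GroundTruth(
        press_bottom_times=bottoms,
        press_depth_cm=depths,
        phase_intervals=intervals,
        elbow_angles_deg=np.full(n_frames, spec.elbow_angle_deg),
        rate_bpm=spec.rate_bpm,
        px_per_cm=spec.rate_px_per_cm,
    )
    return trace, truth
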