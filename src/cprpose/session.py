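"""Session orchestration: one pass over a trace, coded feedback out.

``run_session`` reproduces the live assessment flow: every frame passes
a person-presence gate, sliding windows feed the phase classifier that
drives cycle counting, the press state machine detects compressions,
and each press is scored for depth, frequency and elbow posture against
the guideline bands.  Non-compliant presses emit coded, timestamped
feedback events (the on-device system speaks these; here they are
machine-readable records).  The session terminates once the configured
number of cycles (default 5) is complete.

Frequency feedback uses the mean of the last few press times rather
than the single most recent one: a per-press period is quantised by the
capture frame rate and a short average keeps the spoken banding from
flapping at band edges.  Per-press *metrics* always carry the
instantaneous ``60 / press_time``.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .detector import DetectorConfig, PressDetector
from .keypoints import (
    KeypointFrame,
    KeypointTrace,
    ValidationError,
    lowest_wrist_y,
    person_present,
)
from .metrics import (
    Calibration,
    ElbowTriple,
    FeedbackThresholds,
    PressMetrics,
    classify_press,
)
from .phases import (
    CPR,
    UNCPR,
    AmplitudeThresholdModel,
    CycleConfig,
    PhaseModel,
    SessionState,
    classify_phase,
    phase_features,
    update_cycle,
)

__all__ = ["FeedbackEvent", "SessionReport", "run_session", "summarize", "EVENT_CODES", "MESSAGES"]

logger = logging.getLogger(__name__)

EVENT_CODES = (
    "MISSING",
    "NEXT_CYCLE",
    "TOO_SHALLOW",
    "TOO_DEEP",
    "TOO_SLOW",
    "TOO_FAST",
    "POSE_ABNORMAL",
    "SESSION_END",
)

#: Display strings per code; swappable catalog (e.g. "Pressing too slow"
#: vs "Please press faster" are alternative phrasings of TOO_SLOW).
MESSAGES: dict[str, str] = {
    "MISSING": "Missing",
    "NEXT_CYCLE": "Next cycle",
    "TOO_SHALLOW": "Pressing too shallow",
    "TOO_DEEP": "Pressing too deep",
    "TOO_SLOW": "Pressing too slow",
    "TOO_FAST": "Pressing too fast",
    "POSE_ABNORMAL": "Abnormal compression pose",
    "SESSION_END": "Session complete",
}


@dataclass(frozen=True)
class FeedbackEvent:
    """One coded feedback message with the metric value that triggered it."""

    timestamp: float
    code: str
    value: Optional[float]
    message: str

    def __post_init__(self) -> None:
        if self.code not in EVENT_CODES:
            raise ValidationError(f"unknown feedback code {self.code!r}")

    def to_dict(self) -> dict:
        return {
            "t": self.timestamp,
            "code": self.code,
            "value": self.value,
            "message": self.message,
        }


@dataclass
class SessionReport:
    """Everything a completed session produced."""

    presses: list[PressMetrics]
    events: list[FeedbackEvent]
    cycles_completed: int
    summary: dict
    press_cycles: list[int] = field(default_factory=list)  # cycle index per press

    def to_dict(self) -> dict:
        return {
            "schema_version": "report/1",
            "cycles_completed": self.cycles_completed,
            "presses": [
                {
                    "cycle": c,
                    "bottom_time_s": p.bottom_time_s,
                    "press_time_s": p.press_time_s,
                    "depth_cm": p.depth_cm,
                    "frequency_bpm": p.frequency_bpm,
                    "left_elbow_deg": p.left_elbow_deg,
                    "right_elbow_deg": p.right_elbow_deg,
                    "depth_band": p.depth_band,
                    "freq_band": p.freq_band,
                    "posture": p.posture,
                }
                for p, c in zip(self.presses, self.press_cycles)
            ],
            "events": [e.to_dict() for e in self.events],
            "summary": self.summary,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def write_events_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for e in self.events:
                fh.write(json.dumps(e.to_dict()) + "\n")


def _arm_triples(frame: KeypointFrame) -> tuple[ElbowTriple, ElbowTriple]:
    def tri(prefix: str) -> ElbowTriple:
        s = frame.require(f"{prefix}_shoulder")
        e = frame.require(f"{prefix}_elbow")
        w = frame.require(f"{prefix}_wrist")
        return ElbowTriple(A=(s.x, s.y), B=(e.x, e.y), C=(w.x, w.y))

    return tri("left"), tri("right")


def run_session(
    trace: KeypointTrace,
    cal: Calibration,
    detector_cfg: DetectorConfig | None = None,
    thresholds: FeedbackThresholds | None = None,
    cycle_cfg: CycleConfig | None = None,
    phase_model: PhaseModel | None = None,
    freq_window_presses: int = 3,
) -> SessionReport:
    """Assess one full session trace; deterministic for fixed inputs."""
    if cal is None:
        raise ValidationError(
            "calibration required: provide Calibration(px_per_cm=...) or derive one "
            "with Calibration.from_reference(length_px, length_cm)"
        )
    if not trace.frames:
        raise ValidationError("cannot run a session on an empty trace")
    cfg = detector_cfg or DetectorConfig()
    thr = thresholds or FeedbackThresholds()
    cyc = cycle_cfg or CycleConfig()
    model = phase_model or AmplitudeThresholdModel()

    det = PressDetector(cfg)
    st = SessionState()
    events: list[FeedbackEvent] = []
    presses: list[PressMetrics] = []
    press_cycles: list[int] = []
    recent: deque[KeypointFrame] = deque()
    recent_pts: deque[float] = deque(maxlen=max(1, freq_window_presses))
    step = cyc.window_s / 2.0
    next_eval = trace.frames[0].t + cyc.window_s
    in_gap = False
    keep_span = max(2.0 * cyc.window_s, 5.0)
    last_t = trace.frames[0].t

    def emit(t: float, code: str, value: Optional[float] = None) -> None:
        events.append(FeedbackEvent(timestamp=t, code=code, value=value, message=MESSAGES[code]))

    for frame in trace.frames:
        t = frame.t
        last_t = t
        if not person_present(frame, cfg.min_confidence):
            if not in_gap:
                emit(t, "MISSING")
                in_gap = True
            det.reset()
            continue
        in_gap = False
        recent.append(frame)
        while recent and recent[0].t < t - keep_span:
            recent.popleft()

        # scheduled phase classification (50 % overlapping windows)
        while t >= next_eval:
            lo = next_eval - cyc.window_s
            wframes = [fr for fr in recent if lo <= fr.t <= next_eval]
            if wframes:
                try:
                    feats = phase_features(wframes)
                except ValidationError:
                    feats = None
                if feats is not None:
                    label = classify_phase(feats, model)
                    prev = st.previous_phase
                    st = update_cycle(st, label, press_emitted=False, cfg=cyc)
                    if prev == CPR and label.label == UNCPR and not st.terminated:
                        emit(next_eval, "NEXT_CYCLE")
            next_eval += step

        ev = det.step(t, lowest_wrist_y(frame))
        if ev is not None:
            st = update_cycle(st, None, press_emitted=True, cfg=cyc)
            bframe = min(recent, key=lambda fr: abs(fr.t - ev.end_time))
            tri_left, tri_right = _arm_triples(bframe)
            pm = classify_press(ev, tri_left, tri_right, cal, thr)
            presses.append(pm)
            press_cycles.append(max(st.cycle_count, 1))

            if pm.depth_band == "shallow":
                emit(ev.end_time, "TOO_SHALLOW", pm.depth_cm)
            elif pm.depth_band == "deep":
                emit(ev.end_time, "TOO_DEEP", pm.depth_cm)

            recent_pts.append(ev.press_time)
            fb_bpm = 60.0 * len(recent_pts) / sum(recent_pts)
            if fb_bpm < thr.freq_min_bpm:
                emit(ev.end_time, "TOO_SLOW", fb_bpm)
            elif fb_bpm > thr.freq_max_bpm:
                emit(ev.end_time, "TOO_FAST", fb_bpm)

            if pm.posture == "abnormal":
                emit(ev.end_time, "POSE_ABNORMAL", min(pm.left_elbow_deg, pm.right_elbow_deg))

        if st.terminated:
            break

    events.sort(key=lambda e: e.timestamp)
    emit(last_t, "SESSION_END")
    report = SessionReport(
        presses=presses,
        events=events,
        cycles_completed=min(st.cycle_count, cyc.max_cycles),
        summary={},
        press_cycles=press_cycles,
    )
    report.summary = summarize(report)
    return report


def summarize(report: SessionReport) -> dict:
    """Per-cycle and whole-session means and compliance fractions.

    Compliance percentages are straight counts over the press list; an
    empty press list yields a flagged summary with undefined means.
    """
    presses = report.presses
    if not presses:
        logger.warning("summarizing a session with no detected presses")
        return {
            "n_presses": 0,
            "mean_depth_cm": None,
            "mean_frequency_bpm": None,
            "pct_depth_ok": None,
            "pct_freq_ok": None,
            "pct_posture_normal": None,
            "per_cycle": {},
        }

    def block(sub: list[PressMetrics]) -> dict:
        n = len(sub)
        return {
            "n_presses": n,
            "mean_depth_cm": sum(p.depth_cm for p in sub) / n,
            "mean_frequency_bpm": sum(p.frequency_bpm for p in sub) / n,
            "pct_depth_ok": 100.0 * sum(p.depth_band == "ok" for p in sub) / n,
            "pct_freq_ok": 100.0 * sum(p.freq_band == "ok" for p in sub) / n,
            "pct_posture_normal": 100.0 * sum(p.posture == "normal" for p in sub) / n,
        }

    out = block(presses)
    per_cycle: dict[str, dict] = {}
    for cycle in sorted(set(report.press_cycles)):
        sub = [p for p, c in zip(presses, report.press_cycles) if c == cycle]
        per_cycle[str(cycle)] = block(sub)
    out["per_cycle"] = per_cycle
    return out
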