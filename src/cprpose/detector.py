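"""Three-state press detector over the wrist-y trajectory.

The machine watches the lowest-wrist pixel y (image convention: larger y
is lower) and measures the bottom-to-bottom press time of successive
compressions:

* **state 0 — rest**: track the resting wrist height (``initialHeight``)
  until the wrist starts moving down.
* **state 1 — first descent**: track the descending extreme.  When the
  wrist turns upward and the excursion from ``initialHeight`` exceeds
  ``start_threshold_px`` (default 15.5 px), record the bottom time as
  ``startTime`` and move to state 2; a smaller excursion is jitter and
  the machine falls back to rest.
* **state 2 — cycling**: once the wrist has recoiled to within
  ``return_threshold_px`` (default 5 px) of ``initialHeight`` the next
  press is armed.  When the wrist descends back to within the return
  threshold of the previous bottom and turns upward again, the new
  bottom time is ``endTime`` and one press event is emitted with
  ``press_time = endTime - startTime``.  The machine then re-arms in
  state 2 (``startTime <- endTime``) so every subsequent press yields
  exactly one event.

"Turns upward/downward" is a sign change of the frame-to-frame wrist-y
difference exceeding a small hysteresis (default 1 px).  If the wrist
rests near ``initialHeight`` for longer than ``rest_timeout_s`` the
machine resets to state 0, so a pause between compression phases never
contributes a spuriously long press time.

Bottom samples can optionally be refined to sub-frame resolution with a
three-point parabolic vertex fit (on by default); see docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional

from .keypoints import (
    KeypointTrace,
    ValidationError,
    lowest_wrist_y,
    person_present,
)

__all__ = ["DetectorConfig", "DetectorState", "PressEvent", "PressDetector", "detect_presses"]

logger = logging.getLogger(__name__)

#: Calibration at which the stock pixel thresholds were defined (px/cm).
REFERENCE_PX_PER_CM = 10.0


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable constants of the press state machine (pixels / seconds)."""

    start_threshold_px: float = 15.5
    return_threshold_px: float = 5.0
    min_confidence: float = 0.3
    hysteresis_px: float = 1.0
    rest_timeout_s: float = 2.0
    smooth_window: int = 1  # moving-average length; 1 disables smoothing
    refine_bottom: bool = True

    def __post_init__(self) -> None:
        if self.start_threshold_px <= 0 or self.return_threshold_px <= 0:
            raise ValidationError("detector thresholds must be > 0 px")
        if self.start_threshold_px <= self.return_threshold_px:
            raise ValidationError("start_threshold_px must exceed return_threshold_px")
        if self.hysteresis_px < 0:
            raise ValidationError("hysteresis_px must be >= 0")
        if self.rest_timeout_s <= 0:
            raise ValidationError("rest_timeout_s must be > 0")
        if self.smooth_window < 1:
            raise ValidationError("smooth_window must be >= 1")

    def scaled_for(self, px_per_cm: float, reference: float = REFERENCE_PX_PER_CM) -> "DetectorConfig":
        """Rescale the pixel thresholds to a different capture calibration.

        The stock 15.5/5 px thresholds are resolution dependent; this
        keeps their physical meaning (cm of wrist travel) constant.
        """
        if px_per_cm <= 0:
            raise ValidationError("px_per_cm must be > 0")
        s = px_per_cm / reference
        return replace(
            self,
            start_threshold_px=self.start_threshold_px * s,
            return_threshold_px=self.return_threshold_px * s,
            hysteresis_px=self.hysteresis_px * s,
        )


@dataclass(frozen=True)
class PressEvent:
    """One detected compression (times in seconds, heights in pixel y)."""

    start_time: float
    end_time: float
    press_time: float
    bottom_y: float
    initial_height: float

    def __post_init__(self) -> None:
        if not self.press_time > 0:
            raise ValidationError(f"press_time must be > 0, got {self.press_time}")
        if not self.bottom_y > self.initial_height:
            raise ValidationError("press bottom must lie below the initial height (y-down)")


@dataclass
class DetectorState:
    """Mutable state of the press machine; see the module docstring."""

    state: int = 0
    initial_height: float = math.nan
    wrist_y1: float = math.nan  # previous press-bottom y
    wrist_y2: float = math.nan  # recoil-top y
    start_time: float = math.nan
    end_time: float = math.nan
    is_ready_for_second_cycle: bool = False
    # internal trackers
    rest_ref: float = math.nan
    bottom: float = math.nan
    bottom_t: float = math.nan
    armed_t: float = math.nan
    bottom_pending: bool = False
    prev_t: float = math.nan


class PressDetector:
    """Streaming driver around :class:`DetectorState`.

    Feed ``step(t, wrist_y)`` one sample at a time; a
    :class:`PressEvent` is returned whenever a compression completes.
    """

    def __init__(self, cfg: DetectorConfig | None = None):
        self.cfg = cfg or DetectorConfig()
        self.state = DetectorState()
        self._smooth: deque[float] = deque(maxlen=self.cfg.smooth_window)
        self._recent: deque[tuple[float, float]] = deque(maxlen=8)

    def reset(self) -> None:
        """Drop all state, e.g. after the person left the frame."""
        self.state = DetectorState()
        self._smooth.clear()
        self._recent.clear()

    # -- sub-frame bottom refinement -------------------------------------

    def _refined_bottom(self) -> tuple[float, float]:
        """Parabolic vertex through the bottom sample and its neighbours.

        Falls back to the raw sample when the fit is degenerate or the
        vertex lands outside the neighbouring samples.
        """
        st = self.state
        if not self.cfg.refine_bottom:
            return st.bottom_t, st.bottom
        pts = list(self._recent)
        idx = next((i for i, (t, _) in enumerate(pts) if t == st.bottom_t), None)
        if idx is None or idx == 0 or idx == len(pts) - 1:
            return st.bottom_t, st.bottom
        (t0, y0), (t1, y1), (t2, y2) = pts[idx - 1], pts[idx], pts[idx + 1]
        # quadratic through three (t, y); vertex of y = a t^2 + b t + c
        d01, d02, d12 = t0 - t1, t0 - t2, t1 - t2
        denom = d01 * d02 * d12
        if denom == 0:
            return st.bottom_t, st.bottom
        a = (d12 * y0 - d02 * y1 + d01 * y2) / denom
        if a >= 0:  # not a maximum in y
            return st.bottom_t, st.bottom
        b = (-(t1 + t2) * d12 * y0 + (t0 + t2) * d02 * y1 - (t0 + t1) * d01 * y2) / denom
        tv = -b / (2.0 * a)
        if not (t0 <= tv <= t2):
            return st.bottom_t, st.bottom
        c = (y0 - a * t0 * t0 - b * t0)
        yv = a * tv * tv + b * tv + c
        return tv, max(yv, st.bottom)

    # -- state machine ----------------------------------------------------

    def step(self, t: float, wrist_y: float) -> Optional[PressEvent]:
        """Advance the machine by one sample; maybe emit a press event."""
        st = self.state
        cfg = self.cfg
        if not math.isnan(st.prev_t) and t <= st.prev_t:
            raise ValidationError(f"non-monotone sample time: {t} after {st.prev_t}")
        if math.isnan(wrist_y):
            logger.warning("skipping frame at t=%.3f: wrist y is NaN", t)
            return None
        st.prev_t = t

        self._smooth.append(wrist_y)
        y = sum(self._smooth) / len(self._smooth)
        self._recent.append((t, y))
        hys = cfg.hysteresis_px
        event: Optional[PressEvent] = None

        if st.state == 0:
            if math.isnan(st.rest_ref):
                st.rest_ref = y
            elif y > st.rest_ref + hys:  # wrist starts moving down
                st.initial_height = st.rest_ref
                st.bottom, st.bottom_t = y, t
                st.state = 1
            else:
                st.rest_ref += 0.2 * (y - st.rest_ref)  # follow slow drift

        elif st.state == 1:
            if y >= st.bottom:
                st.bottom, st.bottom_t = y, t
            elif y < st.bottom - hys:  # wrist turned upward
                if st.bottom - st.initial_height > cfg.start_threshold_px:
                    st.start_time, st.wrist_y1 = self._refined_bottom()
                    st.state = 2
                    st.is_ready_for_second_cycle = False
                    st.bottom_pending = False
                    st.armed_t = math.nan
                else:  # jitter, not a press
                    st.state = 0
                    st.rest_ref = y

        else:  # state 2
            if not st.is_ready_for_second_cycle:
                if abs(y - st.initial_height) < cfg.return_threshold_px:
                    st.is_ready_for_second_cycle = True
                    st.wrist_y2 = y
                    st.armed_t = t
            elif not st.bottom_pending:
                st.wrist_y2 = min(st.wrist_y2, y)
                if st.wrist_y1 - y < cfg.return_threshold_px:
                    # wrist back within the return band of the previous bottom
                    st.bottom_pending = True
                    st.bottom, st.bottom_t = y, t
                elif t - st.armed_t > cfg.rest_timeout_s:
                    # no follow-up press: pause between phases -> full reset
                    st.state = 0
                    st.rest_ref = y
                    st.is_ready_for_second_cycle = False
            else:
                if y >= st.bottom:
                    st.bottom, st.bottom_t = y, t
                elif y < st.bottom - hys:  # new bottom confirmed
                    st.end_time, bottom_y = self._refined_bottom()
                    event = PressEvent(
                        start_time=st.start_time,
                        end_time=st.end_time,
                        press_time=st.end_time - st.start_time,
                        bottom_y=bottom_y,
                        initial_height=st.initial_height,
                    )
                    st.wrist_y1 = bottom_y
                    st.start_time = st.end_time
                    st.is_ready_for_second_cycle = False
                    st.bottom_pending = False

        return event


def detect_presses(trace: KeypointTrace, cfg: DetectorConfig | None = None) -> list[PressEvent]:
    """Run the press machine over a whole trace.

    Frames failing the presence gate reset the machine: a stale resting
    height is unsafe after an occlusion.  Events come back ordered by
    start time; the result is deterministic for a fixed trace + config.
    """
    cfg = cfg or DetectorConfig()
    det = PressDetector(cfg)
    events: list[PressEvent] = []
    for frame in trace.frames:
        if not person_present(frame, cfg.min_confidence):
            det.reset()
            continue
        ev = det.step(frame.t, lowest_wrist_y(frame))
        if ev is not None:
            events.append(ev)
    return events
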