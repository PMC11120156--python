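"""Domain types and file I/O for 2-D pose-keypoint traces.

Coordinate convention
---------------------
All coordinates are **image pixels** with the y axis pointing *down*: a
larger y value means the point is physically lower in the scene.  Every
depth computation in this package relies on that convention, so the
lowest wrist in a frame is the one with the *maximum* y.

The six keypoints required for compression analysis are the left/right
shoulder, elbow and wrist (the "arm" points of the upper-limb skeleton).
Traces may carry additional named keypoints; they are ignored by the
analysis but preserved by the JSON-lines dialect.

File dialects
-------------
``csv``
    Header ``t,<name>_x,<name>_y,<name>_c,...`` over the six required
    keypoints in the order of :data:`REQUIRED_KEYPOINTS`.  An optional
    first line ``#meta {...}`` carries trace metadata as JSON.
``jsonl``
    One JSON object per line: ``{"t": <s>, "kp": {"<name>": [x, y, c]}}``.
    An optional first line ``{"_meta": {...}}`` carries metadata.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = [
    "REQUIRED_KEYPOINTS",
    "ValidationError",
    "MissingKeypointError",
    "Keypoint",
    "KeypointFrame",
    "KeypointTrace",
    "lowest_wrist_y",
    "person_present",
    "read_trace",
    "write_trace",
]

#: Keypoint names every frame must carry (possibly at zero confidence).
REQUIRED_KEYPOINTS: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
)

#: Default confidence below which a keypoint is treated as undetected.
DEFAULT_MIN_CONFIDENCE = 0.3


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class MissingKeypointError(ValidationError):
    """A required keypoint is absent from a frame."""

    def __init__(self, name: str):
        self.keypoint = name
        super().__init__(f"required keypoint {name!r} is missing from frame")


@dataclass(frozen=True)
class Keypoint:
    """One named keypoint in image-pixel coordinates (y down)."""

    name: str
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"keypoint {self.name!r} has non-finite coordinates ({self.x}, {self.y})"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"keypoint {self.name!r} confidence {self.confidence} outside [0, 1]"
            )


@dataclass
class KeypointFrame:
    """All keypoints observed at one timestamp (seconds)."""

    t: float
    keypoints: dict[str, Keypoint]

    def require(self, name: str) -> Keypoint:
        """Return keypoint ``name`` or raise :class:`MissingKeypointError`."""
        try:
            return self.keypoints[name]
        except KeyError:
            raise MissingKeypointError(name) from None


@dataclass
class KeypointTrace:
    """A time-ordered sequence of keypoint frames.

    Timestamps must be strictly increasing.  ``metadata`` is free-form
    (fps hint, source, calibration in px/cm when known).
    """

    frames: list[KeypointFrame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.frames, self.frames[1:]):
            if cur.t <= prev.t:
                raise ValidationError(
                    f"trace timestamps must be strictly increasing "
                    f"({prev.t} followed by {cur.t})"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[KeypointFrame]:
        return iter(self.frames)

    @property
    def duration(self) -> float:
        """Span from first to last timestamp in seconds (0 if < 2 frames)."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].t - self.frames[0].t


def lowest_wrist_y(frame: KeypointFrame) -> float:
    """Pixel y of the physically lowest wrist.

    With the image y-down convention the lowest wrist has the maximum
    pixel y, so this is ``max(left_wrist.y, right_wrist.y)``.
    """
    left = frame.require("left_wrist")
    right = frame.require("right_wrist")
    return max(left.y, right.y)


def person_present(frame: KeypointFrame, min_confidence: float = DEFAULT_MIN_CONFIDENCE) -> bool:
    """True iff all six required keypoints are detected confidently.

    Degenerate frames (missing keypoints) return False rather than raise:
    presence gating has to tolerate arbitrary pose-backend output.
    """
    for name in REQUIRED_KEYPOINTS:
        kp = frame.keypoints.get(name)
        if kp is None or kp.confidence < min_confidence:
            return False
    return True


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "#meta "


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        return "jsonl"
    return "csv"


def _csv_header() -> list[str]:
    cols = ["t"]
    for name in REQUIRED_KEYPOINTS:
        cols += [f"{name}_x", f"{name}_y", f"{name}_c"]
    return cols


def write_trace(trace: KeypointTrace, path: str | Path, dialect: str | None = None) -> None:
    """Write ``trace`` to ``path`` in the given dialect (inferred from suffix).

    Column/key order is stable; floats are written with ``repr`` so finite
    values round-trip bit-exactly through :func:`read_trace`.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            if trace.metadata:
                fh.write(_META_PREFIX + json.dumps(trace.metadata, sort_keys=True) + "\n")
            writer = csv.writer(fh)
            writer.writerow(_csv_header())
            for fr in trace.frames:
                row: list[str] = [repr(float(fr.t))]
                for name in REQUIRED_KEYPOINTS:
                    kp = fr.require(name)
                    row += [repr(float(kp.x)), repr(float(kp.y)), repr(float(kp.confidence))]
                writer.writerow(row)
    elif dialect == "jsonl":
        with path.open("w") as fh:
            if trace.metadata:
                fh.write(json.dumps({"_meta": trace.metadata}, sort_keys=True) + "\n")
            for fr in trace.frames:
                kp = {
                    name: [k.x, k.y, k.confidence]
                    for name, k in sorted(fr.keypoints.items())
                }
                fh.write(json.dumps({"t": fr.t, "kp": kp}) + "\n")
    else:
        raise ValidationError(f"unknown trace dialect {dialect!r} (expected 'csv' or 'jsonl')")


def read_trace(path: str | Path, dialect: str | None = None) -> KeypointTrace:
    """Read a keypoint trace written by :func:`write_trace`.

    Raises :class:`ValidationError` with a line number for malformed rows,
    for empty files, and for non-monotone timestamps.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        frames, meta = _read_csv(path)
    elif dialect == "jsonl":
        frames, meta = _read_jsonl(path)
    else:
        raise ValidationError(f"unknown trace dialect {dialect!r} (expected 'csv' or 'jsonl')")
    if not frames:
        raise ValidationError(f"{path}: trace file contains no frames")
    return KeypointTrace(frames=frames, metadata=meta)


def _read_csv(path: Path) -> tuple[list[KeypointFrame], dict]:
    meta: dict = {}
    frames: list[KeypointFrame] = []
    expected = _csv_header()
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith(_META_PREFIX):
        try:
            meta = json.loads(lines[0][len(_META_PREFIX):])
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}, line 1: malformed metadata JSON: {exc}") from exc
        start = 1
    rows = list(csv.reader(lines[start:]))
    if not rows:
        raise ValidationError(f"{path}: trace file contains no frames")
    header = rows[0]
    if header != expected:
        raise ValidationError(
            f"{path}, line {start + 1}: unexpected CSV header {header!r}"
        )
    for i, row in enumerate(rows[1:], start=start + 2):
        if not row:
            continue
        if len(row) != len(expected):
            raise ValidationError(
                f"{path}, line {i}: expected {len(expected)} fields, got {len(row)}"
            )
        try:
            t = float(row[0])
            kps: dict[str, Keypoint] = {}
            for j, name in enumerate(REQUIRED_KEYPOINTS):
                x, y, c = (float(v) for v in row[1 + 3 * j: 4 + 3 * j])
                kps[name] = Keypoint(name=name, x=x, y=y, confidence=c)
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
        frames.append(KeypointFrame(t=t, keypoints=kps))
    return frames, meta


def _read_jsonl(path: Path) -> tuple[list[KeypointFrame], dict]:
    meta: dict = {}
    frames: list[KeypointFrame] = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}, line {i}: malformed JSON: {exc}") from exc
            if i == 1 and "_meta" in obj:
                meta = obj["_meta"]
                continue
            try:
                t = float(obj["t"])
                kps = {
                    name: Keypoint(name=name, x=float(v[0]), y=float(v[1]), confidence=float(v[2]))
                    for name, v in obj["kp"].items()
                }
            except (KeyError, TypeError, IndexError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}, line {i}: malformed frame record: {exc}") from exc
            frames.append(KeypointFrame(t=t, keypoints=kps))
    return frames, meta
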