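"""CPR/UNCPR phase classification and compression-cycle tracking.

A training session alternates active compression phases ("CPR") with
pauses for checks ("UNCPR"); every 30 compressions followed by a pause
constitutes one cycle, and a full session is 5 cycles.  Phases are
classified over short sliding windows of keypoint frames with a
two-class softmax model:

* the default is a deterministic amplitude-threshold model requiring no
  training — a window whose normalised wrist-y excursion exceeds a
  threshold is CPR;
* alternatively a small feed-forward network (one hidden layer, trained
  with scikit-learn) can be fit on labelled windows; inference runs a
  plain forward pass over the stored weights so probabilities are
  always an explicit softmax over the model logits.

Features are scale-free: wrist-y variance, mean |frame-to-frame delta|
and peak-to-trough excursion, each normalised by the shoulder-to-
shoulder pixel distance, so the classifier is invariant to camera zoom.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.special import softmax as _softmax

from .keypoints import KeypointFrame, ValidationError, lowest_wrist_y
from .synthetic import GroundTruth

__all__ = [
    "CPR",
    "UNCPR",
    "PhaseLabel",
    "CycleConfig",
    "SessionState",
    "phase_features",
    "classify_phase",
    "train_phase_classifier",
    "update_cycle",
    "AmplitudeThresholdModel",
    "MLPPhaseModel",
    "extract_labeled_windows",
    "save_phase_model",
    "load_phase_model",
]

CPR = "CPR"
UNCPR = "UNCPR"
CLASSES = (CPR, UNCPR)

N_FEATURES = 3


@dataclass(frozen=True)
class PhaseLabel:
    """A classified window: hard label plus softmax probabilities."""

    label: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"phase probabilities sum to {total}, not 1")
        argmax = max(self.probabilities, key=self.probabilities.get)  # type: ignore[arg-type]
        if self.probabilities[argmax] != self.probabilities[self.label]:
            raise ValidationError("phase label inconsistent with probability argmax")


@dataclass(frozen=True)
class CycleConfig:
    """Cycle-protocol constants: 30 presses per cycle, 5 cycles total."""

    presses_per_cycle: int = 30
    max_cycles: int = 5
    window_s: float = 1.0  # classifier window; overlaps 50 %

    def __post_init__(self) -> None:
        if self.presses_per_cycle < 1 or self.max_cycles < 1 or self.window_s <= 0:
            raise ValidationError("cycle configuration values must be positive")


@dataclass(frozen=True)
class SessionState:
    """Running cycle bookkeeping (immutable; updates return new state)."""

    cycle_count: int = 0
    presses_in_cycle: int = 0
    previous_phase: str = UNCPR
    terminated: bool = False


def phase_features(window: Sequence[KeypointFrame]) -> np.ndarray:
    """Scale-free motion features of one window of frames.

    Returns ``[variance, mean |delta|, peak-to-trough]`` of the lowest-
    wrist y series, each normalised by the mean shoulder-to-shoulder
    distance.  Frames whose wrists or shoulders are undetected
    (confidence 0) are skipped; a window with no usable frame is an
    error.
    """
    ys: list[float] = []
    widths: list[float] = []
    for fr in window:
        lw = fr.keypoints.get("left_wrist")
        rw = fr.keypoints.get("right_wrist")
        ls = fr.keypoints.get("left_shoulder")
        rs = fr.keypoints.get("right_shoulder")
        if any(k is None or k.confidence <= 0 for k in (lw, rw, ls, rs)):
            continue
        ys.append(max(lw.y, rw.y))
        widths.append(math.hypot(ls.x - rs.x, ls.y - rs.y))
    if not ys:
        raise ValidationError("phase window has no frames with usable keypoints")
    width = float(np.mean(widths))
    if width <= 0:
        raise ValidationError("degenerate shoulder geometry: zero shoulder distance")
    y = np.asarray(ys) / width
    delta = np.abs(np.diff(y)).mean() if len(y) > 1 else 0.0
    return np.array([float(np.var(y)), float(delta), float(y.max() - y.min())])


class PhaseModel(Protocol):
    """Anything producing two logits (CPR, UNCPR) from a feature vector."""

    def logits(self, features: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class AmplitudeThresholdModel:
    """Deterministic fallback: threshold the excursion feature.

    A window whose normalised peak-to-trough wrist excursion exceeds
    ``threshold`` (default 0.1 shoulder widths) is CPR.  ``sharpness``
    controls how quickly the softmax saturates away from the boundary.
    """

    threshold: float = 0.1
    sharpness: float = 50.0

    def logits(self, features: np.ndarray) -> np.ndarray:
        z = self.sharpness * (float(features[2]) - self.threshold)
        return np.array([z, -z])


@dataclass(frozen=True)
class MLPPhaseModel:
    """Weights of a trained one-hidden-layer softmax classifier.

    Inference is a plain forward pass: standardise features, ReLU hidden
    layer, then logits ``[0, z]`` whose softmax reproduces the network's
    CPR/UNCPR probabilities exactly.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, 1)
    b2: np.ndarray

    def logits(self, features: np.ndarray) -> np.ndarray:
        x = (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_scale
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        z = float((h @ self.w2 + self.b2).item())  # logit of UNCPR (second class)
        return np.array([0.0, z])


def classify_phase(features: np.ndarray, model: PhaseModel | None = None) -> PhaseLabel:
    """Softmax the model logits into a :class:`PhaseLabel`."""
    if model is None:
        model = AmplitudeThresholdModel()
    probs = _softmax(np.asarray(model.logits(np.asarray(features, dtype=float)), dtype=float))
    mapping = {CLASSES[i]: float(p) for i, p in enumerate(probs)}
    label = CLASSES[int(np.argmax(probs))]
    return PhaseLabel(label=label, probabilities=mapping)


def train_phase_classifier(
    windows: Sequence[np.ndarray],
    labels: Sequence[str],
    seed: int = 0,
    hidden: int = 8,
) -> MLPPhaseModel:
    """Fit the small feed-forward phase classifier on labelled windows.

    ``windows`` are feature vectors from :func:`phase_features`;
    ``labels`` are "CPR"/"UNCPR".  Requires at least two examples per
    class; fully reproducible given ``seed``.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(list(windows), dtype=float)
    y = np.asarray(list(labels))
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValidationError(f"expected ({len(y)}, {N_FEATURES}) feature matrix, got {X.shape}")
    for cls in CLASSES:
        if int((y == cls).sum()) < 2:
            raise ValidationError(f"need at least 2 examples of class {cls!r} to train")

    scaler = StandardScaler().fit(X)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="relu",
        solver="lbfgs",  # deterministic and fast at desk-scale data sizes
        random_state=seed,
        max_iter=2000,
    ).fit(scaler.transform(X), y)
    # sklearn sorts classes: ("CPR", "UNCPR"); binary output is the
    # logit of the second class, matching MLPPhaseModel.logits.
    assert tuple(clf.classes_) == CLASSES
    return MLPPhaseModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        w1=clf.coefs_[0].copy(),
        b1=clf.intercepts_[0].copy(),
        w2=clf.coefs_[1].copy(),
        b2=clf.intercepts_[1].copy(),
    )


def update_cycle(
    state: SessionState,
    phase: PhaseLabel | None,
    press_emitted: bool,
    cfg: CycleConfig | None = None,
) -> SessionState:
    """Advance cycle bookkeeping by one observation.

    A cycle increments on every UNCPR -> CPR transition (the first CPR
    onset of a session yields cycle 1).  ``phase=None`` records a press
    without a new phase observation.  Termination latches once
    ``max_cycles`` cycles are complete — either the configured press
    count was reached or the phase fell back to UNCPR.
    """
    cfg = cfg or CycleConfig()
    if state.terminated:
        return state
    cycle_count = state.cycle_count
    presses = state.presses_in_cycle + (1 if press_emitted else 0)
    prev = state.previous_phase
    current = prev if phase is None else phase.label
    if prev == UNCPR and current == CPR:
        cycle_count += 1
        presses = 1 if press_emitted else 0
    cycle_done = presses >= cfg.presses_per_cycle or (prev == CPR and current == UNCPR)
    terminated = cycle_count >= cfg.max_cycles and cycle_done
    return SessionState(
        cycle_count=cycle_count,
        presses_in_cycle=presses,
        previous_phase=current,
        terminated=terminated,
    )


def extract_labeled_windows(
    trace, truth: GroundTruth, cfg: CycleConfig | None = None
) -> tuple[list[np.ndarray], list[str]]:
    """Cut a generated trace into 50 %-overlap windows labelled by truth.

    Each window is labelled with the ground-truth phase at its centre;
    used to build training/evaluation sets for the phase classifier.
    """
    cfg = cfg or CycleConfig()
    frames = trace.frames
    step = cfg.window_s / 2.0
    t0, t_end = frames[0].t, frames[-1].t
    feats: list[np.ndarray] = []
    labels: list[str] = []
    start = t0
    while start + cfg.window_s <= t_end:
        end = start + cfg.window_s
        window = [fr for fr in frames if start <= fr.t <= end]
        if window:
            try:
                feats.append(phase_features(window))
            except ValidationError:
                start += step
                continue
            labels.append(truth.phase_at(start + cfg.window_s / 2.0))
        start += step
    return feats, labels


# ---------------------------------------------------------------------------
# Model serialization (versioned JSON)
# ---------------------------------------------------------------------------

_MODEL_SCHEMA = "phase-model/1"


def save_phase_model(model: PhaseModel, path: str | Path) -> None:
    if isinstance(model, AmplitudeThresholdModel):
        obj = {
            "schema_version": _MODEL_SCHEMA,
            "kind": "amplitude",
            "threshold": model.threshold,
            "sharpness": model.sharpness,
        }
    elif isinstance(model, MLPPhaseModel):
        obj = {
            "schema_version": _MODEL_SCHEMA,
            "kind": "mlp",
            "scaler_mean": model.scaler_mean.tolist(),
            "scaler_scale": model.scaler_scale.tolist(),
            "w1": model.w1.tolist(),
            "b1": model.b1.tolist(),
            "w2": model.w2.tolist(),
            "b2": model.b2.tolist(),
        }
    else:
        raise ValidationError(f"cannot serialize phase model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(obj))


def load_phase_model(path: str | Path) -> PhaseModel:
    obj = json.loads(Path(path).read_text())
    if obj.get("schema_version") != _MODEL_SCHEMA:
        raise ValidationError(f"unsupported phase-model schema: {obj.get('schema_version')!r}")
    if obj["kind"] == "amplitude":
        return AmplitudeThresholdModel(threshold=obj["threshold"], sharpness=obj["sharpness"])
    if obj["kind"] == "mlp":
        return MLPPhaseModel(
            scaler_mean=np.asarray(obj["scaler_mean"]),
            scaler_scale=np.asarray(obj["scaler_scale"]),
            w1=np.asarray(obj["w1"]),
            b1=np.asarray(obj["b1"]),
            w2=np.asarray(obj["w2"]),
            b2=np.asarray(obj["b2"]),
        )
    raise ValidationError(f"unknown phase-model kind {obj['kind']!r}")
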