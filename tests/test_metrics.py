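"""Depth, frequency and elbow-angle formulas plus band classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cprpose import (
    Calibration,
    ElbowTriple,
    FeedbackThresholds,
    PressEvent,
    ValidationError,
    classify_press,
    compression_depth,
    compression_frequency,
    compressions_per_second,
    elbow_angle,
    press_period_s,
)

CAL = Calibration(px_per_cm=10.0)


class TestDepth:
    def test_50_px_at_10_px_per_cm_is_5_cm(self):
        assert compression_depth(300.0, 250.0, CAL) == 5.0

    def test_zero_displacement(self):
        assert compression_depth(250.0, 250.0, CAL) == 0.0

    def test_linearity(self):
        d1 = compression_depth(270.0, 250.0, CAL)
        d2 = compression_depth(290.0, 250.0, CAL)
        assert d2 == pytest.approx(2 * d1)

    def test_bottom_above_initial_rejected(self):
        with pytest.raises(ValidationError):
            compression_depth(240.0, 250.0, CAL)

    def test_calibration_from_reference(self):
        cal = Calibration.from_reference(length_px=120.0, length_cm=12.0)
        assert cal.px_per_cm == 10.0


class TestFrequency:
    @pytest.mark.parametrize("pt,bpm", [(0.6, 100.0), (0.5, 120.0), (1.0, 60.0)])
    def test_worked_examples(self, pt, bpm):
        assert compression_frequency(pt) == pytest.approx(bpm, abs=1e-9)

    def test_rate_band_arithmetic(self):
        assert press_period_s(120.0) == 0.5
        assert compressions_per_second(100.0) == pytest.approx(1.667, abs=5e-4)

    @given(f=st.floats(1.0, 500.0))
    def test_involution(self, f):
        assert compression_frequency(60.0 / f) == pytest.approx(f, rel=1e-12)

    def test_nonpositive_press_time_rejected(self):
        with pytest.raises(ValidationError):
            compression_frequency(0.0)


def dot_product_angle(tri: ElbowTriple) -> float:
    """Independent oracle: angle at B via acos(u.v / |u||v|)."""
    u = np.asarray(tri.A) - np.asarray(tri.B)
    v = np.asarray(tri.C) - np.asarray(tri.B)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def random_triples(n, rng, lo=0.0, hi=100.0):
    out = []
    while len(out) < n:
        pts = rng.uniform(lo, hi, size=(3, 2))
        tri = ElbowTriple(A=tuple(pts[0]), B=tuple(pts[1]), C=tuple(pts[2]))
        u = pts[0] - pts[1]
        v = pts[2] - pts[1]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1.0 or nv < 1.0 or abs(np.dot(u, v) / (nu * nv)) > 0.999:
            continue  # near-degenerate: angle ill-conditioned for any method
        out.append(tri)
    return out


class TestElbowAngle:
    def test_collinear_is_180(self):
        assert elbow_angle(ElbowTriple(A=(0, 0), B=(0, 1), C=(0, 2))) == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        assert elbow_angle(ElbowTriple(A=(0, 1), B=(0, 0), C=(1, 0))) == pytest.approx(90.0)

    def test_3_4_5_triangle_is_90(self):
        assert elbow_angle(ElbowTriple(A=(0, 0), B=(4, 0), C=(4, 3))) == pytest.approx(90.0)

    def test_agrees_with_dot_product_oracle(self):
        rng = np.random.default_rng(0)
        for tri in random_triples(500, rng):
            assert elbow_angle(tri) == pytest.approx(dot_product_angle(tri), abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError):
            ElbowTriple(A=(1, 1), B=(1, 1), C=(2, 2))

    @given(
        seed=st.integers(0, 10_000),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        theta=st.floats(0, 2 * math.pi),
        scale=st.floats(0.1, 10.0),
    )
    def test_invariance_and_symmetry(self, seed, dx, dy, theta, scale):
        rng = np.random.default_rng(seed)
        tri = random_triples(1, rng)[0]
        base = elbow_angle(tri)
        c, s = math.cos(theta), math.sin(theta)

        def tf(p):
            x, y = p
            return (scale * (c * x - s * y) + dx, scale * (s * x + c * y) + dy)

        moved = ElbowTriple(A=tf(tri.A), B=tf(tri.B), C=tf(tri.C))
        assert elbow_angle(moved) == pytest.approx(base, abs=1e-6)
        swapped = ElbowTriple(A=tri.C, B=tri.B, C=tri.A)
        assert elbow_angle(swapped) == pytest.approx(base, abs=1e-9)


def event(depth_cm=5.5, press_time=0.55, initial=250.0):
    return PressEvent(
        start_time=10.0,
        end_time=10.0 + press_time,
        press_time=press_time,
        bottom_y=initial + depth_cm * CAL.px_per_cm,
        initial_height=initial,
    )


def straight(angle=175.0):
    from cprpose import arm_geometry

    s, e, w = arm_geometry(angle, 100.0, (320.0, 400.0))
    return ElbowTriple(A=tuple(s), B=tuple(e), C=tuple(w))


class TestClassifyPress:
    def test_shallow_press(self):
        pm = classify_press(event(depth_cm=4.2), straight(), straight(), CAL)
        assert pm.depth_band == "shallow"

    def test_fast_press(self):
        pm = classify_press(event(press_time=60.0 / 130.0), straight(), straight(), CAL)
        assert pm.freq_band == "fast"

    def test_one_bent_elbow_is_abnormal(self):
        pm = classify_press(event(), straight(170.0), straight(160.0), CAL)
        assert pm.posture == "abnormal"

    @pytest.mark.parametrize("depth", [5.0, 6.0])
    def test_depth_band_boundaries_are_compliant(self, depth):
        pm = classify_press(event(depth_cm=depth), straight(), straight(), CAL)
        assert pm.depth_band == "ok"

    @pytest.mark.parametrize("bpm", [100.0, 120.0])
    def test_freq_band_boundaries_are_compliant(self, bpm):
        pm = classify_press(event(press_time=60.0 / bpm), straight(), straight(), CAL)
        assert pm.freq_band == "ok"

    def test_thresholds_validation(self):
        with pytest.raises(ValidationError):
            FeedbackThresholds(depth_min_cm=6.0, depth_max_cm=5.0)
        with pytest.raises(ValidationError):
            FeedbackThresholds(posture_min_deg=200.0)
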