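"""Phase features, softmax classification, training, cycle bookkeeping."""

import numpy as np
import pytest

from cprpose import (
    AmplitudeThresholdModel,
    CycleConfig,
    Keypoint,
    KeypointFrame,
    SessionState,
    SyntheticSpec,
    ValidationError,
    classify_phase,
    extract_labeled_windows,
    generate_session,
    load_phase_model,
    phase_features,
    save_phase_model,
    train_phase_classifier,
    update_cycle,
)
from cprpose.keypoints import REQUIRED_KEYPOINTS
from cprpose.phases import CPR, UNCPR, MLPPhaseModel, PhaseLabel


def static_window(n=10, scale=1.0):
    frames = []
    for i in range(n):
        kps = {
            name: Keypoint(
                name=name,
                x=scale * (100.0 if "left" in name else 200.0),
                y=scale * (400.0 if "wrist" in name else 300.0),
                confidence=0.9,
            )
            for name in REQUIRED_KEYPOINTS
        }
        frames.append(KeypointFrame(t=0.1 * i, keypoints=kps))
    return frames


class TestPhaseFeatures:
    def test_static_window_has_zero_variance(self):
        feats = phase_features(static_window())
        assert feats[0] == 0.0 and feats[2] == 0.0

    def test_scale_invariance(self):
        f1 = phase_features(static_window(scale=1.0))
        f2 = phase_features(static_window(scale=3.0))
        assert np.allclose(f1, f2)

    def test_cpr_window_amplitude_exceeds_pause_window(self):
        spec = SyntheticSpec(rate_bpm=110.0, n_phases=1, presses_per_phase=10, seed=4)
        trace, truth = generate_session(spec)
        cpr_start = [a for a, b, l in truth.phase_intervals if l == "CPR"][0]
        cpr = [fr for fr in trace.frames if cpr_start + 1 <= fr.t <= cpr_start + 2]
        pause = [fr for fr in trace.frames if fr.t < spec.lead_in_s]
        assert phase_features(cpr)[2] > phase_features(pause)[2]

    def test_unusable_window_rejected(self):
        frames = static_window(3)
        bad = [
            KeypointFrame(
                t=fr.t,
                keypoints={n: Keypoint(name=n, x=k.x, y=k.y, confidence=0.0) for n, k in fr.keypoints.items()},
            )
            for fr in frames
        ]
        with pytest.raises(ValidationError):
            phase_features(bad)


class _FixedLogits:
    def __init__(self, z):
        self.z = np.asarray(z, dtype=float)

    def logits(self, features):
        return self.z


class TestSoftmaxClassification:
    def test_equal_logits_give_half_half(self):
        label = classify_phase(np.zeros(3), _FixedLogits([3.0, 3.0]))
        assert label.probabilities[CPR] == pytest.approx(0.5)
        assert label.probabilities[UNCPR] == pytest.approx(0.5)

    def test_dominant_logit_saturates(self):
        label = classify_phase(np.zeros(3), _FixedLogits([50.0, -50.0]))
        assert label.label == CPR
        assert label.probabilities[CPR] == pytest.approx(1.0, abs=1e-9)

    def test_probabilities_sum_to_one_and_positive(self):
        for z in ([-3, 7], [0.1, -0.1], [12, 12]):
            label = classify_phase(np.zeros(3), _FixedLogits(z))
            assert sum(label.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(p > 0 for p in label.probabilities.values())

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValidationError):
            PhaseLabel(label=CPR, probabilities={CPR: 0.2, UNCPR: 0.8})

    def test_heuristic_matches_ground_truth_at_zero_noise(self):
        spec = SyntheticSpec(n_phases=2, presses_per_phase=30, noise_px_sd=0.0, seed=6)
        trace, truth = generate_session(spec)
        feats, labels = extract_labeled_windows(trace, truth)
        pred = [classify_phase(f, AmplitudeThresholdModel()).label for f in feats]
        agreement = np.mean([p == l for p, l in zip(pred, labels)])
        assert agreement >= 0.95


def _window_set(seeds, noise=1.0):
    feats, labels = [], []
    for s in seeds:
        spec = SyntheticSpec(n_phases=2, presses_per_phase=10, noise_px_sd=noise, seed=s)
        trace, truth = generate_session(spec)
        f, l = extract_labeled_windows(trace, truth)
        feats += f
        labels += l
    return feats, labels


class TestTraining:
    def test_separable_training_data_fits_exactly(self):
        feats, labels = _window_set([1])
        model = train_phase_classifier(feats, labels, seed=0)
        pred = [classify_phase(f, model).label for f in feats]
        assert np.mean([p == l for p, l in zip(pred, labels)]) == 1.0

    def test_same_seed_identical_predictions(self):
        feats, labels = _window_set([2])
        m1 = train_phase_classifier(feats, labels, seed=3)
        m2 = train_phase_classifier(feats, labels, seed=3)
        p1 = [classify_phase(f, m1).probabilities[CPR] for f in feats]
        p2 = [classify_phase(f, m2).probabilities[CPR] for f in feats]
        assert p1 == p2

    def test_holdout_accuracy(self):
        train_f, train_l = _window_set([10, 11])
        test_f, test_l = _window_set([12])
        model = train_phase_classifier(train_f, train_l, seed=0)
        pred = [classify_phase(f, model).label for f in test_f]
        assert np.mean([p == l for p, l in zip(pred, test_l)]) >= 0.9

    def test_single_class_data_rejected(self):
        feats = [np.zeros(3)] * 4
        with pytest.raises(ValidationError):
            train_phase_classifier(feats, [CPR] * 4, seed=0)

    def test_model_round_trips_through_json(self, tmp_path):
        feats, labels = _window_set([5])
        model = train_phase_classifier(feats, labels, seed=1)
        save_phase_model(model, tmp_path / "m.json")
        back = load_phase_model(tmp_path / "m.json")
        assert isinstance(back, MLPPhaseModel)
        for f in feats[:20]:
            assert classify_phase(f, back).probabilities == classify_phase(f, model).probabilities
        save_phase_model(AmplitudeThresholdModel(0.2, 10.0), tmp_path / "a.json")
        assert load_phase_model(tmp_path / "a.json") == AmplitudeThresholdModel(0.2, 10.0)


def lab(name):
    return PhaseLabel(label=name, probabilities={CPR: 0.9, UNCPR: 0.1} if name == CPR else {CPR: 0.1, UNCPR: 0.9})


class TestUpdateCycle:
    def test_uncpr_to_cpr_increments(self):
        st = SessionState(previous_phase=UNCPR)
        st = update_cycle(st, lab(CPR), press_emitted=False)
        assert st.cycle_count == 1

    def test_cpr_to_cpr_unchanged(self):
        st = SessionState(cycle_count=2, previous_phase=CPR)
        assert update_cycle(st, lab(CPR), press_emitted=False).cycle_count == 2

    def test_press_counting_and_reset_on_new_cycle(self):
        st = SessionState(cycle_count=1, presses_in_cycle=29, previous_phase=UNCPR)
        st = update_cycle(st, lab(CPR), press_emitted=True)
        assert st.cycle_count == 2
        assert st.presses_in_cycle == 1

    def test_termination_requires_max_cycles_complete(self):
        cfg = CycleConfig(presses_per_cycle=3, max_cycles=2)
        st = SessionState(cycle_count=2, presses_in_cycle=2, previous_phase=CPR)
        st = update_cycle(st, lab(UNCPR), press_emitted=False, cfg=cfg)
        assert st.terminated

    def test_cycle_count_never_decreases(self):
        st = SessionState()
        seq = [CPR, CPR, UNCPR, CPR, UNCPR, UNCPR, CPR]
        prev_count = 0
        for name in seq:
            st = update_cycle(st, lab(name), press_emitted=False)
            assert st.cycle_count >= prev_count
            prev_count = st.cycle_count
        assert st.cycle_count == 3
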