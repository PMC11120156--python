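# Methods

## Input model and conventions

The pipeline consumes time-stamped frames of six upper-limb keypoints
(left/right shoulder, elbow, wrist) in image-pixel coordinates with
per-keypoint confidences.  The y axis points down: a larger pixel y is
physically lower.  Timestamps are required per frame rather than
assuming a constant frame rate, because phone capture rates fluctuate.
The pose model producing the keypoints is outside the package; the
"arm" endpoints of the upper-limb chain are mapped to the shoulder
keypoints of the standard 17-point pose skeleton — the usual choice
when only six upper-limb points are tracked, and our decision since no
other index assignment is forced by the input format.

A frame passes the presence gate when all six keypoints have
confidence ≥ 0.3 (the common pose-estimation convention;
configurable).  Gated-out frames reset the press detector: a resting
height remembered across an occlusion is unsafe.

## Press detection

Compressions are detected by a three-state machine on the lowest-wrist
series `wristY = max(left_wristY, right_wristY)`:

* **state 0 (rest)** tracks the resting height `initialHeight` with a
  light exponential follow (α = 0.2) so slow baseline drift does not
  accumulate; any descent beyond the hysteresis starts a press
  candidate.
* **state 1 (first descent)** tracks the running bottom.  At the
  up-turn, an excursion `bottom − initialHeight > 15.5 px` confirms a
  press and records its bottom time as `startTime`; smaller excursions
  are jitter and return the machine to rest.
* **state 2 (cycling)** arms the next press once the wrist recoils to
  within 5 px of `initialHeight` (near-full chest recoil is therefore a
  precondition of being counted), then waits for the wrist to descend
  back to within 5 px of the previous bottom.  The next up-turn fixes
  `endTime`, emits one press event with
  `press_time = endTime − startTime`, and re-arms with
  `startTime ← endTime`.  A session of n presses per phase therefore
  yields n − 1 events per phase: the first bottom of a phase anchors
  the timing but cannot itself be timed.

"Up/down turn" means a sign change of the frame-to-frame difference
exceeding a 1 px hysteresis (configurable), which suppresses flip-flops
from sub-pixel jitter.  If the wrist rests near `initialHeight` for
longer than `rest_timeout_s` (default 2 s — several times the longest
compliant press period of 0.6 s, well under any realistic inter-cycle
pause) the machine resets fully, so no press time ever spans a pause.

**Sub-frame bottom refinement.**  At 30 fps the frame grid quantises
bottom-to-bottom intervals to ±33 ms, i.e. roughly ±6 /min at
110 /min — coarser than the rate precision worth reporting.  Each
detected bottom is therefore refined by a parabolic vertex fit through
the bottom sample and its two neighbours (the compression waveform is
locally quadratic at its extremum).  The fit falls back to the raw
sample whenever it is degenerate or the vertex leaves the bracketing
samples.  Refinement is on by default (`refine_bottom`); with it, a
noise-free 110 /min session is recovered to better than 0.1 /min and
0.01 cm.

The stock pixel thresholds (15.5 / 5 px) are resolution dependent;
`DetectorConfig.scaled_for(px_per_cm)` rescales them relative to the
10 px/cm reference calibration so their physical meaning (~1.55 cm
press-start excursion, ~0.5 cm return band) is preserved across
capture resolutions.  An optional moving-average smoother (window 3,
off by default) is available for noisy backends.

## Per-press metrics

* depth: `(bottom_y − initialHeight) / rate` with `rate` in px/cm;
* frequency: `60 / press_time` in /min;
* elbow angle: law of cosines on the shoulder–elbow–wrist triple, with
  the cosine ratio clamped to [−1, 1] before the arccos so collinear
  (straight-arm) triples return exactly 180°.

Compliance bands are closed intervals — depth ∈ [5, 6] cm and rate
∈ [100, 120] /min are compliant at their boundaries; posture is normal
only when *both* elbow angles strictly exceed 165°.  Elbow triples are
sampled at the press-bottom frame, the moment of maximal load.

The live feedback banding for frequency averages the last 3 press
times before applying the band (configurable via
`freq_window_presses`): a single period is quantised by the capture
frame rate, and the short average keeps spoken feedback from flapping
at band edges.  Per-press metrics always carry the instantaneous
`60 / press_time`.

## Phase classification and cycle tracking

Sliding windows (1.0 s, 50 % overlap — at least one full compression
at any compliant rate) are classified CPR vs UNCPR from three
scale-free features of the wrist-y series: variance, mean absolute
frame-to-frame delta, and peak-to-trough excursion, each normalised by
the shoulder-to-shoulder pixel distance so camera zoom cancels.

Two softmax models are provided.  The default is a deterministic
amplitude threshold (window excursion > 0.1 shoulder widths ⇒ CPR,
passed through a logistic of configurable sharpness), which needs no
training and is exactly reproducible.  Alternatively a one-hidden-layer
feed-forward classifier (8 ReLU units, lbfgs, standardised features)
can be trained on labelled windows; inference replays the stored
weights in a plain forward pass, so probabilities are always an
explicit softmax over two logits.  Windows for training are labelled
by the ground-truth phase at the window centre, which makes windows
straddling a phase boundary inherently ambiguous — observed agreement
at zero noise is ≈ 96 %, with all disagreements at boundaries.

Cycle bookkeeping increments on every UNCPR→CPR transition (the first
CPR onset of a session opens cycle 1), counts presses within the
cycle, and terminates once `max_cycles` (default 5) cycles are
complete — the configured press count was reached or the phase fell
back to UNCPR.  Because the detector times n − 1 of n presses per
phase, per-cycle press counts of 29/30 are expected and logged rather
than treated as protocol violations.

## Synthetic sessions

The generator emulates a pose backend watching CPR training.  During a
phase the whole arm chain translates vertically with a raised-cosine
waveform `y(t) = y0 + A(1 − cos 2πft)/2`, `A = depth × px_per_cm`,
`f = rate/60`, so each phase starts at rest height (what state 0 of
the detector needs) and ground-truth bottoms fall at `(k + ½)/f`.
Defaults are a guideline-compliant session: 5.5 cm, 110 /min, 175°
elbows, 5 phases × 30 presses, 5 s pauses, 30 fps, 10 px/cm, plus a
1 s lead-in of rest.  Arms are splayed 10° from vertical with 100 px
segments, placing the shoulders ≈ 98 px apart so the shoulder-width
normalisation is well conditioned.  Gaussian pixel noise and keypoint
dropout (confidence zeroed, coordinates untouched) are applied after
the geometry; everything is reproducible from the seed.  A
`recoil_fraction < 1` option leaves residual compression between
presses for robustness experiments.

What the generator does *not* emulate: perspective and camera motion,
correlated (non-white) pose-model error, torso deformation, rescuer
sway, multiple people.  Passing tests on synthetic sessions therefore
demonstrate the correctness of the measurement pipeline given
reasonable keypoints, not the accuracy of any particular pose model.

## Evaluation against a reference device

Per-press depths from a reference device (e.g. a sensor-instrumented
manikin) and from this system are paired by greedy nearest-bottom-time
matching within 0.3 s (about half a compliant press period); unmatched
presses are reported and excluded.  Agreement is summarised by the
MAE, the percentage of presses with |error| ≤ 0.5 cm (boundary counts
as accurate), and a two-sided paired t-test on the per-press
differences — the standard choice for paired continuous agreement; a
Wilcoxon signed-rank option is provided.  Zero-variance differences
make the t-test degenerate: a warning is issued and p = 1 reported.
Published agreement figures for any particular manikin session depend
on that session's private data; this module reproduces the procedure,
and its property suite verifies the statistics against brute-force
recomputation and a type-I-error calibration.

## Sizes used in the shipped checks

The test suite and the acceptance script run sessions of 1–2 phases of
30 presses for parameter recovery (≈ 40 s of simulated video each) and
one 8-phase session (≈ 170 s) for protocol termination — sizes chosen
because every measured quantity (per-press depth/rate recovery, cycle
counting) reaches its asymptotic behaviour within a phase or two.

## Known limitations

* Depth is vertical wrist travel; off-vertical compression vectors and
  camera tilt bias it.  Calibration (px/cm) must be supplied; no
  automatic scale estimation is attempted.
* Presses without near-full recoil (within the 5 px return band) are
  not counted, by construction of the state machine.
* One subject only; no hand-placement (sternum landmark) check.
* The first press of every phase is an anchor and yields no timed
  event, so a 30-press cycle reports 29 measured presses.
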