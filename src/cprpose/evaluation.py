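"""Agreement between a reference depth device and this system.

A sensor-instrumented training manikin (e.g. Laerdal Resusci Anne QCPR)
reports a per-press compression depth; the video pipeline reports its
own.  After pairing presses by nearest bottom time, agreement is
summarised by

* the mean absolute error (MAE) of the paired depths, in cm;
* the tolerance accuracy — the percentage of presses whose absolute
  depth error is <= 0.5 cm (the boundary counts as accurate);
* a two-sided paired test on the per-press differences (Student's
  paired t by default; Wilcoxon signed-rank as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .keypoints import ValidationError

__all__ = [
    "PairedDepthSeries",
    "mean_absolute_error",
    "tolerance_accuracy",
    "paired_depth_test",
    "align_presses",
]


@dataclass(frozen=True)
class PairedDepthSeries:
    """Index-aligned per-press depths (cm) from two measurement methods."""

    reference: np.ndarray
    estimated: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        est = np.asarray(self.estimated, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "estimated", est)
        if ref.ndim != 1 or est.ndim != 1 or len(ref) != len(est):
            raise ValidationError("paired series must be 1-D and of equal length")
        if len(ref) == 0:
            raise ValidationError("paired series must contain at least one press")
        if (ref < 0).any() or (est < 0).any():
            raise ValidationError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.reference)


def mean_absolute_error(pairs: PairedDepthSeries) -> float:
    """Mean of |reference - estimated| over all paired presses, in cm."""
    return float(np.mean(np.abs(pairs.reference - pairs.estimated)))


def tolerance_accuracy(pairs: PairedDepthSeries, tol_cm: float = 0.5) -> float:
    """Percentage of presses with absolute depth error <= ``tol_cm``."""
    if tol_cm < 0:
        raise ValidationError("tolerance must be >= 0 cm")
    err = np.abs(pairs.reference - pairs.estimated)
    return float(100.0 * np.mean(err <= tol_cm))


def paired_depth_test(pairs: PairedDepthSeries, method: str = "t") -> float:
    """Two-sided p-value of the paired test on per-press differences.

    ``method`` is ``"t"`` (paired t-test) or ``"wilcoxon"``.  With fewer
    than two pairs or zero-variance differences the test is degenerate:
    a warning is issued and p = 1.0 returned.
    """
    if method not in ("t", "wilcoxon"):
        raise ValidationError(f"unknown test method {method!r} (expected 't' or 'wilcoxon')")
    diff = pairs.reference - pairs.estimated
    # t needs nonzero variance of differences; wilcoxon only fails when
    # every difference is exactly zero.
    degenerate = len(diff) < 2 or (
        np.ptp(diff) == 0 if method == "t" else not np.any(diff)
    )
    if degenerate:
        warnings.warn(
            "degenerate paired test (n < 2 or no variation in differences); reporting p = 1",
            stacklevel=2,
        )
        return 1.0
    if method == "t":
        return float(stats.ttest_rel(pairs.reference, pairs.estimated).pvalue)
    return float(stats.wilcoxon(pairs.reference, pairs.estimated).pvalue)


def align_presses(
    ref_times: np.ndarray,
    ref_depths: np.ndarray,
    est_times: np.ndarray,
    est_depths: np.ndarray,
    window_s: float = 0.3,
) -> tuple[PairedDepthSeries, list[int], list[int]]:
    """Pair presses from two devices by nearest bottom time.

    Greedy in time order: each reference press takes the closest unused
    estimated press within ``window_s``.  Returns the paired series plus
    the indices of unmatched reference and estimated presses (excluded
    from paired metrics, reported for transparency).
    """
    ref_times = np.asarray(ref_times, dtype=float)
    est_times = np.asarray(est_times, dtype=float)
    if len(ref_times) != len(ref_depths) or len(est_times) != len(est_depths):
        raise ValidationError("times and depths must have equal lengths")
    used = np.zeros(len(est_times), dtype=bool)
    ref_idx: list[int] = []
    est_idx: list[int] = []
    for i in np.argsort(ref_times):
        dt = np.abs(est_times - ref_times[i])
        dt[used] = np.inf
        j = int(np.argmin(dt)) if len(dt) else -1
        if j >= 0 and dt[j] <= window_s:
            used[j] = True
            ref_idx.append(int(i))
            est_idx.append(j)
    unmatched_ref = [i for i in range(len(ref_times)) if i not in set(ref_idx)]
    unmatched_est = [j for j in range(len(est_times)) if not used[j]]
    if not ref_idx:
        raise ValidationError(f"no presses could be paired within {window_s} s")
    order = np.argsort([ref_times[i] for i in ref_idx])
    ref_sel = np.asarray([ref_depths[ref_idx[k]] for k in order], dtype=float)
    est_sel = np.asarray([est_depths[est_idx[k]] for k in order], dtype=float)
    return PairedDepthSeries(reference=ref_sel, estimated=est_sel), unmatched_ref, unmatched_est
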