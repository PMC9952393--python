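"""Finger-tapping kinematics and phase analysis.

The finger-tapping test (a standard item of neurological exams for
Parkinson's disease) asks the subject to tap the index fingertip against
the thumb tip repeatedly, opening as far as possible.  Given estimated
3-D trajectories of the two fingertips, the quantities of clinical
interest are the inter-tip distance and its first two finite
differences — velocity and acceleration per frame, the sampling interval
being ignored — plus where in the open/close cycle each frame falls.

Phases are labeled per tap as percentages: 0 marks the start of the
opening phase, 50 the apex (maximal opening, shared between phases) and
100 the end of the closing phase; frames are mapped linearly within each
phase.  Rest periods between trials are detected as flat runs of the
distance signal and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "TapSequence",
    "TapKinematics",
    "TapErrorReport",
    "PhaseLabels",
    "tap_kinematics",
    "tap_errors",
    "label_phases",
    "phase_error_bands",
]


@dataclass
class TapSequence:
    """Thumb-tip and index-tip trajectories, (T, 2, 3) in mm."""

    frames: np.ndarray
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (2, 3):
            raise ValueError("frames must be (T, 2, 3)")
        if self.frame_index is None:
            self.frame_index = np.arange(self.frames.shape[0])

    def __len__(self) -> int:
        return self.frames.shape[0]

    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.frames[:, 0] - self.frames[:, 1], axis=-1)


@dataclass
class TapKinematics:
    """Distance (mm) and its frame-wise first/second differences."""

    distance: np.ndarray       # (T,)
    velocity: np.ndarray       # (T-1,) mm/frame
    acceleration: np.ndarray   # (T-2,) mm/frame^2
    complete: bool = True      # False when T was too short for a derivative


@dataclass
class TapErrorReport:
    """Mean +/- sd agreement between predicted and true tapping kinematics."""

    pos_err: float             # all-keypoint mean error over the two tips, mm
    dis_err: tuple[float, float]
    vel_err: tuple[float, float]
    acc_err: tuple[float, float]


@dataclass
class PhaseLabels:
    percent: np.ndarray    # per-frame phase in [0, 100]; NaN outside taps
    tap_id: np.ndarray     # per-frame tap index, -1 outside taps
    rest_mask: np.ndarray  # True on detected rest frames

    @property
    def n_taps(self) -> int:
        ids = self.tap_id[self.tap_id >= 0]
        return int(ids.max() + 1) if ids.size else 0


def tap_kinematics(seq: TapSequence) -> TapKinematics:
    """Distance, velocity and acceleration series of the fingertip gap."""
    d = seq.distances()
    t = d.shape[0]
    vel = np.diff(d) if t >= 2 else np.empty(0)
    acc = np.diff(d, n=2) if t >= 3 else np.empty(0)
    return TapKinematics(distance=d, velocity=vel, acceleration=acc, complete=t >= 3)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = np.abs(x)
    return (float(x.mean()), float(x.std())) if x.size else (float("nan"), float("nan"))


def tap_errors(pred: TapSequence, truth: TapSequence) -> TapErrorReport:
    """Positional and kinematic errors of a predicted tapping sequence.

    Pos is the mean Euclidean error over the two fingertips; Dis/Vel/Acc
    compare the scalar distance series and its finite differences as
    mean +/- sd of the absolute deviation.
    """
    if len(pred) != len(truth):
        raise ValueError("sequences must have equal length")
    pos = float(np.linalg.norm(pred.frames - truth.frames, axis=-1).mean())
    kp, kt = tap_kinematics(pred), tap_kinematics(truth)
    return TapErrorReport(
        pos_err=pos,
        dis_err=_mean_sd(kp.distance - kt.distance),
        vel_err=_mean_sd(kp.velocity - kt.velocity),
        acc_err=_mean_sd(kp.acceleration - kt.acceleration),
    )


def _smooth(x: np.ndarray, window: int = 3) -> np.ndarray:
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(xp, kernel, mode="valid")


def _rest_mask(d: np.ndarray, rest_threshold: float, window: int) -> np.ndarray:
    """Frames whose centered window of the signal spans less than the threshold."""
    t = d.shape[0]
    mask = np.zeros(t, dtype=bool)
    half = window // 2
    for i in range(t):
        lo, hi = max(0, i - half), min(t, i + half + 1)
        seg = d[lo:hi]
        if seg.max() - seg.min() < rest_threshold:
            mask[i] = True
    return mask


def label_phases(
    distance: np.ndarray,
    rest_threshold: float = 3.0,
    smooth_window: int = 3,
    rest_window: int = 9,
) -> PhaseLabels:
    """Segment a distance signal into taps and label frames 0-100 by phase.

    The signal is lightly smoothed (moving average) before extremum
    detection.  Rest runs — windows in which the signal spans less than
    ``rest_threshold`` mm — are excluded.  Within each active run, local
    minima bound the taps and the maximum of each segment is its apex;
    frames map linearly 0 -> 50 across the opening phase and 50 -> 100
    across the closing phase, the apex frame belonging to both.
    """
    d = np.asarray(distance, dtype=np.float64).reshape(-1)
    t = d.shape[0]
    percent = np.full(t, np.nan)
    tap_id = np.full(t, -1, dtype=np.int64)
    if t < 3:
        return PhaseLabels(percent=percent, tap_id=tap_id, rest_mask=np.ones(t, dtype=bool))
    sm = _smooth(d, smooth_window)
    rest = _rest_mask(sm, rest_threshold, rest_window)

    next_id = 0
    # Active runs of consecutive non-rest frames.
    active = np.flatnonzero(~rest)
    if active.size:
        splits = np.flatnonzero(np.diff(active) > 1) + 1
        runs = np.split(active, splits)
    else:
        runs = []
    for run in runs:
        lo, hi = int(run[0]), int(run[-1])
        if hi - lo < 2:
            continue
        seg = sm[lo : hi + 1]
        minima, _ = find_peaks(-seg)
        bounds = [0, *minima.tolist(), len(seg) - 1]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < 2:
                continue
            apex = b0 + int(np.argmax(seg[b0 : b1 + 1]))
            if apex in (b0, b1):
                continue
            if not (seg[apex] > seg[b0] and seg[apex] > seg[b1]):
                continue
            idx = np.arange(b0, b1 + 1)
            ph = np.where(
                idx <= apex,
                50.0 * (idx - b0) / (apex - b0),
                50.0 + 50.0 * (idx - apex) / (b1 - apex),
            )
            g = idx + lo
            percent[g] = ph
            tap_id[g] = next_id
            next_id += 1
    return PhaseLabels(percent=percent, tap_id=tap_id, rest_mask=rest)


def phase_error_bands(
    errors: np.ndarray,
    labels: PhaseLabels,
    bins: int | np.ndarray = 10,
) -> dict[str, np.ndarray]:
    """Mean +/- sd of per-frame errors grouped by phase-percentage bin.

    ``bins`` is a count of equal-width bins over [0, 100] or an explicit
    edge array.  Empty bins report NaN means (missing, not zero).
    """
    errors = np.asarray(errors, dtype=np.float64).reshape(-1)
    if errors.shape[0] != labels.percent.shape[0]:
        raise ValueError("errors must align with the labeled frames")
    edges = np.linspace(0.0, 100.0, bins + 1) if np.isscalar(bins) else np.asarray(bins, dtype=np.float64)
    labeled = ~np.isnan(labels.percent)
    pct = labels.percent[labeled]
    err = errors[labeled]
    which = np.clip(np.digitize(pct, edges) - 1, 0, len(edges) - 2)
    n = len(edges) - 1
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    count = np.zeros(n, dtype=np.int64)
    for b in range(n):
        sel = which == b
        count[b] = sel.sum()
        if count[b]:
            mean[b] = err[sel].mean()
            sd[b] = err[sel].std()
    return {"edges": edges, "mean": mean, "sd": sd, "count": count}
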