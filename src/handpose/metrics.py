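"""Keypoint accuracy metrics: mean Euclidean error and success-rate curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorReport", "SuccessCurve", "keypoint_errors", "success_rate"]


@dataclass
class ErrorReport:
    """Mean Euclidean keypoint error, per keypoint and overall, in mm."""

    per_keypoint: np.ndarray   # (J,)
    overall: float
    n_frames: int


@dataclass
class SuccessCurve:
    thresholds: np.ndarray
    fraction: np.ndarray
    mode: str


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    if pred.ndim != 3 or pred.shape[-1] != 3:
        raise ValueError("expected (frames, J, 3) keypoint arrays")
    return pred, truth


def keypoint_errors(pred: np.ndarray, truth: np.ndarray) -> ErrorReport:
    """Per-keypoint and all-keypoint mean Euclidean error over frames."""
    pred, truth = _check_pair(pred, truth)
    dist = np.linalg.norm(pred - truth, axis=-1)        # (frames, J)
    per_kp = dist.mean(axis=0)
    return ErrorReport(per_keypoint=per_kp, overall=float(dist.mean()), n_frames=pred.shape[0])


def success_rate(
    pred: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray,
    mode: str = "worst-keypoint",
) -> SuccessCurve:
    """Fraction of frames (or frame/keypoint pairs) with error below a threshold.

    ``worst-keypoint`` counts a frame as a success only when its maximum
    keypoint error is below the threshold; ``per-keypoint`` counts each
    (frame, keypoint) pair independently.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64).reshape(-1)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    pred, truth = _check_pair(pred, truth)
    dist = np.linalg.norm(pred - truth, axis=-1)
    if mode == "worst-keypoint":
        errs = dist.max(axis=1)
    elif mode == "per-keypoint":
        errs = dist.reshape(-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frac = (errs[None, :] < thresholds[:, None]).mean(axis=1)
    return SuccessCurve(thresholds=thresholds, fraction=frac, mode=mode)
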