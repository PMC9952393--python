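"""Pinhole camera geometry for millimeter depth rasters.

A depth image is a 2.5D observation: every pixel with a non-zero depth
value corresponds to one point on the observed surface.  The conversions
here move between image coordinates ``(u, v, d)`` — column, row, depth in
mm — and camera-centered world coordinates in mm.  The pixel convention is
0-based, ``(u, v) = (column, row)``, with the continuous pixel center at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "DepthFrame",
    "pixel_to_world",
    "world_to_pixel",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        vals = (self.fx, self.fy, self.cx, self.cy)
        if not all(np.isfinite(vals)):
            raise ValueError("intrinsics must be finite")
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass
class DepthFrame:
    """A calibrated depth raster: ``depth[v, u]`` in mm, 0 marking invalid pixels."""

    depth: np.ndarray
    intrinsics: CameraIntrinsics

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2 or min(self.depth.shape) < 1:
            raise ValueError("depth must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth must be finite")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative (0 = invalid)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def valid_mask(self) -> np.ndarray:
        return self.depth > 0


def pixel_to_world(u, v, d, K: CameraIntrinsics) -> np.ndarray:
    """Back-project image coordinates ``(u, v)`` at depth ``d`` (mm) to world mm.

    Broadcasts over array inputs; returns an array with a trailing axis of
    length 3.  Zero depth maps to the origin.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v)) and np.all(np.isfinite(d))):
        raise ValueError("pixel coordinates and depth must be finite")
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    x = (u - K.cx) * d / K.fx
    y = (v - K.cy) * d / K.fy
    return np.stack(np.broadcast_arrays(x, y, d), axis=-1)


def world_to_pixel(p, K: CameraIntrinsics) -> np.ndarray:
    """Project world points (mm) to ``(u, v, d)``; requires z > 0 (in front of camera)."""
    p = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("world points must be finite")
    z = p[..., 2]
    if np.any(z <= 0):
        raise ValueError("point behind camera: z must be > 0 for projection")
    u = p[..., 0] * K.fx / z + K.cx
    v = p[..., 1] * K.fy / z + K.cy
    return np.stack([u, v, z], axis=-1)


def frame_to_points(frame: DepthFrame) -> np.ndarray:
    """World coordinates (mm) of every pixel of a depth frame, shape H x W x 3.

    Invalid pixels (depth 0) map to the origin; filter with ``frame.valid_mask()``.
    """
    h, w = frame.shape
    v, u = np.mgrid[0:h, 0:w]
    return pixel_to_world(u, v, frame.depth, frame.intrinsics)
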