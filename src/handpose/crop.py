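"""Hand localization, cube cropping and depth normalization.

The estimator works on a fixed-size crop centered on the hand.  A crop is
defined by a 3-D center (mm, world) and a cube edge length ``cube_mm``;
the depth raster inside the projected cube is resampled to
``out_size x out_size`` with nearest-neighbor lookup (avoids phantom
depths at silhouette edges) and depth values are mapped affinely so the
near cube face is -1 and the far face is +1.  Invalid or out-of-cube
pixels take the background value +1.

Alongside the image, each crop carries a half-resolution grid of 3-D
point positions in *normalized crop coordinates* — the world offset from
the crop center divided by ``cube_mm / 2`` — which is the coordinate
system the dense codec operates in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import DepthFrame, pixel_to_world

__all__ = [
    "CropSpec",
    "CropSample",
    "estimate_hand_center",
    "crop_and_normalize",
    "normalize_keypoints",
    "uncrop_keypoints",
]

DEFAULT_CUBE_MM = 250.0
# Tolerance on the "inside the cube" test for the half-resolution points.
_CUBE_EPS = 1e-9


@dataclass(frozen=True)
class CropSpec:
    """Crop geometry: cube center (mm, world), cube edge (mm), output resolution."""

    center: tuple[float, float, float]
    cube_mm: float = DEFAULT_CUBE_MM
    out_size: int = 128

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=np.float64)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("center must be a finite 3-vector")
        object.__setattr__(self, "center", tuple(float(x) for x in c))
        if self.cube_mm <= 0:
            raise ValueError("cube_mm must be positive")
        if self.out_size < 2 or self.out_size % 2 != 0:
            raise ValueError("out_size must be even (half-resolution grid must be integral)")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=np.float64)

    @property
    def half_extent(self) -> float:
        return self.cube_mm / 2.0


@dataclass
class CropSample:
    """A normalized hand crop plus the geometry needed to invert it.

    Attributes
    ----------
    image : (out_size, out_size) float array in [-1, 1]; +1 is background.
    spec : the CropSpec that produced the sample.
    points : (out_size/2, out_size/2, 3) point grid in normalized crop
        coordinates (world offset from center over cube_mm/2).
    valid_mask : boolean grid matching ``points``; False where the source
        depth was invalid or the point falls outside the crop cube.
    """

    image: np.ndarray
    spec: CropSpec
    points: np.ndarray
    valid_mask: np.ndarray


def estimate_hand_center(frame: DepthFrame, near: float = 200.0, far: float = 1500.0) -> np.ndarray:
    """Locate the hand as the world centroid of pixels in a depth window.

    A simple depth-gated centroid: assumes the hand is the only object in
    ``[near, far]`` mm.  Real deployments would substitute a detector; for
    rendered scenes with a single hand this is exact enough to seed the crop.
    """
    sel = (frame.depth >= near) & (frame.depth <= far) & (frame.depth > 0)
    if not np.any(sel):
        raise ValueError(f"no valid pixels with depth in [{near}, {far}] mm")
    v, u = np.nonzero(sel)
    pts = pixel_to_world(u, v, frame.depth[sel], frame.intrinsics)
    return pts.mean(axis=0)


def crop_and_normalize(frame: DepthFrame, spec: CropSpec) -> CropSample:
    """Cut the cube around ``spec.center`` out of a frame and normalize it.

    The crop window is the projection of the cube's front face at the
    center depth; depth is normalized affinely so ``center.z -/+ cube/2``
    map to -/+1 and clamped.  The half-resolution point grid is built by
    nearest-neighbor subsampling of the cropped depth.
    """
    c = spec.center_array
    if c[2] <= 0:
        raise ValueError("crop center must be in front of the camera (z > 0)")
    K = frame.intrinsics
    h, w = frame.shape
    half = spec.half_extent

    # Projected pixel half-widths of the cube at the center depth.
    uc = c[0] * K.fx / c[2] + K.cx
    vc = c[1] * K.fy / c[2] + K.cy
    du = half * K.fx / c[2]
    dv = half * K.fy / c[2]
    if uc + du < 0 or uc - du > w - 1 or vc + dv < 0 or vc - dv > h - 1:
        raise ValueError("crop window lies fully outside the frame")

    def _sample(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # Sample positions across the crop window at resolution n (pixel
        # centers of the n x n output grid), nearest-neighbor in the source.
        t = (np.arange(n) + 0.5) / n            # in (0, 1)
        us = uc - du + t * 2 * du
        vs = vc - dv + t * 2 * dv
        ui = np.rint(us).astype(np.int64)
        vi = np.rint(vs).astype(np.int64)
        inside = (ui >= 0) & (ui < w)
        insid_v = (vi >= 0) & (vi < h)
        uu, vv = np.meshgrid(np.clip(ui, 0, w - 1), np.clip(vi, 0, h - 1))
        d = frame.depth[vv, uu]
        ok = np.outer(insid_v, inside) & (d > 0)
        return uu, vv, np.where(ok, d, 0.0)

    # Full-resolution normalized image.
    _, _, d_full = _sample(spec.out_size)
    valid_full = d_full > 0
    z_norm = (d_full - c[2]) / half
    in_cube_z = np.abs(z_norm) <= 1 + _CUBE_EPS
    image = np.where(valid_full & in_cube_z, np.clip(z_norm, -1.0, 1.0), 1.0)

    # Half-resolution point grid in normalized crop coordinates.
    uu, vv, d_half = _sample(spec.out_size // 2)
    valid_half = d_half > 0
    pts_world = pixel_to_world(uu, vv, d_half, K)
    pts = (pts_world - c) / half
    in_cube = np.all(np.abs(pts) <= 1 + _CUBE_EPS, axis=-1)
    mask = valid_half & in_cube
    pts = np.where(mask[..., None], pts, 0.0)
    return CropSample(image=image, spec=spec, points=pts, valid_mask=mask)


def normalize_keypoints(keys_world: np.ndarray, spec: CropSpec) -> np.ndarray:
    """World-mm keypoints -> normalized crop coordinates of ``spec``."""
    keys_world = np.asarray(keys_world, dtype=np.float64)
    return (keys_world - spec.center_array) / spec.half_extent


def uncrop_keypoints(coords: np.ndarray, spec: CropSpec) -> np.ndarray:
    """Normalized crop coordinates -> world mm; exact inverse of normalize_keypoints."""
    coords = np.asarray(coords, dtype=np.float64)
    return spec.center_array + coords * spec.half_extent
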