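"""Synthetic articulated-hand depth data with exact keypoint ground truth.

The generator renders a toy hand — palm approximated by three thick
capsules, a two-segment thumb and a three-segment index finger — to
calibrated millimeter depth images via analytic ray-capsule
intersection.  Two modes cover the data the estimator consumes:

* pose mode: random articulations and placements with J = 6 annotated
  keypoints (two tips, two MCP joints, palm center, wrist);
* tapping mode: cyclic open/close motion of thumb and index whose
  fingertip distance follows a prescribed rectified-sinusoid profile
  (solved per frame against the forward kinematics), with J = 2.

The toy hand reproduces the *structure* real depth data has — a single
articulated surface, self-occlusion of fingertips at contact, exact 3-D
annotations — not the shape or sensor noise of a real hand and camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .camera import CameraIntrinsics, DepthFrame

__all__ = [
    "Capsule",
    "Joint",
    "HandSkeleton",
    "PoseParams",
    "SyntheticFrame",
    "TapMotionConfig",
    "make_hand_skeleton",
    "pose_skeleton",
    "render_depth",
    "generate_pose_dataset",
    "generate_tap_sequence",
    "DEFAULT_INTRINSICS",
]

DEFAULT_INTRINSICS = CameraIntrinsics(fx=200.0, fy=200.0, cx=64.0, cy=64.0)
DEFAULT_IMAGE_SIZE = 128
# Nominal hand placement range along the optical axis, mm.
DEFAULT_DEPTH_RANGE = (450.0, 650.0)


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str | None
    offset: tuple[float, float, float]      # rest offset from parent, hand frame mm
    axis: tuple[float, float, float] | None = None   # flexion axis; None = rigid
    limits: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class Capsule:
    a: str          # joint name of one endpoint
    b: str
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("capsule radius must be positive")


@dataclass
class HandSkeleton:
    joints: list[Joint]
    capsules: list[Capsule]
    keypoint_map: list[str]
    # Joint-angle sets for the fully closed / fully open tapping poses.
    tap_closed: dict[str, float] = field(default_factory=dict)
    tap_open: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise ValueError("duplicate joint names")
        order = set()
        for j in self.joints:
            if j.parent is not None and j.parent not in order:
                raise ValueError(f"joint {j.name} listed before its parent (hierarchy must be acyclic)")
            order.add(j.name)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]


@dataclass
class PoseParams:
    """Per-joint flexion angles (rad) plus a global rigid placement."""

    angles: dict[str, float] = field(default_factory=dict)
    translation: tuple[float, float, float] = (0.0, 0.0, 550.0)
    rotation: float = 0.0    # in-plane rotation about the optical axis, rad


@dataclass
class SyntheticFrame:
    frame: DepthFrame
    keys: np.ndarray          # (J, 3) world mm
    pose: PoseParams


@dataclass
class TapMotionConfig:
    """Conditions of a synthetic finger-tapping trial.

    Defaults follow the exam protocol: ten taps, opened as far as the
    configured amplitude, at 20 frames per open/close cycle.
    """

    taps: int = 10
    frames_per_tap: int = 20
    amplitude: float = 80.0
    rest_frames: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.frames_per_tap < 4 or self.frames_per_tap % 2:
            raise ValueError("frames_per_tap must be even and >= 4 (so the apex frame is sampled)")
        if self.taps < 1:
            raise ValueError("need at least one tap")


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def make_hand_skeleton() -> HandSkeleton:
    """The default toy hand, calibrated so the tapping tips can touch.

    The index finger curls about the palm-frame x axis with per-joint
    angle fractions; the thumb has a single flexion whose axis and
    closed angle are solved in closed form so that at the fully closed
    pose the two tip centers coincide (zero fingertip distance), making
    any tapping amplitude up to the open distance reachable.
    """
    index_mcp = np.array([15.0, 70.0, 0.0])
    seg_len = (35.0, 22.0, 18.0)
    fractions = (1.0, 0.8, 0.6)
    closed_curl = 1.4

    # The camera looks down +z, so flexion curls the finger toward the
    # camera (-z): rotation about -x takes +y onto -z.  Closed index tip
    # in the hand frame (chain of accumulated rotations).
    pos = index_mcp.copy()
    cum = 0.0
    for L, f in zip(seg_len, fractions):
        cum += closed_curl * f
        pos = pos + L * np.array([0.0, np.cos(cum), -np.sin(cum)])
    closed_tip = pos

    # Thumb on the camera side of the palm (negative z offsets).
    thumb_mcp = np.array([-25.0, 20.0, -10.0])
    target = closed_tip - thumb_mcp
    # Thumb rest offsets, rescaled so the chain length matches the reach
    # needed at the closed pose exactly.
    p1 = np.array([24.0, 24.0, -12.0])
    p2 = np.array([17.0, 8.0, -9.0])
    total = p1 + p2
    scale = np.linalg.norm(target) / np.linalg.norm(total)
    p1, p2, total = p1 * scale, p2 * scale, total * scale
    # Rotation taking the rest chain onto the target: axis from the cross
    # product, angle from the dot product (norms are equal by construction).
    u = total / np.linalg.norm(total)
    w = target / np.linalg.norm(target)
    cross = np.cross(u, w)
    sin_a = np.linalg.norm(cross)
    axis = cross / sin_a if sin_a > 1e-12 else np.array([1.0, 0.0, 0.0])
    closed_thumb = float(np.arctan2(sin_a, np.dot(u, w)))

    joints = [
        Joint("wrist", None, (0.0, 0.0, 0.0)),
        Joint("palm_l", "wrist", (-20.0, 70.0, 0.0)),
        Joint("palm_c", "wrist", (0.0, 45.0, 0.0)),
        Joint("palm_r", "wrist", (20.0, 70.0, 0.0)),
        Joint("index_mcp", "wrist", tuple(index_mcp), axis=(-1.0, 0.0, 0.0), limits=(-0.3, 2.0)),
        Joint("index_pip", "index_mcp", (0.0, seg_len[0], 0.0), axis=(-1.0, 0.0, 0.0), limits=(-0.3, 2.0)),
        Joint("index_dip", "index_pip", (0.0, seg_len[1], 0.0), axis=(-1.0, 0.0, 0.0), limits=(-0.3, 2.0)),
        Joint("index_tip", "index_dip", (0.0, seg_len[2], 0.0)),
        Joint("thumb_mcp", "wrist", tuple(thumb_mcp), axis=tuple(axis), limits=(-0.1, closed_thumb + 0.1)),
        Joint("thumb_ip", "thumb_mcp", tuple(p1)),
        Joint("thumb_tip", "thumb_ip", tuple(p2)),
    ]
    capsules = [
        Capsule("wrist", "palm_l", 13.0),
        Capsule("wrist", "palm_r", 13.0),
        Capsule("palm_l", "palm_r", 13.0),
        Capsule("index_mcp", "index_pip", 9.0),
        Capsule("index_pip", "index_dip", 8.0),
        Capsule("index_dip", "index_tip", 7.0),
        Capsule("thumb_mcp", "thumb_ip", 10.0),
        Capsule("thumb_ip", "thumb_tip", 8.0),
    ]
    keypoints = ["thumb_tip", "index_tip", "thumb_mcp", "index_mcp", "palm_c", "wrist"]
    closed = {
        "index_mcp": closed_curl * fractions[0],
        "index_pip": closed_curl * fractions[1],
        "index_dip": closed_curl * fractions[2],
        "thumb_mcp": closed_thumb,
    }
    open_ = {"index_mcp": 0.0, "index_pip": 0.0, "index_dip": 0.0, "thumb_mcp": 0.0}
    return HandSkeleton(joints=joints, capsules=capsules, keypoint_map=keypoints,
                        tap_closed=closed, tap_open=open_)


def pose_skeleton(skel: HandSkeleton, pose: PoseParams) -> dict[str, np.ndarray]:
    """Forward kinematics: joint positions in world mm for a pose."""
    positions: dict[str, np.ndarray] = {}
    rotations: dict[str, np.ndarray] = {}
    for j in skel.joints:
        angle = float(pose.angles.get(j.name, 0.0))
        if j.axis is None:
            if angle != 0.0:
                raise ValueError(f"joint {j.name} is rigid but got a flexion angle")
            R_local = np.eye(3)
        else:
            lo, hi = j.limits
            if not (lo <= angle <= hi):
                raise ValueError(f"angle {angle:.3f} for joint {j.name} outside limits [{lo}, {hi}]")
            R_local = _rot_axis(np.asarray(j.axis, dtype=np.float64), angle)
        if j.parent is None:
            positions[j.name] = np.zeros(3)
            rotations[j.name] = R_local
        else:
            Rp = rotations[j.parent]
            positions[j.name] = positions[j.parent] + Rp @ np.asarray(j.offset, dtype=np.float64)
            rotations[j.name] = Rp @ R_local
    # Global in-plane rotation about the optical axis, then translation.
    Rg = _rot_axis(np.array([0.0, 0.0, 1.0]), pose.rotation)
    t = np.asarray(pose.translation, dtype=np.float64)
    return {name: Rg @ p + t for name, p in positions.items()}


def _capsule_depths(dirs: np.ndarray, pa: np.ndarray, pb: np.ndarray, r: float) -> np.ndarray:
    """Smallest positive ray parameter t hitting a capsule, per ray (inf = miss).

    Rays start at the camera origin with direction ``dirs`` whose z
    component is 1, so t equals the depth of the hit point.
    """
    t_best = np.full(dirs.shape[0], np.inf)
    ba = pb - pa
    baba = float(ba @ ba)
    dd = np.einsum("pi,pi->p", dirs, dirs)
    if baba > 1e-12:
        oa = -pa
        bard = dirs @ ba
        baoa = float(oa @ ba)
        rdoa = dirs @ oa
        oaoa = float(oa @ oa)
        a = baba * dd - bard**2
        b = baba * rdoa - baoa * bard
        c = baba * oaoa - baoa**2 - r * r * baba
        h = b * b - a * c
        ok = (h >= 0) & (a > 1e-12)
        if np.any(ok):
            t = (-b[ok] - np.sqrt(h[ok])) / a[ok]
            y = baoa + t * bard[ok]
            hit = (y > 0) & (y < baba) & (t > 0)
            idx = np.flatnonzero(ok)[hit]
            t_best[idx] = np.minimum(t_best[idx], t[hit])
    for pe in (pa, pb):
        # Spherical end caps.
        bq = dirs @ pe
        cq = float(pe @ pe) - r * r
        h = bq * bq - dd * cq
        ok = h >= 0
        if np.any(ok):
            t = (bq[ok] - np.sqrt(h[ok])) / dd[ok]
            hit = t > 0
            idx = np.flatnonzero(ok)[hit]
            t_best[idx] = np.minimum(t_best[idx], t[hit])
    return t_best


def render_depth(
    positions: dict[str, np.ndarray],
    capsules: list[Capsule],
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    size: tuple[int, int] = (DEFAULT_IMAGE_SIZE, DEFAULT_IMAGE_SIZE),
) -> DepthFrame:
    """Z-buffer depth of posed capsules; background pixels are 0."""
    h, w = size
    for cap in capsules:
        for end in (cap.a, cap.b):
            if positions[end][2] <= cap.radius:
                raise ValueError(f"capsule endpoint {end} is behind or at the camera plane")
    v, u = np.mgrid[0:h, 0:w]
    dirs = np.stack(
        [(u.ravel() - K.cx) / K.fx, (v.ravel() - K.cy) / K.fy, np.ones(h * w)], axis=-1
    )
    depth = np.full(h * w, np.inf)
    for cap in capsules:
        t = _capsule_depths(dirs, positions[cap.a], positions[cap.b], cap.radius)
        depth = np.minimum(depth, t)
    depth = np.where(np.isfinite(depth), depth, 0.0)
    return DepthFrame(depth=depth.reshape(h, w), intrinsics=K)


def keypoints_of(skel: HandSkeleton, positions: dict[str, np.ndarray]) -> np.ndarray:
    return np.stack([positions[name] for name in skel.keypoint_map])


def _default_pose_sampler(skel: HandSkeleton, rng: np.random.Generator) -> PoseParams:
    curl = rng.uniform(0.05, 1.35)
    fractions = {"index_mcp": 1.0, "index_pip": 0.8, "index_dip": 0.6}
    angles = {name: curl * f for name, f in fractions.items()}
    angles["thumb_mcp"] = rng.uniform(0.0, skel.tap_closed["thumb_mcp"])
    z = rng.uniform(*DEFAULT_DEPTH_RANGE)
    return PoseParams(
        angles=angles,
        translation=(rng.uniform(-30, 30), rng.uniform(-30, 30), z),
        rotation=rng.uniform(-0.5, 0.5),
    )


def generate_pose_dataset(
    skel: HandSkeleton,
    n: int,
    pose_sampler=None,
    seed: int = 0,
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    size: tuple[int, int] = (DEFAULT_IMAGE_SIZE, DEFAULT_IMAGE_SIZE),
) -> list[SyntheticFrame]:
    """Render ``n`` annotated frames with randomly sampled poses."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = pose_sampler or _default_pose_sampler
    out = []
    h, w = size
    while len(out) < n:
        pose = sampler(skel, rng)
        positions = pose_skeleton(skel, pose)
        keys = keypoints_of(skel, positions)
        # Every keypoint must project inside the image; resample otherwise.
        u = keys[:, 0] * K.fx / keys[:, 2] + K.cx
        v = keys[:, 1] * K.fy / keys[:, 2] + K.cy
        if np.any(u < 0) or np.any(u > w - 1) or np.any(v < 0) or np.any(v > h - 1):
            continue
        frame = render_depth(positions, skel.capsules, K, size)
        out.append(SyntheticFrame(frame=frame, keys=keys, pose=pose))
    return out


def _tap_pose(skel: HandSkeleton, s: float, base: PoseParams) -> PoseParams:
    """Pose at opening fraction s: 0 = fully closed (tips touch), 1 = fully open."""
    angles = {
        name: (1.0 - s) * skel.tap_closed[name] + s * skel.tap_open[name]
        for name in skel.tap_closed
    }
    return PoseParams(angles=angles, translation=base.translation, rotation=base.rotation)


def _tip_distance(skel: HandSkeleton, s: float, base: PoseParams) -> float:
    positions = pose_skeleton(skel, _tap_pose(skel, s, base))
    return float(np.linalg.norm(positions["thumb_tip"] - positions["index_tip"]))


def generate_tap_sequence(
    skel: HandSkeleton,
    cfg: TapMotionConfig,
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    size: tuple[int, int] = (DEFAULT_IMAGE_SIZE, DEFAULT_IMAGE_SIZE),
    base: PoseParams | None = None,
    render: bool = True,
):
    """Synthesize a finger-tapping trial.

    The fingertip distance follows ``amplitude * sin(pi * phase)`` within
    each tap (solved per frame against the forward kinematics, so the
    peak equals the amplitude exactly when the noise is off), with
    ``rest_frames`` closed-pose frames inserted between taps.  Pose noise
    perturbs the opening fraction so the tip distance acquires an
    additive jitter of roughly ``noise_sd`` mm.

    Returns ``(frames, truth)``: the rendered depth frames (or posed
    joint dictionaries when ``render=False``) and a TapSequence holding
    the exact fingertip trajectories of the generated poses.
    """
    from .tapping import TapSequence

    base = base or PoseParams(translation=(0.0, -40.0, 550.0))
    rng = np.random.default_rng(cfg.seed)

    # Monotone opening profile d(s); verified on a grid, inverted by brentq.
    grid = np.linspace(0.0, 1.0, 257)
    dg = np.array([_tip_distance(skel, s, base) for s in grid])
    if np.any(np.diff(dg) <= 0):
        raise ValueError("tip distance is not monotone in the opening fraction")
    if cfg.amplitude > dg[-1]:
        raise ValueError(f"amplitude {cfg.amplitude} mm exceeds the reachable opening {dg[-1]:.1f} mm")

    def solve_s(target: float) -> float:
        target = float(np.clip(target, dg[0], dg[-1]))
        if target <= dg[0]:
            return 0.0
        if target >= dg[-1]:
            return 1.0
        k = int(np.searchsorted(dg, target))
        return brentq(lambda s: _tip_distance(skel, s, base) - target,
                      grid[k - 1], grid[k], xtol=1e-12)

    fpt = cfg.frames_per_tap
    targets: list[float] = []
    for tap in range(cfg.taps):
        targets.extend(cfg.amplitude * np.sin(np.pi * np.arange(fpt) / fpt))
        if cfg.rest_frames and tap < cfg.taps - 1:
            targets.extend([0.0] * cfg.rest_frames)
    targets.append(0.0)   # end the trial closed

    slope = np.gradient(dg, grid)
    frames_out = []
    tips = np.empty((len(targets), 2, 3))
    for i, target in enumerate(targets):
        s = solve_s(target)
        if cfg.noise_sd > 0:
            local_slope = max(float(np.interp(s, grid, slope)), 1e-6)
            s = float(np.clip(s + rng.normal(0.0, cfg.noise_sd) / local_slope, 0.0, 1.0))
        positions = pose_skeleton(skel, _tap_pose(skel, s, base))
        tips[i, 0] = positions["thumb_tip"]
        tips[i, 1] = positions["index_tip"]
        if render:
            frames_out.append(render_depth(positions, skel.capsules, K, size))
        else:
            frames_out.append(positions)
    return frames_out, TapSequence(frames=tips)
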