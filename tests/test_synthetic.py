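"""The articulated toy hand: kinematics, rendering, dataset generators."""

import numpy as np
import pytest

from handpose.camera import world_to_pixel
from handpose.synthetic import (
    Capsule,
    PoseParams,
    TapMotionConfig,
    DEFAULT_INTRINSICS,
    generate_pose_dataset,
    generate_tap_sequence,
    keypoints_of,
    make_hand_skeleton,
    pose_skeleton,
    render_depth,
)
from handpose.tapping import label_phases


def _bone_lengths(skel, positions):
    out = {}
    for j in skel.joints:
        if j.parent is not None:
            out[j.name] = np.linalg.norm(positions[j.name] - positions[j.parent])
    return out


class TestForwardKinematics:
    def test_zero_pose_is_rigid_transform(self, skeleton):
        rest = pose_skeleton(skeleton, PoseParams(translation=(0, 0, 500)))
        moved = pose_skeleton(skeleton, PoseParams(translation=(10, -5, 520)))
        for name in skeleton.joint_names:
            np.testing.assert_allclose(
                moved[name] - rest[name], [10, -5, 20], atol=1e-9
            )

    def test_quarter_flexion_of_two_link_chain(self, skeleton):
        # 90 deg at the index MCP rotates everything distal a quarter turn
        # about the MCP in the flexion plane: (y, z) -> (z, -y) for the
        # -x flexion axis, curling the finger toward the camera
        base = PoseParams(translation=(0, 0, 500))
        rest = pose_skeleton(skeleton, base)
        bent = pose_skeleton(
            skeleton,
            PoseParams(angles={"index_mcp": np.pi / 2}, translation=(0, 0, 500)),
        )
        mcp = rest["index_mcp"]
        rel_rest = rest["index_tip"] - mcp
        rel_bent = bent["index_tip"] - mcp
        expect = np.array([rel_rest[0], rel_rest[2], -rel_rest[1]])
        np.testing.assert_allclose(rel_bent, expect, atol=1e-9)

    def test_bone_lengths_pose_invariant(self, skeleton):
        rng = np.random.default_rng(0)
        rest = _bone_lengths(skeleton, pose_skeleton(skeleton, PoseParams(translation=(0, 0, 500))))
        for _ in range(5):
            pose = PoseParams(
                angles={
                    "index_mcp": rng.uniform(0, 1.3),
                    "index_pip": rng.uniform(0, 1.0),
                    "index_dip": rng.uniform(0, 0.8),
                    "thumb_mcp": rng.uniform(0, 0.3),
                },
                translation=(0, 0, 500),
                rotation=rng.uniform(-1, 1),
            )
            lengths = _bone_lengths(skeleton, pose_skeleton(skeleton, pose))
            for name, l0 in rest.items():
                assert lengths[name] == pytest.approx(l0, abs=1e-9)

    def test_out_of_limit_pose_rejected(self, skeleton):
        with pytest.raises(ValueError, match="limits"):
            pose_skeleton(skeleton, PoseParams(angles={"index_mcp": 3.0}, translation=(0, 0, 500)))


class TestRenderDepth:
    def test_sphere_depth_at_principal_pixel(self):
        # a degenerate capsule is a sphere: depth at the principal pixel
        # is the center depth minus the radius
        positions = {"a": np.array([0.0, 0.0, 500.0]), "b": np.array([0.0, 0.0, 500.0])}
        frame = render_depth(positions, [Capsule("a", "b", 30.0)], DEFAULT_INTRINSICS)
        K = DEFAULT_INTRINSICS
        assert frame.depth[int(K.cy), int(K.cx)] == pytest.approx(470.0, abs=1e-6)

    def test_empty_scene_is_all_zero(self):
        frame = render_depth({}, [], DEFAULT_INTRINSICS)
        assert np.all(frame.depth == 0.0)

    def test_silhouette_area_matches_analytic_capsule(self):
        # an isolated capsule fronto-parallel at depth z projects to a
        # stadium of length L*f/z and width 2r*f/z
        z, r, L = 500.0, 20.0, 80.0
        positions = {"a": np.array([-L / 2, 0, z]), "b": np.array([L / 2, 0, z])}
        frame = render_depth(positions, [Capsule("a", "b", r)], DEFAULT_INTRINSICS, (128, 128))
        f = DEFAULT_INTRINSICS.fx
        analytic = (L * 2 * r + np.pi * r * r) * (f / z) ** 2
        rendered = (frame.depth > 0).sum()
        assert abs(rendered - analytic) / analytic < 0.1

    def test_geometry_behind_camera_rejected(self):
        positions = {"a": np.array([0.0, 0.0, -50.0]), "b": np.array([0.0, 0.0, 100.0])}
        with pytest.raises(ValueError, match="behind"):
            render_depth(positions, [Capsule("a", "b", 10.0)], DEFAULT_INTRINSICS)


class TestPoseDataset:
    def test_seeded_determinism(self, skeleton):
        a = generate_pose_dataset(skeleton, 3, seed=5)
        b = generate_pose_dataset(skeleton, 3, seed=5)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.frame.depth, fb.frame.depth)
            np.testing.assert_array_equal(fa.keys, fb.keys)

    def test_keypoints_project_inside_image(self, pose_frames):
        for item in pose_frames:
            uvd = world_to_pixel(item.keys, item.frame.intrinsics)
            assert np.all(uvd[:, 0] >= 0) and np.all(uvd[:, 0] <= 127)
            assert np.all(uvd[:, 1] >= 0) and np.all(uvd[:, 1] <= 127)

    def test_surface_never_behind_keypoints(self, skeleton, pose_frames):
        """The rendered surface at a keypoint's pixel sits at or in front of
        the keypoint's capsule (occluders are allowed; annotations floating
        in front of the surface are not)."""
        max_r = max(c.radius for c in skeleton.capsules)
        for item in pose_frames:
            uvd = world_to_pixel(item.keys, item.frame.intrinsics)
            for (u, v, z) in uvd:
                d = item.frame.depth[int(round(v)), int(round(u))]
                if d > 0:
                    assert d - z <= max_r + 2.0

    def test_open_pose_keypoints_on_surface(self, skeleton):
        """With the hand open and facing the camera (no self-occlusion),
        every keypoint lies within its capsule radius plus the pixel
        footprint of some rendered surface point."""
        from handpose.camera import frame_to_points
        from handpose.synthetic import render_depth, keypoints_of

        positions = pose_skeleton(skeleton, PoseParams(translation=(0, -40, 500)))
        frame = render_depth(positions, skeleton.capsules)
        pts = frame_to_points(frame)[frame.valid_mask()]
        keys = keypoints_of(skeleton, positions)
        max_r = max(c.radius for c in skeleton.capsules)
        footprint = 500.0 / frame.intrinsics.fx  # mm per pixel at hand depth
        for k in keys:
            assert np.linalg.norm(pts - k, axis=1).min() <= max_r + 2 * footprint


class TestTapSequence:
    def test_noise_free_profile(self, skeleton):
        cfg = TapMotionConfig(taps=4, frames_per_tap=16, amplitude=60.0)
        _, truth = generate_tap_sequence(skeleton, cfg, render=False)
        d = truth.distances()
        # exactly cfg.taps local maxima, each equal to the amplitude
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(d)
        assert len(peaks) == 4
        assert abs(d.max() - 60.0) < 1e-6
        assert abs(d[peaks].min() - 60.0) < 1e-6

    def test_phase_labeling_cross_module(self, skeleton):
        cfg = TapMotionConfig(taps=10, frames_per_tap=20, amplitude=80.0)
        _, truth = generate_tap_sequence(skeleton, cfg, render=False)
        assert label_phases(truth.distances()).n_taps == 10

    def test_seeded_noise_reproducible(self, skeleton):
        cfg = TapMotionConfig(taps=2, frames_per_tap=12, amplitude=50.0, noise_sd=1.0, seed=9)
        _, t1 = generate_tap_sequence(skeleton, cfg, render=False)
        _, t2 = generate_tap_sequence(skeleton, cfg, render=False)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_noise_perturbs_distance_at_requested_scale(self, skeleton):
        cfg = TapMotionConfig(taps=6, frames_per_tap=20, amplitude=60.0, noise_sd=1.0, seed=3)
        _, noisy = generate_tap_sequence(skeleton, cfg, render=False)
        clean_cfg = TapMotionConfig(taps=6, frames_per_tap=20, amplitude=60.0)
        _, clean = generate_tap_sequence(skeleton, clean_cfg, render=False)
        resid = noisy.distances() - clean.distances()
        assert 0.5 < np.std(resid) < 2.0

    def test_amplitude_beyond_reach_rejected(self, skeleton):
        with pytest.raises(ValueError, match="amplitude"):
            generate_tap_sequence(
                skeleton, TapMotionConfig(amplitude=500.0), render=False
            )

    def test_rendered_frames_contain_hand(self, skeleton):
        cfg = TapMotionConfig(taps=1, frames_per_tap=8, amplitude=60.0)
        frames, truth = generate_tap_sequence(skeleton, cfg)
        assert len(frames) == len(truth)
        for f in frames:
            assert (f.depth > 0).sum() > 100
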