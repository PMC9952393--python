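import numpy as np
import pytest

from handpose.camera import CameraIntrinsics
from handpose.synthetic import make_hand_skeleton, generate_pose_dataset
from handpose.estimator import make_crop_dataset


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=64.0, cy=64.0)


@pytest.fixture(scope="session")
def skeleton():
    return make_hand_skeleton()


@pytest.fixture(scope="session")
def pose_frames(skeleton):
    """A small rendered pose dataset shared across tests."""
    return generate_pose_dataset(skeleton, 6, seed=42)


@pytest.fixture(scope="session")
def crop_dataset(pose_frames):
    return make_crop_dataset(pose_frames, cube_mm=250.0, out_size=64)
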