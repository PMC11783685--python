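import math

import numpy as np
import pytest

from poserom import (
    Keypoint2D,
    Movement,
    PoseFrame,
    StudyGenConfig,
    generate_study,
)


def vector_angle_deg(vertex: Keypoint2D, a: Keypoint2D, b: Keypoint2D) -> float:
    """Independent angle oracle: atan2 of |cross| and dot of the two edge
    vectors.  Deliberately avoids the law of cosines."""
    ux, uy = a.x_px - vertex.x_px, a.y_px - vertex.y_px
    wx, wy = b.x_px - vertex.x_px, b.y_px - vertex.y_px
    cross = ux * wy - uy * wx
    dot = ux * wx + uy * wy
    return math.degrees(math.atan2(abs(cross), dot))


def make_frame(keypoints: dict, frame_index: int = 0, timestamp: float = 0.0) -> PoseFrame:
    return PoseFrame(frame_index, timestamp, keypoints)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (30 participants, all five movements)."""
    config = StudyGenConfig(seed=7)
    table, ground_truth = generate_study(config)
    return config, table, ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
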