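"""Joint-angle geometry on 2D pixel keypoints.

Sagittal movements (hip flexion/extension, knee flexion) use a triangle of
three keypoints: the interior angle ``alpha`` at the measured joint is
obtained with the law of cosines and the reported range of motion is the
supplement, ``beta = 180 - alpha``, so that a straight (neutral) limb reads
0 degrees.

Hip inner/outer rotation uses a right triangle between the knee, the ankle,
and the vertical pixel line dropped from the knee: the rotation angle is
``theta = atan(|x_ankle - x_knee| / (y_ankle - y_knee))``.  This references
the image vertical, so unlike the sagittal angles it is *not* invariant
under rotating the camera frame; the camera must be level.

Direction convention (not part of the reported magnitude): for the LEFT leg
viewed from the front, an ankle displaced toward image right of the knee is
labelled *inner* rotation and toward image left *outer*; mirrored for the
right leg.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

from .errors import DegenerateGeometryError, InvalidPostureError
from .pose_model import (
    AngleMeasurement,
    JointName,
    Keypoint2D,
    Method,
    Movement,
    PoseFrame,
    Side,
    StudyTable,
)

__all__ = [
    "angle_at_vertex",
    "hip_sagittal_rom",
    "knee_flexion_rom",
    "hip_rotation_rom",
    "measure_frame",
    "save_measurement",
    "round_half_away",
]

# tolerated floating-point excursion of the arccos argument beyond [-1, 1]
_ACOS_SLACK = 1e-12


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (goniometer reading)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _dist(p: Keypoint2D, q: Keypoint2D) -> float:
    return math.hypot(p.x_px - q.x_px, p.y_px - q.y_px)


def angle_at_vertex(vertex: Keypoint2D, a: Keypoint2D, b: Keypoint2D) -> float:
    """Interior angle at ``vertex`` between segments vertex-a and vertex-b.

    Law of cosines:  alpha = arccos((|va|^2 + |vb|^2 - |ab|^2) / (2|va||vb|)).
    Result in degrees, in [0, 180].  Invariant under translation, rotation
    and uniform scaling of the three points.
    """
    d_va = _dist(vertex, a)
    d_vb = _dist(vertex, b)
    if d_va == 0.0 or d_vb == 0.0:
        which = "a" if d_va == 0.0 else "b"
        raise DegenerateGeometryError(
            f"zero-length limb segment: point '{which}' coincides with the vertex"
        )
    d_ab = _dist(a, b)
    arg = (d_va * d_va + d_vb * d_vb - d_ab * d_ab) / (2.0 * d_va * d_vb)
    if arg > 1.0 + _ACOS_SLACK or arg < -1.0 - _ACOS_SLACK:
        raise DegenerateGeometryError(
            f"law-of-cosines argument {arg} outside [-1, 1] beyond numerical slack"
        )
    arg = max(-1.0, min(1.0, arg))
    return math.degrees(math.acos(arg))


def hip_sagittal_rom(
    knee: Keypoint2D, hip: Keypoint2D, shoulder: Keypoint2D
) -> float:
    """Hip flexion/extension ROM: beta = 180 - alpha, alpha at the hip
    between the hip-knee and hip-shoulder lines.  0 for an upright neutral
    posture (knee, hip, shoulder collinear)."""
    return 180.0 - angle_at_vertex(hip, knee, shoulder)


def knee_flexion_rom(hip: Keypoint2D, knee: Keypoint2D, ankle: Keypoint2D) -> float:
    """Knee flexion ROM: beta = 180 - alpha, alpha at the knee between the
    knee-hip and knee-ankle lines.  0 for a straight leg."""
    return 180.0 - angle_at_vertex(knee, hip, ankle)


def hip_rotation_rom(
    knee: Keypoint2D, ankle: Keypoint2D, side: Union[Side, str] = Side.LEFT
) -> tuple[float, Optional[str]]:
    """Hip rotation angle theta from the frontal-view right triangle.

    theta = atan(|dx| / dy) with dx = x_ankle - x_knee and dy the vertical
    drop from knee to ankle (image y is down, so the ankle must be strictly
    below the knee).  Returns ``(theta_deg, direction)`` where direction is
    ``"inner"`` / ``"outer"`` per the module convention, or ``None`` when
    the shank is exactly vertical (theta == 0).
    """
    side = Side(side)
    if ankle.x_px == knee.x_px and ankle.y_px == knee.y_px:
        raise DegenerateGeometryError("knee and ankle keypoints coincide")
    dy = ankle.y_px - knee.y_px
    if dy <= 0:
        raise InvalidPostureError(
            "ankle must lie strictly below the knee in the image for a "
            f"rotation measurement (knee y={knee.y_px}, ankle y={ankle.y_px})"
        )
    dx = ankle.x_px - knee.x_px
    theta = math.degrees(math.atan(abs(dx) / dy))
    if dx == 0:
        direction: Optional[str] = None
    elif side is Side.LEFT:
        direction = "inner" if dx > 0 else "outer"
    else:
        direction = "inner" if dx < 0 else "outer"
    return theta, direction


def _raw_angle(frame: PoseFrame, movement: Movement, side: Union[Side, str]) -> float:
    kp = frame.keypoints
    if movement in (Movement.HIP_FLEXION, Movement.HIP_EXTENSION):
        return hip_sagittal_rom(kp[JointName.KNEE], kp[JointName.HIP], kp[JointName.SHOULDER])
    if movement is Movement.KNEE_FLEXION:
        return knee_flexion_rom(kp[JointName.HIP], kp[JointName.KNEE], kp[JointName.ANKLE])
    theta, _ = hip_rotation_rom(kp[JointName.KNEE], kp[JointName.ANKLE], side)
    return theta


def measure_frame(
    frame: PoseFrame,
    movement: Movement,
    side: Union[Side, str] = Side.LEFT,
    *,
    participant_id: str = "P00",
    session: int = 1,
) -> AngleMeasurement:
    """Measure one frame with the geometry op matching the movement and
    round to the nearest whole degree (ties away from zero)."""
    frame.require(movement)
    angle = _raw_angle(frame, movement, side)
    return AngleMeasurement(
        participant_id=participant_id,
        session=session,
        movement=movement,
        method=Method.APP,
        angle_deg=float(round_half_away(angle)),
        timestamp=frame.timestamp,
    )


def render_frame(frame: PoseFrame):
    """Render a frame's skeleton to a PIL image (for saved reference pictures)."""
    from PIL import Image, ImageDraw

    w, h = frame.resolution
    img = Image.new("RGB", (w, h), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    bones = [
        (JointName.SHOULDER, JointName.HIP),
        (JointName.HIP, JointName.KNEE),
        (JointName.KNEE, JointName.ANKLE),
    ]
    for j1, j2 in bones:
        if j1 in frame.keypoints and j2 in frame.keypoints:
            p, q = frame.keypoints[j1], frame.keypoints[j2]
            draw.line([(p.x_px, p.y_px), (q.x_px, q.y_px)], fill=(200, 200, 200), width=2)
    for kp in frame.keypoints.values():
        draw.ellipse(
            [kp.x_px - 4, kp.y_px - 4, kp.x_px + 4, kp.y_px + 4], fill=(60, 120, 255)
        )
    return img


def save_measurement(
    measurement: AngleMeasurement,
    log: StudyTable,
    frame: Optional[PoseFrame] = None,
    frame_store: Optional[Union[str, Path]] = None,
) -> StudyTable:
    """Append a measurement to the log and persist its source frame.

    The frame file is named ``{participant}_{session}_{movement}.png`` so it
    can later serve as the reference picture for that measurement.
    """
    log.add(measurement)
    if frame is not None and frame_store is not None:
        store = Path(frame_store)
        store.mkdir(parents=True, exist_ok=True)
        name = (
            f"{measurement.participant_id}_{measurement.session}_"
            f"{measurement.movement.value}.png"
        )
        render_frame(frame).save(store / name)
    return log
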