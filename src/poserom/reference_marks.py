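"""Reference-picture angles from manually placed anatomical landmarks.

An experienced rater marks bony landmarks on the saved video frame (the
same landmarks a universal goniometer would use) and the joint angle is
computed from those pixel coordinates with *exactly the same geometry* as
the live keypoint measurement — the two methods differ only in where the
points come from, never in the math.

Landmark sets per movement:

* hip flexion/extension — greater trochanter (hip vertex), lateral femoral
  epicondyle (knee role), midpoint of the humeral head (shoulder role);
* knee flexion — greater trochanter (hip role), lateral femoral epicondyle
  (knee vertex), lateral malleolus of the fibula (ankle role);
* hip inner/outer rotation — midpoint of the patella (knee role), centre of
  the talocrural articular space (ankle role).

Values are read at 1-degree intervals (rounded, ties away from zero).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

from .angle_engine import (
    hip_rotation_rom,
    hip_sagittal_rom,
    knee_flexion_rom,
    round_half_away,
)
from .errors import FormatError, ParseError, ValidationError
from .pose_model import (
    AngleMeasurement,
    Keypoint2D,
    Method,
    Movement,
    Side,
)

# canonical landmark names
GREATER_TROCHANTER = "greater_trochanter"
LATERAL_FEMORAL_EPICONDYLE = "lateral_femoral_epicondyle"
HUMERAL_HEAD_MIDPOINT = "humeral_head_midpoint"
LATERAL_MALLEOLUS = "lateral_malleolus"
PATELLA_MIDPOINT = "patella_midpoint"
TALOCRURAL_CENTRE = "talocrural_centre"

#: Ordered landmark names each movement requires.
LANDMARKS_BY_MOVEMENT: dict[Movement, tuple[str, ...]] = {
    Movement.HIP_FLEXION: (
        GREATER_TROCHANTER,
        LATERAL_FEMORAL_EPICONDYLE,
        HUMERAL_HEAD_MIDPOINT,
    ),
    Movement.HIP_EXTENSION: (
        GREATER_TROCHANTER,
        LATERAL_FEMORAL_EPICONDYLE,
        HUMERAL_HEAD_MIDPOINT,
    ),
    Movement.KNEE_FLEXION: (
        GREATER_TROCHANTER,
        LATERAL_FEMORAL_EPICONDYLE,
        LATERAL_MALLEOLUS,
    ),
    Movement.HIP_INNER_ROTATION: (PATELLA_MIDPOINT, TALOCRURAL_CENTRE),
    Movement.HIP_OUTER_ROTATION: (PATELLA_MIDPOINT, TALOCRURAL_CENTRE),
}


@dataclass(frozen=True)
class LandmarkSet:
    """Operator-placed landmarks for one movement on one reference picture."""

    movement: Movement
    points: Mapping[str, Keypoint2D]

    def __post_init__(self) -> None:
        expected = LANDMARKS_BY_MOVEMENT[self.movement]
        got = set(self.points)
        if got != set(expected):
            raise ValidationError(
                f"{self.movement.value} needs landmarks {expected}, got {sorted(got)}"
            )


def reference_angle_unrounded(landmarks: LandmarkSet, side: Union[Side, str] = Side.LEFT) -> float:
    """The landmark angle before the 1-degree reading resolution is applied."""
    pts = landmarks.points
    mv = landmarks.movement
    if mv in (Movement.HIP_FLEXION, Movement.HIP_EXTENSION):
        return hip_sagittal_rom(
            knee=pts[LATERAL_FEMORAL_EPICONDYLE],
            hip=pts[GREATER_TROCHANTER],
            shoulder=pts[HUMERAL_HEAD_MIDPOINT],
        )
    if mv is Movement.KNEE_FLEXION:
        return knee_flexion_rom(
            hip=pts[GREATER_TROCHANTER],
            knee=pts[LATERAL_FEMORAL_EPICONDYLE],
            ankle=pts[LATERAL_MALLEOLUS],
        )
    theta, _ = hip_rotation_rom(
        knee=pts[PATELLA_MIDPOINT], ankle=pts[TALOCRURAL_CENTRE], side=side
    )
    return theta


def reference_angle(
    landmarks: LandmarkSet,
    side: Union[Side, str] = Side.LEFT,
    *,
    participant_id: str = "P00",
    session: int = 1,
    timestamp: Optional[float] = None,
) -> AngleMeasurement:
    """Reference-picture measurement: same geometry as the app, read at 1-degree
    intervals, method ``reference``."""
    angle = reference_angle_unrounded(landmarks, side)
    return AngleMeasurement(
        participant_id=participant_id,
        session=session,
        movement=landmarks.movement,
        method=Method.REFERENCE,
        angle_deg=float(round_half_away(angle)),
        timestamp=timestamp,
    )


# ---------------------------------------------------------------------------
# landmark file I/O (CSV: participant_id,session,movement,point_name,x_px,y_px)

LANDMARK_COLUMNS = ["participant_id", "session", "movement", "point_name", "x_px", "y_px"]

LandmarkKey = tuple[str, int, Movement]


def read_landmarks(path: Union[str, Path]) -> dict[LandmarkKey, LandmarkSet]:
    """Read operator landmark placements, one LandmarkSet per
    (participant, session, movement)."""
    path = Path(path)
    grouped: dict[LandmarkKey, dict[str, Keypoint2D]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(LANDMARK_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                key = (row["participant_id"], int(row["session"]), Movement(row["movement"]))
                point = Keypoint2D(float(row["x_px"]), float(row["y_px"]))
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
            name = row["point_name"]
            pts = grouped.setdefault(key, {})
            if name in pts:
                raise ParseError(
                    f"line {line_no}: duplicate point '{name}' for {key}"
                )
            pts[name] = point
    return {key: LandmarkSet(key[2], pts) for key, pts in grouped.items()}


def write_landmarks(
    landmarks: Mapping[LandmarkKey, LandmarkSet], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_COLUMNS)
        for (pid, session, movement), lms in sorted(
            landmarks.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
        ):
            for name in LANDMARKS_BY_MOVEMENT[movement]:
                kp = lms.points[name]
                writer.writerow([pid, session, movement.value, name, repr(kp.x_px), repr(kp.y_px)])
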