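"""Domain types and file I/O for keypoint streams and study tables.

Coordinate convention: image pixels with the origin at the top-left corner,
``x`` increasing rightward and ``y`` increasing downward.  All geometry in
:mod:`poserom.angle_engine` is written against this convention.

Timestamps are seconds-as-float in memory.  Study-table files store them as
ISO-8601 UTC strings; keypoint files keep video-relative seconds as floats.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, IntegrityError, ParseError, ValidationError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_RESOLUTION = (1280, 720)


class JointName(str, Enum):
    """The four keypoints the angle engine consumes (measured side)."""

    SHOULDER = "shoulder"
    HIP = "hip"
    KNEE = "knee"
    ANKLE = "ankle"


class Movement(str, Enum):
    HIP_FLEXION = "hip_flexion"
    HIP_EXTENSION = "hip_extension"
    HIP_INNER_ROTATION = "hip_inner_rotation"
    HIP_OUTER_ROTATION = "hip_outer_rotation"
    KNEE_FLEXION = "knee_flexion"


#: Fixed protocol order: hip and knee flexion first, then hip extension,
#: then hip inner and outer rotation.
PROTOCOL_ORDER = (
    Movement.HIP_FLEXION,
    Movement.KNEE_FLEXION,
    Movement.HIP_EXTENSION,
    Movement.HIP_INNER_ROTATION,
    Movement.HIP_OUTER_ROTATION,
)

SAGITTAL_MOVEMENTS = frozenset(
    {Movement.HIP_FLEXION, Movement.HIP_EXTENSION, Movement.KNEE_FLEXION}
)
ROTATION_MOVEMENTS = frozenset(
    {Movement.HIP_INNER_ROTATION, Movement.HIP_OUTER_ROTATION}
)

#: Keypoints each movement requires in a frame.
REQUIRED_KEYPOINTS = {
    Movement.HIP_FLEXION: (JointName.KNEE, JointName.HIP, JointName.SHOULDER),
    Movement.HIP_EXTENSION: (JointName.KNEE, JointName.HIP, JointName.SHOULDER),
    Movement.KNEE_FLEXION: (JointName.HIP, JointName.KNEE, JointName.ANKLE),
    Movement.HIP_INNER_ROTATION: (JointName.KNEE, JointName.ANKLE),
    Movement.HIP_OUTER_ROTATION: (JointName.KNEE, JointName.ANKLE),
}


class Method(str, Enum):
    APP = "app"
    REFERENCE = "reference"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Keypoint2D:
    """A 2D pixel coordinate (origin top-left, y down)."""

    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_px) and math.isfinite(self.y_px)):
            raise ValidationError(
                f"keypoint coordinates must be finite, got ({self.x_px}, {self.y_px})"
            )


@dataclass(frozen=True)
class PoseFrame:
    """One video frame's named keypoints in pixel space."""

    frame_index: int
    timestamp: float
    keypoints: Mapping[JointName, Keypoint2D]
    resolution: tuple[int, int] = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise ValidationError(f"resolution must be positive, got {self.resolution}")

    def require(self, movement: Movement) -> None:
        """Raise if any keypoint the movement needs is absent."""
        from .errors import MissingKeypointError

        for joint in REQUIRED_KEYPOINTS[movement]:
            if joint not in self.keypoints:
                raise MissingKeypointError(
                    f"frame {self.frame_index}: missing keypoint "
                    f"'{joint.value}' required for {movement.value}"
                )


def _is_whole(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) <= tol


@dataclass(frozen=True)
class AngleMeasurement:
    """One saved joint angle.

    ``angle_deg`` carries the reported range-of-motion value: the
    supplementary angle beta = 180 - alpha for sagittal movements, the
    shank deviation theta for rotations.  App values are whole degrees;
    reference-picture values are read at 1-degree intervals.
    """

    participant_id: str
    session: int
    movement: Movement
    method: Method
    angle_deg: float
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValidationError(f"session must be 1 or 2, got {self.session}")
        upper = 90.0 if self.movement in ROTATION_MOVEMENTS else 180.0
        if not (0.0 <= self.angle_deg <= upper):
            raise ValidationError(
                f"{self.movement.value} angle {self.angle_deg} outside [0, {upper}]"
            )
        # both methods report at 1-degree resolution
        if not _is_whole(self.angle_deg):
            raise ValidationError(
                f"{self.method.value} angle must be a whole degree, got {self.angle_deg}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.participant_id, self.session, self.movement.value, self.method.value)


class StudyTable:
    """Participant x session x movement x method angle matrix.

    At most one record per (participant, session, movement, method) key.
    """

    def __init__(
        self,
        records: Iterable[AngleMeasurement] = (),
        *,
        inter_session_interval_h: float = 24.0,
    ) -> None:
        self._records: dict[tuple, AngleMeasurement] = {}
        self.inter_session_interval_h = inter_session_interval_h
        for rec in records:
            self.add(rec)

    def add(self, rec: AngleMeasurement) -> None:
        if rec.key in self._records:
            raise IntegrityError(f"duplicate measurement key {rec.key}")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AngleMeasurement]:
        return iter(self._records.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self._records == other._records

    @property
    def participants(self) -> list[str]:
        return sorted({r.participant_id for r in self})

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def select(
        self,
        *,
        movement: Optional[Movement] = None,
        session: Optional[int] = None,
        method: Optional[Method] = None,
    ) -> list[AngleMeasurement]:
        out = []
        for r in self:
            if movement is not None and r.movement is not movement:
                continue
            if session is not None and r.session != session:
                continue
            if method is not None and r.method is not method:
                continue
            out.append(r)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": r.participant_id,
                "session": r.session,
                "movement": r.movement.value,
                "method": r.method.value,
                "angle_deg": r.angle_deg,
                "timestamp": r.timestamp,
            }
            for r in self
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "session",
                "movement",
                "method",
                "angle_deg",
                "timestamp",
            ],
        )


# ---------------------------------------------------------------------------
# keypoint stream I/O

KEYPOINT_COLUMNS = [
    "frame_index",
    "timestamp",
    "shoulder_x",
    "shoulder_y",
    "hip_x",
    "hip_y",
    "knee_x",
    "knee_y",
    "ankle_x",
    "ankle_y",
]


def _frame_from_row(
    row: Mapping[str, str], line_no: int, resolution: tuple[int, int]
) -> PoseFrame:
    def _num(fieldname: str, caster, required: bool = True):
        raw = row.get(fieldname, "")
        raw = raw.strip() if isinstance(raw, str) else raw
        if raw in ("", None):
            if required:
                raise ParseError(
                    f"line {line_no}: missing required field '{fieldname}'"
                )
            return None
        try:
            return caster(raw)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"line {line_no}: non-numeric value {raw!r} in field '{fieldname}'"
            ) from exc

    frame_index = _num("frame_index", int)
    timestamp = _num("timestamp", float)
    keypoints: dict[JointName, Keypoint2D] = {}
    for joint in JointName:
        x = _num(f"{joint.value}_x", float, required=False)
        y = _num(f"{joint.value}_y", float, required=False)
        if (x is None) != (y is None):
            missing = f"{joint.value}_x" if x is None else f"{joint.value}_y"
            raise ParseError(
                f"line {line_no}: frame {frame_index} has half a keypoint — "
                f"field '{missing}' is empty"
            )
        if x is not None:
            keypoints[joint] = Keypoint2D(x, y)
    return PoseFrame(frame_index, timestamp, keypoints, resolution)


def read_pose_frames(
    path: PathLike,
    format: Optional[str] = None,
    *,
    resolution: tuple[int, int] = DEFAULT_RESOLUTION,
) -> list[PoseFrame]:
    """Read a keypoint stream from CSV or JSON, sorted by frame_index.

    Missing keypoints appear as empty cells (CSV) or omitted keys (JSON);
    the frame is still returned and rejected later only if a measurement
    actually needs the absent joint.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    frames: list[PoseFrame] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = set(KEYPOINT_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise FormatError(
                    f"{path}: missing required column(s): {', '.join(sorted(missing))}"
                )
            for line_no, row in enumerate(reader, start=2):
                frames.append(_frame_from_row(row, line_no, resolution))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        for i, obj in enumerate(payload):
            row = {k: ("" if v is None else v) for k, v in obj.items()}
            frames.append(_frame_from_row(row, i + 1, resolution))
    else:
        raise ValidationError(f"unknown keypoint format {fmt!r}")
    frames.sort(key=lambda f: f.frame_index)
    return frames


def write_pose_frames(
    frames: Sequence[PoseFrame], path: PathLike, format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for f in sorted(frames, key=lambda f: f.frame_index):
        row: dict[str, object] = {"frame_index": f.frame_index, "timestamp": f.timestamp}
        for joint in JointName:
            kp = f.keypoints.get(joint)
            row[f"{joint.value}_x"] = "" if kp is None else repr(kp.x_px)
            row[f"{joint.value}_y"] = "" if kp is None else repr(kp.y_px)
        rows.append(row)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=KEYPOINT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        for row in rows:
            for k, v in list(row.items()):
                if v == "":
                    row[k] = None
                elif isinstance(v, str):
                    row[k] = float(v)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValidationError(f"unknown keypoint format {fmt!r}")


# ---------------------------------------------------------------------------
# study table I/O

STUDY_COLUMNS = ["participant_id", "session", "movement", "method", "angle_deg", "timestamp"]

_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


def seconds_to_iso(t: Optional[float]) -> str:
    if t is None:
        return ""
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat().replace("+00:00", "Z")


def iso_to_seconds(s: str) -> Optional[float]:
    s = s.strip()
    if not s:
        return None
    return datetime.fromisoformat(s.replace("Z", "+00:00")).timestamp()


def _measurement_from_row(row: Mapping[str, object], line_no: int) -> AngleMeasurement:
    try:
        session = int(str(row["session"]))
        movement = Movement(str(row["movement"]))
        method = Method(str(row["method"]))
        angle = float(str(row["angle_deg"]))
    except KeyError as exc:
        raise FormatError(f"line {line_no}: missing required column {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"line {line_no}: {exc}") from exc
    ts_raw = row.get("timestamp", "")
    ts = iso_to_seconds(str(ts_raw)) if ts_raw not in (None, "") else None
    return AngleMeasurement(
        participant_id=str(row["participant_id"]),
        session=session,
        movement=movement,
        method=method,
        angle_deg=angle,
        timestamp=ts,
    )


def read_study_table(path: PathLike, format: Optional[str] = None) -> StudyTable:
    """Read a study table (CSV or JSON).  Duplicate keys are rejected."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    table = StudyTable()
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        if not lines or not lines[0].strip():
            logger.warning("%s: empty study table file", path)
            return table
        reader = csv.DictReader(lines)
        missing = set(STUDY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        for line_no, row in enumerate(reader, start=2):
            table.add(_measurement_from_row(row, line_no))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            raw = fh.read()
        if not raw.strip():
            logger.warning("%s: empty study table file", path)
            return table
        for i, obj in enumerate(json.loads(raw)):
            table.add(_measurement_from_row(obj, i + 1))
    else:
        raise ValidationError(f"unknown study table format {fmt!r}")
    return table


def write_study_table(
    table: StudyTable,
    path: PathLike,
    format: Optional[str] = None,
    *,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a study table; ``header_comments`` become leading ``#`` lines (CSV)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records = sorted(table, key=lambda r: r.key)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            writer = csv.writer(fh)
            writer.writerow(STUDY_COLUMNS)
            for r in records:
                writer.writerow(
                    [
                        r.participant_id,
                        r.session,
                        r.movement.value,
                        r.method.value,
                        int(r.angle_deg) if _is_whole(r.angle_deg) else r.angle_deg,
                        seconds_to_iso(r.timestamp),
                    ]
                )
    elif fmt == "json":
        payload = [
            {
                "participant_id": r.participant_id,
                "session": r.session,
                "movement": r.movement.value,
                "method": r.method.value,
                "angle_deg": r.angle_deg,
                "timestamp": seconds_to_iso(r.timestamp) or None,
            }
            for r in records
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown study table format {fmt!r}")
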