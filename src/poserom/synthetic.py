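"""Synthetic skeletons, cameras, and whole test-retest studies.

The generator inverts the measurement geometry: given a true joint angle it
poses a planar stick skeleton in a fronto-parallel plane at the standardized
camera distance and projects it through a pinhole camera.  Because the
skeleton plane is parallel to the image plane, the projection is a
similarity transform and every projected angle equals the posed angle
exactly — so project-then-measure round-trips to machine precision before
rounding.

Postures (upright stance, per the measurement protocol):

* hip flexion/extension — lateral view; trunk vertical, thigh rotated
  forward/backward by the true angle, shank hanging vertically;
* knee flexion — lateral view; trunk and thigh vertical, shank rotated
  backward by the true angle;
* hip inner/outer rotation — frontal view; shank of fixed length tilted so
  the ankle is displaced laterally from the vertical through the knee,
  a 2D proxy for rotation about the femoral long axis, which is exactly
  what the frontal-view measurement observes.

A whole study draws participant true angles from Normal(mu, sigma_b^2),
session values adding Normal(0, sigma_w^2), measures noisy projected
frames with the app geometry, and derives session-1 reference measurements
from landmark coordinates (true joint centres + optional anatomical offset
+ placement noise) on the same frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .angle_engine import _raw_angle, measure_frame
from .errors import FramingError, ValidationError
from .pose_model import (
    JointName,
    Keypoint2D,
    Movement,
    PROTOCOL_ORDER,
    PoseFrame,
    Side,
    StudyTable,
)
from .reference_marks import (
    LANDMARKS_BY_MOVEMENT,
    LandmarkSet,
    reference_angle,
)

logger = logging.getLogger(__name__)

#: Anatomical ranges (degrees) the generator enforces by resampling.
ANATOMICAL_RANGES: dict[Movement, tuple[float, float]] = {
    Movement.HIP_FLEXION: (0.0, 130.0),
    Movement.HIP_EXTENSION: (0.0, 40.0),
    Movement.HIP_INNER_ROTATION: (0.0, 60.0),
    Movement.HIP_OUTER_ROTATION: (0.0, 60.0),
    Movement.KNEE_FLEXION: (0.0, 150.0),
}

#: session-1 start of the simulated protocol (UTC epoch seconds); session 2
#: follows after the configured test-retest interval.  Fixed so identical
#: configs produce byte-identical tables.
_BASE_EPOCH_S = 1_704_099_600.0  # 2024-01-01T09:00:00Z


@dataclass(frozen=True)
class CameraSetup:
    """Standardized webcam geometry: lens 55 cm above the floor, 2.05 m from
    the participant plane, 720p.  The horizontal field of view defaults to
    78 degrees, typical of integrated laptop webcams and wide enough for a
    standing adult to fit the frame at this distance."""

    height_cm: float = 55.0
    distance_m: float = 2.05
    resolution: tuple[int, int] = (1280, 720)
    hfov_deg: float = 78.0

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.distance_m <= 0:
            raise ValidationError("camera height and distance must be positive")
        if not 0 < self.hfov_deg < 180:
            raise ValidationError(f"hfov_deg must be in (0, 180), got {self.hfov_deg}")

    @property
    def focal_px(self) -> float:
        return (self.resolution[0] / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths as fixed fractions of stature (standard proportions:
    trunk 0.30, thigh 0.245, shank 0.246)."""

    stature_cm: float = 177.5
    trunk_frac: float = 0.30
    thigh_frac: float = 0.245
    shank_frac: float = 0.246

    def __post_init__(self) -> None:
        if self.stature_cm <= 0:
            raise ValidationError("stature must be positive")
        for frac in (self.trunk_frac, self.thigh_frac, self.shank_frac):
            if frac <= 0:
                raise ValidationError("segment fractions must be positive")

    @property
    def trunk_m(self) -> float:
        return self.stature_cm / 100.0 * self.trunk_frac

    @property
    def thigh_m(self) -> float:
        return self.stature_cm / 100.0 * self.thigh_frac

    @property
    def shank_m(self) -> float:
        return self.stature_cm / 100.0 * self.shank_frac


def _project(
    world_xy: dict[JointName, tuple[float, float]], camera: CameraSetup
) -> dict[JointName, Keypoint2D]:
    """Pinhole projection of points in the fronto-parallel subject plane.

    World coordinates: metres, origin at the camera centre, X rightward in
    the image, Y up.  Image: u = cx + f X/Z, v = cy - f Y/Z (y down).
    """
    w, h = camera.resolution
    f = camera.focal_px
    z = camera.distance_m
    out = {}
    for joint, (x, y) in world_xy.items():
        u = w / 2.0 + f * x / z
        v = h / 2.0 - f * y / z
        if not (0 <= u < w and 0 <= v < h):
            raise FramingError(
                f"{joint.value} keypoint projects outside the {w}x{h} frame "
                f"(u={u:.1f}, v={v:.1f}); widen hfov_deg or increase distance_m"
            )
        out[joint] = Keypoint2D(u, v)
    return out


def project_skeleton(
    movement: Movement,
    angle_deg: float,
    *,
    anthropometry: Anthropometry = Anthropometry(),
    camera: CameraSetup = CameraSetup(),
    side: Union[Side, str] = Side.LEFT,
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> PoseFrame:
    """Pose a standing skeleton at a true joint angle and project it.

    The emitted frame reproduces ``angle_deg`` exactly under the matching
    measurement op, before whole-degree rounding.
    """
    lo, hi = ANATOMICAL_RANGES[movement]
    if not lo <= angle_deg <= hi:
        raise ValidationError(
            f"{movement.value} angle {angle_deg} outside anatomical range [{lo}, {hi}]"
        )
    side = Side(side)
    a = anthropometry
    floor_y = -camera.height_cm / 100.0  # camera is height_cm above the floor
    ankle_y = floor_y
    knee_y = ankle_y + a.shank_m
    hip_y = knee_y + a.thigh_m
    shoulder_y = hip_y + a.trunk_m
    rad = math.radians(angle_deg)

    # standing column (X=0 at the subject's vertical axis)
    world: dict[JointName, tuple[float, float]] = {
        JointName.ANKLE: (0.0, ankle_y),
        JointName.KNEE: (0.0, knee_y),
        JointName.HIP: (0.0, hip_y),
        JointName.SHOULDER: (0.0, shoulder_y),
    }
    if movement in (Movement.HIP_FLEXION, Movement.HIP_EXTENSION):
        # lateral view, anterior toward image right; thigh swings from the hip
        s = 1.0 if movement is Movement.HIP_FLEXION else -1.0
        kx = s * a.thigh_m * math.sin(rad)
        ky = hip_y - a.thigh_m * math.cos(rad)
        world[JointName.KNEE] = (kx, ky)
        world[JointName.ANKLE] = (kx, ky - a.shank_m)  # shank hangs vertical
    elif movement is Movement.KNEE_FLEXION:
        # lateral view; shank swings backward (heel lifts) from the knee
        ax = -a.shank_m * math.sin(rad)
        ay = knee_y - a.shank_m * math.cos(rad)
        world[JointName.ANKLE] = (ax, ay)
    else:
        # frontal view; fixed-length shank tilted from the vertical.  For the
        # left leg, inner rotation displaces the ankle toward image right.
        inner_sign = 1.0 if side is Side.LEFT else -1.0
        s = inner_sign if movement is Movement.HIP_INNER_ROTATION else -inner_sign
        world[JointName.ANKLE] = (
            s * a.shank_m * math.sin(rad),
            knee_y - a.shank_m * math.cos(rad),
        )

    keypoints = _project(world, camera)
    return PoseFrame(frame_index, timestamp, keypoints, camera.resolution)


def add_detection_noise(
    frame: PoseFrame, sigma_px: float, rng: np.random.Generator
) -> PoseFrame:
    """Perturb every keypoint coordinate with iid Gaussian noise of SD
    ``sigma_px``.  ``sigma_px = 0`` returns the frame unchanged."""
    if sigma_px < 0:
        raise ValidationError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return frame
    noisy = {}
    for joint, kp in frame.keypoints.items():
        dx, dy = rng.normal(0.0, sigma_px, size=2)
        noisy[joint] = Keypoint2D(kp.x_px + dx, kp.y_px + dy)
    return PoseFrame(frame.frame_index, frame.timestamp, noisy, frame.resolution)


def estimate_angle_noise_sd(
    movement: Movement,
    angle_deg: float,
    sigma_px: float,
    *,
    anthropometry: Anthropometry = Anthropometry(),
    camera: CameraSetup = CameraSetup(),
    side: Union[Side, str] = Side.LEFT,
    n_draws: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo estimate of the angle-domain SD induced by pixel noise of
    SD ``sigma_px`` at a given posture (unrounded geometry)."""
    if sigma_px == 0:
        return 0.0
    rng = np.random.default_rng(0) if rng is None else rng
    frame = project_skeleton(
        movement, angle_deg, anthropometry=anthropometry, camera=camera, side=side
    )
    vals = np.empty(n_draws)
    for i in range(n_draws):
        vals[i] = _raw_angle(add_detection_noise(frame, sigma_px, rng), movement, side)
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# whole-study generation


class MovementParams(BaseModel):
    """Population mean and between-subject SD of a movement's true ROM."""

    mean_deg: float
    between_sd_deg: float = Field(ge=0.0)


#: Default movement populations: anatomically plausible active ROMs for
#: healthy young adults measured standing, chosen for documentation and
#: testing (not estimates of any particular cohort).
DEFAULT_MOVEMENTS: dict[Movement, MovementParams] = {
    Movement.HIP_FLEXION: MovementParams(mean_deg=105.0, between_sd_deg=10.0),
    Movement.KNEE_FLEXION: MovementParams(mean_deg=125.0, between_sd_deg=8.0),
    Movement.HIP_EXTENSION: MovementParams(mean_deg=18.0, between_sd_deg=5.0),
    Movement.HIP_INNER_ROTATION: MovementParams(mean_deg=35.0, between_sd_deg=8.0),
    Movement.HIP_OUTER_ROTATION: MovementParams(mean_deg=40.0, between_sd_deg=8.0),
}


class StudyGenConfig(BaseModel):
    """Parameters of a synthetic test-retest study.

    Defaults emulate the standardized protocol: 30 participants, two
    sessions 24 h apart, five movements in fixed order, app measurements in
    whole degrees and reference-picture measurements at 1-degree intervals.
    """

    n_participants: int = Field(default=30, ge=3)
    movements: dict[Movement, MovementParams] = Field(
        default_factory=lambda: dict(DEFAULT_MOVEMENTS)
    )
    within_sd_deg: float = Field(default=3.0, ge=0.0)
    keypoint_noise_sd_px: float = Field(default=1.0, ge=0.0)
    landmark_noise_sd_px: float = Field(default=2.0, ge=0.0)
    landmark_offset_px: float = Field(default=0.0)
    inter_session_interval_h: float = Field(default=24.0, gt=0.0)
    side: Side = Side.LEFT
    stature_cm: float = Field(default=177.5, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_means(self) -> "StudyGenConfig":
        for movement, params in self.movements.items():
            lo, hi = ANATOMICAL_RANGES[movement]
            if not lo <= params.mean_deg <= hi:
                raise ValueError(
                    f"{movement.value} mean {params.mean_deg} outside [{lo}, {hi}]"
                )
        return self

    def theoretical_icc(self, sigma_meas_deg: float = 0.0) -> dict[Movement, float]:
        """sigma_b^2 / (sigma_b^2 + sigma_w^2 + sigma_meas^2) per movement."""
        out = {}
        for movement, params in self.movements.items():
            vb = params.between_sd_deg**2
            vw = self.within_sd_deg**2
            out[movement] = vb / (vb + vw + sigma_meas_deg**2) if vb + vw > 0 else 1.0
        return out


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    counter: dict[str, int],
) -> float:
    """Draw Normal(mean, sd^2), resampling out-of-range values (counted)."""
    if sd == 0:
        return min(hi, max(lo, mean))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
        counter["resampled"] += 1
    raise ValidationError(
        f"could not draw a value in [{lo}, {hi}] from N({mean}, {sd}^2)"
    )


def _landmarks_from_frame(
    frame: PoseFrame,
    movement: Movement,
    offset_px: float,
    noise_sd_px: float,
    rng: np.random.Generator,
) -> LandmarkSet:
    """Operator landmark placements: true joint centres plus a constant
    anatomical offset (applied along +x) plus Gaussian placement noise."""
    role_map = dict(zip(LANDMARKS_BY_MOVEMENT[movement], _landmark_roles(movement)))
    pts = {}
    for name, joint in role_map.items():
        kp = frame.keypoints[joint]
        dx = offset_px + (rng.normal(0.0, noise_sd_px) if noise_sd_px > 0 else 0.0)
        dy = rng.normal(0.0, noise_sd_px) if noise_sd_px > 0 else 0.0
        pts[name] = Keypoint2D(kp.x_px + dx, kp.y_px + dy)
    return LandmarkSet(movement, pts)


def _landmark_roles(movement: Movement) -> tuple[JointName, ...]:
    if movement in (Movement.HIP_FLEXION, Movement.HIP_EXTENSION):
        return (JointName.HIP, JointName.KNEE, JointName.SHOULDER)
    if movement is Movement.KNEE_FLEXION:
        return (JointName.HIP, JointName.KNEE, JointName.ANKLE)
    return (JointName.KNEE, JointName.ANKLE)


def generate_study(
    config: StudyGenConfig,
) -> tuple[StudyTable, dict]:
    """Simulate a complete two-session study with app and reference methods.

    Returns the StudyTable and a ground-truth record holding the latent
    participant and session angles, the generated frames' noise settings,
    the per-movement measurement-noise SD (Monte-Carlo estimate when pixel
    noise is present), the theoretical ICC, and resampling counts.
    """
    rng = np.random.default_rng(config.seed)
    anthropometry = Anthropometry(stature_cm=config.stature_cm)
    camera = CameraSetup()
    table = StudyTable(inter_session_interval_h=config.inter_session_interval_h)
    counter = {"resampled": 0}
    movements = [m for m in PROTOCOL_ORDER if m in config.movements]

    latent_true: dict[str, dict[str, float]] = {}
    latent_session: dict[str, dict[str, dict[str, float]]] = {}

    # angle-domain noise per movement, estimated at the population mean
    sigma_meas: dict[Movement, float] = {}
    for movement in movements:
        sigma_meas[movement] = estimate_angle_noise_sd(
            movement,
            config.movements[movement].mean_deg,
            config.keypoint_noise_sd_px,
            anthropometry=anthropometry,
            camera=camera,
            side=config.side,
            rng=rng,
        )

    n_draws_total = 0
    interval_s = config.inter_session_interval_h * 3600.0
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        latent_true[pid] = {}
        latent_session[pid] = {"1": {}, "2": {}}
        for mi, movement in enumerate(movements):
            params = config.movements[movement]
            lo, hi = ANATOMICAL_RANGES[movement]
            theta_i = _truncated_normal(
                rng, params.mean_deg, params.between_sd_deg, lo, hi, counter
            )
            n_draws_total += 1
            latent_true[pid][movement.value] = theta_i
            for session in (1, 2):
                theta_is = _truncated_normal(
                    rng, theta_i, config.within_sd_deg, lo, hi, counter
                )
                n_draws_total += 1
                latent_session[pid][str(session)][movement.value] = theta_is
                ts = (
                    _BASE_EPOCH_S
                    + (session - 1) * interval_s
                    + i * 300.0
                    + mi * 60.0
                )
                frame = project_skeleton(
                    movement,
                    theta_is,
                    anthropometry=anthropometry,
                    camera=camera,
                    side=config.side,
                    frame_index=mi,
                    timestamp=ts,
                )
                noisy = add_detection_noise(frame, config.keypoint_noise_sd_px, rng)
                app = measure_frame(
                    noisy, movement, config.side, participant_id=pid, session=session
                )
                table.add(app)
                if session == 1:
                    lms = _landmarks_from_frame(
                        frame,
                        movement,
                        config.landmark_offset_px,
                        config.landmark_noise_sd_px,
                        rng,
                    )
                    ref = reference_angle(
                        lms,
                        config.side,
                        participant_id=pid,
                        session=1,
                        timestamp=ts + 30.0,
                    )
                    table.add(ref)

    frac_resampled = counter["resampled"] / max(1, n_draws_total)
    if frac_resampled > 0.01:
        logger.warning(
            "%.1f%% of angle draws fell outside anatomical ranges and were "
            "resampled; consider narrower movement parameters",
            100 * frac_resampled,
        )

    theo = config.theoretical_icc()
    ground_truth = {
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "participant_true_angles_deg": latent_true,
        "session_angles_deg": latent_session,
        "sigma_meas_deg": {m.value: sigma_meas[m] for m in movements},
        "theoretical_icc": {m.value: theo[m] for m in movements},
        "theoretical_icc_with_meas_noise": {
            m.value: (
                config.movements[m].between_sd_deg**2
                / (
                    config.movements[m].between_sd_deg**2
                    + config.within_sd_deg**2
                    + sigma_meas[m] ** 2
                )
            )
            for m in movements
        },
        "n_resampled_draws": counter["resampled"],
        "resampled_fraction": frac_resampled,
    }
    return table, ground_truth
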