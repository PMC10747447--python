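"""Synthetic paired-session generator with known ground truth.

Real concurrent-validity studies record a subject simultaneously with a
low-rate multi-camera RGB rig and a high-rate reference motion-capture
system.  This module emulates such a session end to end:

1. a smooth single-extremum joint-angle profile (raised-cosine ramp, hold,
   raised-cosine return) drives
2. an articulated 7-keypoint skeleton (forward kinematics constructed to be
   exactly consistent with :mod:`mvkin.kinematics` — extracting the task
   angle from the generated keypoints recovers the driving profile to
   machine precision), which is
3. projected through a ring of pinhole cameras at the capture rate with
   i.i.d. Gaussian pixel noise, while
4. a reference-system trace of the same motion is sampled at a higher rate
   with independent Gaussian angle noise and an optional constant offset.

Ground truth is retained in the output bundle at both clocks, so recovery
error and agreement statistics can be checked against a known answer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cameras import CameraModel
from .errors import ConfigurationError
from .kinematics import torso_frame
from .series import AngleTrace, KeypointSeries2D, SignConvention, Task

__all__ = [
    "DEFAULT_KEYPOINTS",
    "SkeletonParams",
    "MotionProfile",
    "NoiseModel",
    "SessionBundle",
    "generate_angle_profile",
    "forward_kinematics",
    "project_with_noise",
    "simulate_paired_session",
]

# Seven-point body model: neck, both shoulders, both hips, right knee and ankle.
DEFAULT_KEYPOINTS = (
    "neck",
    "shoulder_L",
    "shoulder_R",
    "hip_R",
    "hip_L",
    "knee_R",
    "ankle_R",
)

_REQUIRED_KEYPOINTS = frozenset(DEFAULT_KEYPOINTS)


@dataclass
class SkeletonParams:
    """Segment lengths (meters) and root position of the synthetic skeleton.

    Defaults approximate a 1.75 m adult: hip-to-neck torso 0.50 m, shoulder
    half-width 0.18 m, hip half-width 0.10 m, femur 0.45 m, tibia 0.43 m,
    pelvis root 0.95 m above the floor.
    """

    torso_length_m: float = 0.50
    shoulder_half_width_m: float = 0.18
    hip_half_width_m: float = 0.10
    femur_length_m: float = 0.45
    tibia_length_m: float = 0.43
    root_m: tuple[float, float, float] = (0.0, 0.0, 0.95)
    keypoints: tuple[str, ...] = DEFAULT_KEYPOINTS

    def __post_init__(self) -> None:
        for name in (
            "torso_length_m",
            "shoulder_half_width_m",
            "hip_half_width_m",
            "femur_length_m",
            "tibia_length_m",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        self.root_m = tuple(float(c) for c in self.root_m)
        self.keypoints = tuple(self.keypoints)
        missing = _REQUIRED_KEYPOINTS - set(self.keypoints)
        if missing:
            raise ConfigurationError(
                f"keypoint set must contain the 7 core names; missing {sorted(missing)}"
            )


@dataclass
class MotionProfile:
    """Single-repetition angle profile: rise, hold, return.

    The profile is a raised-cosine ramp from 0° to ``peak_deg``, a plateau
    of ``hold_fraction`` of the duration, and a mirrored raised-cosine
    return to 0°, sampled at ``rate_hz``.  Smooth and single-extremum, so a
    max/min section of the trace is well defined.
    """

    task: Task = Task.SIDE_DIP_LEFT
    peak_deg: float = 40.0
    duration_s: float = 5.0
    rate_hz: float = 12.0
    hold_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if not 0.0 < self.peak_deg <= 180.0:
            raise ConfigurationError("peak_deg must be in (0, 180]")
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be > 0")
        if not self.rate_hz > 0:
            raise ConfigurationError("rate_hz must be > 0")
        if not 0.0 <= self.hold_fraction < 1.0:
            raise ConfigurationError("hold_fraction must be in [0, 1)")


@dataclass
class NoiseModel:
    """Measurement-noise settings for one simulated session.

    pixel_sigma_px: i.i.d. Gaussian noise added to every projected 2D
    keypoint coordinate.  ref_sigma_deg / ref_offset_deg: independent
    Gaussian noise and a constant bias on the reference-system angle trace,
    emulating the systematic inter-system discrepancies of two measurement
    principles observing the same motion.  ``seed`` pins all randomness.
    """

    pixel_sigma_px: float = 1.0
    ref_sigma_deg: float = 1.0
    ref_offset_deg: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.pixel_sigma_px < 0 or self.ref_sigma_deg < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        self.seed = int(self.seed)


@dataclass
class SessionBundle:
    """Everything one simulated repetition produced.

    ``truth_camera`` is the noiseless driving angle sampled on the camera
    clock; ``truth_reference`` the same continuous profile on the reference
    clock; ``reference`` is truth_reference + noise + offset.  ``views``
    hold the noisy per-camera 2D keypoints.
    """

    task: Task
    truth_camera: AngleTrace
    truth_reference: AngleTrace
    reference: AngleTrace
    views: list[KeypointSeries2D]
    skeleton: SkeletonParams
    rig: list[CameraModel]
    noise: NoiseModel
    repetition: int = 0
    meta: dict = field(default_factory=dict)


def _profile_values(profile: MotionProfile, rate_hz: float) -> np.ndarray:
    """Sample the continuous ramp-hold-return profile at ``rate_hz``."""
    n = int(round(profile.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    u = np.clip(t / profile.duration_s, 0.0, 1.0)
    rise = (1.0 - profile.hold_fraction) / 2.0
    vals = np.empty_like(u)
    up = u < rise
    hold = (u >= rise) & (u <= 1.0 - rise)
    down = u > 1.0 - rise
    if rise > 0:
        vals[up] = 0.5 * (1.0 - np.cos(np.pi * u[up] / rise))
        vals[down] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - u[down]) / rise))
    else:  # pure hold: step profile has no ramp; keep endpoints at 0
        vals[up] = 0.0
        vals[down] = 0.0
    vals[hold] = 1.0
    sign = -1.0 if profile.task is Task.SIDE_DIP_RIGHT else 1.0
    vals = sign * profile.peak_deg * vals
    vals[0] = 0.0
    vals[-1] = 0.0
    return vals


def generate_angle_profile(profile: MotionProfile, rate_hz: float | None = None) -> AngleTrace:
    """Ground-truth angle trace for one repetition of a task.

    ``round(duration*rate) + 1`` samples starting and ending at 0°.  Side
    dips to the left are positive and to the right negative (left-positive
    convention); the Y-balance hip angle is unsigned.
    """
    rate = profile.rate_hz if rate_hz is None else float(rate_hz)
    if rate <= 0:
        raise ConfigurationError("sampling rate must be > 0")
    values = _profile_values(profile, rate)
    convention = (
        SignConvention.LEFT_POSITIVE if profile.task.is_side_dip else SignConvention.UNSIGNED
    )
    return AngleTrace(
        values=values,
        rate_hz=rate,
        task=profile.task,
        convention=convention,
        meta={"peak_deg": profile.peak_deg, "hold_fraction": profile.hold_fraction},
    )


def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _neutral_pose(p: SkeletonParams) -> dict[str, np.ndarray]:
    """Neutral standing pose.  Subject faces +Y; their left is +X."""
    root = np.asarray(p.root_m)
    neck = root + [0.0, 0.0, p.torso_length_m]
    pose = {
        "neck": neck,
        "shoulder_L": neck + [p.shoulder_half_width_m, 0.0, 0.0],
        "shoulder_R": neck - [p.shoulder_half_width_m, 0.0, 0.0],
        "hip_L": root + [p.hip_half_width_m, 0.0, 0.0],
        "hip_R": root - [p.hip_half_width_m, 0.0, 0.0],
    }
    pose["knee_R"] = pose["hip_R"] + [0.0, 0.0, -p.femur_length_m]
    pose["ankle_R"] = pose["knee_R"] + [0.0, 0.0, -p.tibia_length_m]
    return pose


def _pose_at_angle(p: SkeletonParams, task: Task, angle_deg: float) -> dict[str, np.ndarray]:
    pose = _neutral_pose(p)
    theta = np.radians(angle_deg)
    root = np.asarray(p.root_m)
    if task.is_side_dip:
        # Tilt the upper body about the anterior (+Y) axis through the pelvis.
        # Positive angle drops the left (+X) shoulder, matching the
        # left-positive side-bend convention.
        R = _rot_y(theta)
        for name in ("neck", "shoulder_L", "shoulder_R"):
            pose[name] = root + R @ (pose[name] - root)
    elif task is Task.YBT_HIP_EXTENSION:
        # Swing the extended right leg posteriorly in the sagittal plane,
        # measured from the torso frame's -Z so angle extraction round-trips.
        frame = torso_frame(pose["neck"], pose["shoulder_L"], pose["shoulder_R"], pose["hip_R"])
        z = frame.z_axis
        posterior = np.array([0.0, -1.0, 0.0])
        posterior = posterior - (posterior @ z) * z
        posterior = posterior / np.linalg.norm(posterior)
        leg_dir = -z * np.cos(theta) + posterior * np.sin(theta)
        pose["knee_R"] = pose["hip_R"] + p.femur_length_m * leg_dir
        pose["ankle_R"] = pose["knee_R"] + p.tibia_length_m * leg_dir  # knee fully extended
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown task {task}")
    return pose


def forward_kinematics(params: SkeletonParams, trace: AngleTrace, task: Task | None = None):
    """3D keypoint series realizing an angle trace.

    The pose at each frame is constructed so that the corresponding angle
    operation in :mod:`mvkin.kinematics` recovers the driving angle exactly
    (to floating-point rounding): side dips rotate the shoulder line about
    the anterior axis, the Y-balance reach rotates the extended right leg in
    the sagittal plane away from the torso's -Z axis.
    """
    from .series import Skeleton3DSeries  # local import avoids cycle at module load

    if len(trace) == 0:
        raise ConfigurationError("angle trace is empty")
    task = Task(task if task is not None else trace.task)
    names = params.keypoints
    positions = np.empty((len(trace), len(names), 3))
    for i, ang in enumerate(trace.values):
        pose = _pose_at_angle(params, task, float(ang))
        for j, name in enumerate(names):
            positions[i, j] = pose[name]
    return Skeleton3DSeries(keypoints=names, positions=positions, rate_hz=trace.rate_hz)


def project_with_noise(
    camera: CameraModel,
    skel,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> KeypointSeries2D:
    """Project a 3D skeleton series through one camera with pixel noise.

    Perspective projection plus i.i.d. Gaussian noise of ``pixel_sigma_px``
    on each coordinate.  Keypoints behind the camera, at its optical
    center, or projecting outside the image are marked missing (NaN), never
    fabricated.  Passing the same ``rng`` state (or relying on
    ``noise.seed``) reproduces the output bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    pix, valid = camera.project(skel.positions)
    if noise.pixel_sigma_px > 0:
        pix = pix + rng.normal(0.0, noise.pixel_sigma_px, size=pix.shape)
    else:
        # keep the draw order identical regardless of sigma
        rng.normal(0.0, 1.0, size=pix.shape)
    pix[~valid] = np.nan
    return KeypointSeries2D(
        camera=camera.name, keypoints=skel.keypoints, coords=pix, rate_hz=skel.rate_hz
    )


def simulate_paired_session(config) -> list[SessionBundle]:
    """Simulate a full paired capture session from a config.

    Returns one :class:`SessionBundle` per repetition.  Each repetition
    re-uses the same skeleton, rig and motion profile but draws fresh noise
    from an independent, deterministic sub-stream of ``config.seed``.
    """
    from .config import SimulationConfig  # avoid import cycle

    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_dict(config)

    profile = config.motion_profile()
    skeleton = config.skeleton_params()
    rig = config.camera_ring()
    noise = config.noise_model()

    bundles = []
    for rep in range(config.repetitions):
        rep_seq = np.random.SeedSequence(entropy=noise.seed, spawn_key=(rep,))
        cam_rngs = [np.random.default_rng(c) for c in rep_seq.spawn(len(rig))]
        ref_rng = np.random.default_rng(np.random.SeedSequence(entropy=noise.seed, spawn_key=(rep, len(rig))))

        truth_cam = generate_angle_profile(profile)
        truth_ref = generate_angle_profile(profile, rate_hz=config.reference_rate_hz)
        skel = forward_kinematics(skeleton, truth_cam, profile.task)
        views = [
            project_with_noise(cam, skel, noise, rng=rng) for cam, rng in zip(rig, cam_rngs)
        ]

        ref_values = truth_ref.values + noise.ref_offset_deg
        if noise.ref_sigma_deg > 0:
            ref_values = ref_values + ref_rng.normal(0.0, noise.ref_sigma_deg, size=ref_values.shape)
        reference = truth_ref.with_values(ref_values)
        reference.meta.update({"noisy": True, "seed": noise.seed, "repetition": rep})

        bundles.append(
            SessionBundle(
                task=profile.task,
                truth_camera=truth_cam,
                truth_reference=truth_ref,
                reference=reference,
                views=views,
                skeleton=skeleton,
                rig=rig,
                noise=noise,
                repetition=rep,
                meta={"seed": noise.seed, "repetition": rep},
            )
        )
    return bundles
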