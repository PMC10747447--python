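"""Simulation configuration: schema, validation, YAML/JSON round-trip.

The config is a nested mapping with five sections (all optional except
where noted); unknown keys anywhere are rejected so typos fail loudly.

.. code-block:: yaml

    task: side_dip_left          # side_dip_left | side_dip_right | ybt_hip_extension
    seed: 42                     # required: pins all randomness
    repetitions: 5
    profile:
      peak_deg: 40.0
      duration_s: 5.0
      rate_hz: 12.0
      hold_fraction: 0.2
    reference:
      rate_hz: 100.0
      noise_sigma_deg: 1.0
      offset_deg: 0.0
    skeleton:
      torso_length_m: 0.5
      shoulder_half_width_m: 0.18
      hip_half_width_m: 0.10
      femur_length_m: 0.45
      tibia_length_m: 0.43
      root_m: [0.0, 0.0, 0.95]
    rig:
      n_cameras: 4
      radius_m: 3.0
      height_m: 1.2
      focal_px: 1000.0
      image_size_px: [1920, 1080]
    noise:
      pixel_sigma_px: 1.0

Defaults describe the study conditions the package emulates: a ~5 s side
dip to 40° captured by a 4-camera ring at 12 Hz with 1 px keypoint noise,
referenced against a 100 Hz system with 1° angle noise, five repetitions.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cameras import CameraModel, make_camera_ring
from .errors import SchemaError
from .series import Task
from .synthetic import MotionProfile, NoiseModel, SkeletonParams

__all__ = ["SimulationConfig", "load_config", "save_config"]


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class SimulationConfig:
    """Validated parameters of one synthetic paired session."""

    task: Task = Task.SIDE_DIP_LEFT
    seed: int = 42
    repetitions: int = 5
    peak_deg: float = 40.0
    duration_s: float = 5.0
    rate_hz: float = 12.0
    hold_fraction: float = 0.2
    reference_rate_hz: float = 100.0
    reference_noise_sigma_deg: float = 1.0
    reference_offset_deg: float = 0.0
    pixel_sigma_px: float = 1.0
    skeleton: SkeletonParams = field(default_factory=SkeletonParams)
    n_cameras: int = 4
    radius_m: float = 3.0
    height_m: float = 1.2
    focal_px: float = 1000.0
    image_size_px: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.seed = int(self.seed)
        self.repetitions = int(self.repetitions)
        if self.repetitions < 1:
            raise SchemaError("repetitions must be >= 1")
        if self.reference_rate_hz <= 0:
            raise SchemaError("reference rate_hz must be > 0")

    # ---- factories for the pipeline objects -------------------------------
    def motion_profile(self) -> MotionProfile:
        return MotionProfile(
            task=self.task,
            peak_deg=self.peak_deg,
            duration_s=self.duration_s,
            rate_hz=self.rate_hz,
            hold_fraction=self.hold_fraction,
        )

    def skeleton_params(self) -> SkeletonParams:
        return self.skeleton

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            pixel_sigma_px=self.pixel_sigma_px,
            ref_sigma_deg=self.reference_noise_sigma_deg,
            ref_offset_deg=self.reference_offset_deg,
            seed=self.seed,
        )

    def camera_ring(self) -> list[CameraModel]:
        return make_camera_ring(
            n_cameras=self.n_cameras,
            radius_m=self.radius_m,
            height_m=self.height_m,
            focal_px=self.focal_px,
            image_size_px=self.image_size_px,
            target=self.skeleton.root_m,
        )

    # ---- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        if not isinstance(data, dict):
            raise SchemaError("config must be a mapping")
        _check_keys(
            data,
            {"task", "seed", "repetitions", "profile", "reference", "skeleton", "rig", "noise"},
            "config",
        )
        if "seed" not in data:
            raise SchemaError("config is missing required key 'seed'")
        kwargs: dict = {"seed": data["seed"]}
        if "task" in data:
            kwargs["task"] = data["task"]
        if "repetitions" in data:
            kwargs["repetitions"] = data["repetitions"]

        profile = dict(data.get("profile", {}))
        _check_keys(profile, {"peak_deg", "duration_s", "rate_hz", "hold_fraction"}, "profile")
        kwargs.update(profile)

        ref = dict(data.get("reference", {}))
        _check_keys(ref, {"rate_hz", "noise_sigma_deg", "offset_deg"}, "reference")
        if "rate_hz" in ref:
            kwargs["reference_rate_hz"] = ref["rate_hz"]
        if "noise_sigma_deg" in ref:
            kwargs["reference_noise_sigma_deg"] = ref["noise_sigma_deg"]
        if "offset_deg" in ref:
            kwargs["reference_offset_deg"] = ref["offset_deg"]

        skel = dict(data.get("skeleton", {}))
        _check_keys(
            skel,
            {
                "torso_length_m",
                "shoulder_half_width_m",
                "hip_half_width_m",
                "femur_length_m",
                "tibia_length_m",
                "root_m",
            },
            "skeleton",
        )
        if "root_m" in skel:
            skel["root_m"] = tuple(skel["root_m"])
        kwargs["skeleton"] = SkeletonParams(**skel)

        rig = dict(data.get("rig", {}))
        _check_keys(rig, {"n_cameras", "radius_m", "height_m", "focal_px", "image_size_px"}, "rig")
        if "image_size_px" in rig:
            rig["image_size_px"] = tuple(rig["image_size_px"])
        kwargs.update(rig)

        noise = dict(data.get("noise", {}))
        _check_keys(noise, {"pixel_sigma_px"}, "noise")
        kwargs.update(noise)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "task": self.task.value,
            "seed": self.seed,
            "repetitions": self.repetitions,
            "profile": {
                "peak_deg": self.peak_deg,
                "duration_s": self.duration_s,
                "rate_hz": self.rate_hz,
                "hold_fraction": self.hold_fraction,
            },
            "reference": {
                "rate_hz": self.reference_rate_hz,
                "noise_sigma_deg": self.reference_noise_sigma_deg,
                "offset_deg": self.reference_offset_deg,
            },
            "skeleton": {
                "torso_length_m": self.skeleton.torso_length_m,
                "shoulder_half_width_m": self.skeleton.shoulder_half_width_m,
                "hip_half_width_m": self.skeleton.hip_half_width_m,
                "femur_length_m": self.skeleton.femur_length_m,
                "tibia_length_m": self.skeleton.tibia_length_m,
                "root_m": list(self.skeleton.root_m),
            },
            "rig": {
                "n_cameras": self.n_cameras,
                "radius_m": self.radius_m,
                "height_m": self.height_m,
                "focal_px": self.focal_px,
                "image_size_px": list(self.image_size_px),
            },
            "noise": {"pixel_sigma_px": self.pixel_sigma_px},
        }

    def digest(self) -> str:
        """Stable hash of the config, recorded in output manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
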