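"""Core time-series containers shared across the pipeline.

Three containers travel through the pipeline:

* :class:`KeypointSeries2D` — what one camera saw: named 2D keypoints in
  pixels, frame by frame.  ``NaN`` marks a missing observation (keypoint
  outside the image, or behind the camera).
* :class:`Skeleton3DSeries` — triangulated named 3D keypoints in world
  coordinates (meters), with per-point reprojection residuals.
* :class:`AngleTrace` — a sampled joint-angle signal in degrees, tagged with
  its task and sign convention.

All containers store data as plain numpy arrays; pandas enters only at the
file-format boundary (:mod:`mvkin.io`).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Task",
    "SignConvention",
    "KeypointSeries2D",
    "Skeleton3DSeries",
    "AngleTrace",
]


class Task(str, enum.Enum):
    """Movement task analysed by the pipeline."""

    SIDE_DIP_LEFT = "side_dip_left"
    SIDE_DIP_RIGHT = "side_dip_right"
    YBT_HIP_EXTENSION = "ybt_hip_extension"

    @property
    def is_side_dip(self) -> bool:
        return self in (Task.SIDE_DIP_LEFT, Task.SIDE_DIP_RIGHT)

    @property
    def family(self) -> str:
        """Task family ignoring side (side dips pair across systems)."""
        return "side_dip" if self.is_side_dip else "ybt"


class SignConvention(str, enum.Enum):
    """How an angle trace encodes direction.

    ``UNSIGNED``: magnitudes in [0, 180] (hip/knee angles).
    ``LEFT_POSITIVE``: trunk side-bending, positive toward the subject's
    left.  ``RIGHT_POSITIVE`` is the mirrored convention some reference
    systems export; :func:`mvkin.alignment.harmonize_signs` negates it.
    """

    UNSIGNED = "unsigned_0_180"
    LEFT_POSITIVE = "left_positive"
    RIGHT_POSITIVE = "right_positive"

    @property
    def is_signed(self) -> bool:
        return self is not SignConvention.UNSIGNED


def _as_float_array(values, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ConfigurationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class KeypointSeries2D:
    """Per-camera time series of named 2D keypoints in pixels.

    ``coords`` has shape (n_frames, n_keypoints, 2); missing observations
    are NaN in both coordinates.
    """

    camera: str
    keypoints: tuple[str, ...]
    coords: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.keypoints = tuple(self.keypoints)
        self.coords = _as_float_array(self.coords, 3, "coords")
        if self.coords.shape[1:] != (len(self.keypoints), 2):
            raise ConfigurationError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.keypoints)} keypoints"
            )
        if not self.rate_hz > 0:
            raise ConfigurationError("rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    def missing_mask(self) -> np.ndarray:
        """(n_frames, n_keypoints) boolean mask of missing observations."""
        return np.isnan(self.coords).any(axis=2)


@dataclass
class Skeleton3DSeries:
    """Time series of named 3D keypoints in world coordinates (meters).

    ``positions`` has shape (n_frames, n_keypoints, 3) with NaN rows for
    keypoints that could not be reconstructed; ``residual_px`` carries the
    RMS reprojection residual of each reconstructed point.
    """

    keypoints: tuple[str, ...]
    positions: np.ndarray
    rate_hz: float
    residual_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.keypoints = tuple(self.keypoints)
        self.positions = _as_float_array(self.positions, 3, "positions")
        if self.positions.shape[1:] != (len(self.keypoints), 3):
            raise ConfigurationError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.keypoints)} keypoints"
            )
        if not self.rate_hz > 0:
            raise ConfigurationError("rate_hz must be > 0")
        if self.residual_px is not None:
            self.residual_px = _as_float_array(self.residual_px, 2, "residual_px")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    def get(self, keypoint: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one keypoint."""
        return self.positions[:, self.keypoints.index(keypoint), :]

    def has(self, *names: str) -> tuple[str, ...]:
        """Return the subset of ``names`` absent from this series."""
        return tuple(n for n in names if n not in self.keypoints)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Skeleton3DSeries":
        """Apply the rigid map x -> R x + t to every keypoint."""
        pos = self.positions @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return replace(self, positions=pos)


@dataclass
class AngleTrace:
    """A sampled joint-angle signal in degrees.

    ``values`` may contain NaN for frames where the angle could not be
    computed; the temporal-alignment stage bridges interior gaps.  Angle
    operations guarantee unsigned values in [0, 180] and signed values in
    [-180, 180]; synthetic reference traces carry additive noise and may
    exceed those bands marginally, so the bands are not enforced here.
    """

    values: np.ndarray
    rate_hz: float
    task: Task | None = None
    convention: SignConvention = SignConvention.UNSIGNED
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ConfigurationError("AngleTrace values must be one-dimensional")
        if not self.rate_hz > 0:
            raise ConfigurationError("rate_hz must be > 0")
        if self.task is not None:
            self.task = Task(self.task)
        self.convention = SignConvention(self.convention)
        self.meta = dict(self.meta)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz

    def negated(self, convention: SignConvention | None = None) -> "AngleTrace":
        return replace(
            self,
            values=-self.values,
            convention=convention if convention is not None else self.convention,
        )

    def with_values(self, values: np.ndarray, rate_hz: float | None = None) -> "AngleTrace":
        return replace(self, values=values, rate_hz=rate_hz if rate_hz else self.rate_hz)
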