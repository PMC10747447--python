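"""Anatomical joint angles from 3D keypoints.

The measurement model uses a small set of body keypoints (neck, shoulders,
hips, knee, ankle) rather than a full marker protocol.  Three scalar angles
are reported:

* **Hip flexion/extension** — the angle between the downward axis of a torso
  coordinate frame and the femur (hip→knee) vector.  Defined in 3D,
  irrespective of the plane the thigh moves in: 0° in the anatomically
  neutral standing pose, rising to 180° with the femur antiparallel to
  neutral.  Hip *extension* (leg behind the body, as in a posterior reach)
  uses the same unsigned formula; task metadata distinguishes it.
* **Knee flexion** — the angle between the femur (hip→knee) and tibia
  (knee→ankle) axes; 0° when fully extended.
* **Trunk side-bending** — the signed elevation of the line joining the two
  shoulders relative to the floor plane Z = 0; positive when the subject
  bends to their left (left shoulder lower).

The torso frame follows the convention: Z points from the reference hip
joint to the neck; X is the normal of the plane through the two shoulders
and that hip (re-orthogonalized against Z so the frame is orthonormal to
machine precision); Y = Z x X completes a right-handed triad.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFrameError, MissingKeypointError, ConfigurationError
from .series import AngleTrace, SignConvention, Skeleton3DSeries, Task

__all__ = [
    "TorsoFrame",
    "torso_frame",
    "hip_flexion_angle",
    "knee_flexion_angle",
    "trunk_side_bend_angle",
    "angle_trace_from_skeleton",
    "required_keypoints",
]

_EPS = 1e-12


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateFrameError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class TorsoFrame:
    """Right-handed orthonormal torso coordinate frame.

    origin: the hip joint used to anchor the frame.
    z_axis: unit vector hip -> neck.
    x_axis: unit normal of the shoulder-shoulder-hip plane (orthogonal to z).
    y_axis: z x x.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


def torso_frame(neck, shoulder_l, shoulder_r, hip) -> TorsoFrame:
    """Build the torso coordinate frame from four keypoints.

    Z is the unit vector from ``hip`` to ``neck``; X is the unit normal of
    the plane through ``shoulder_l``, ``shoulder_r`` and ``hip`` (cross
    product of the two hip→shoulder vectors, left first), projected
    orthogonal to Z; Y = Z x X.

    Raises
    ------
    DegenerateFrameError
        If the points are coincident or collinear (no unique plane/axis).
    """
    neck = np.asarray(neck, float)
    shoulder_l = np.asarray(shoulder_l, float)
    shoulder_r = np.asarray(shoulder_r, float)
    hip = np.asarray(hip, float)

    z = _unit(neck - hip, "hip->neck axis")
    normal = np.cross(shoulder_l - hip, shoulder_r - hip)
    if np.linalg.norm(normal) < _EPS:
        raise DegenerateFrameError("shoulders and hip are collinear; torso plane undefined")
    x = normal - (normal @ z) * z  # enforce orthogonality to Z
    if np.linalg.norm(x) < _EPS:
        raise DegenerateFrameError("torso plane normal is parallel to the hip->neck axis")
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return TorsoFrame(origin=hip, x_axis=x, y_axis=y, z_axis=z)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle in degrees between two unit vectors.

    Mathematically arccos of the clamped dot product; evaluated as
    atan2(|u x v|, u.v), which is identical on [0, 180] but keeps full
    floating-point precision near 0 and 180 where arccos degrades.
    """
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    s = float(np.linalg.norm(np.cross(u, v)))
    return float(np.degrees(np.arctan2(s, c)))


def hip_flexion_angle(frame: TorsoFrame, hip, knee) -> float:
    """Hip flexion/extension angle in degrees, unsigned [0, 180].

    The angle between the negative torso Z axis and the femur (hip→knee)
    vector.  0° is the anatomically neutral posture (femur along -Z);
    raising the leg in any plane increases the angle toward 180°.
    """
    femur = _unit(np.asarray(knee, float) - np.asarray(hip, float), "femur axis")
    return _angle_between(-frame.z_axis, femur)


def knee_flexion_angle(hip, knee, ankle) -> float:
    """Knee flexion angle in degrees, unsigned [0, 180]; 0° = fully extended."""
    femur = _unit(np.asarray(knee, float) - np.asarray(hip, float), "femur axis")
    tibia = _unit(np.asarray(ankle, float) - np.asarray(knee, float), "tibia axis")
    return _angle_between(femur, tibia)


def trunk_side_bend_angle(shoulder_l, shoulder_r) -> float:
    """Signed trunk side-bending angle in degrees (left positive).

    The elevation of the shoulder line (right shoulder → left shoulder)
    relative to the floor plane Z = 0: arctangent of the vertical drop of
    the left shoulder over the horizontal extent of the line.  Positive
    when the left shoulder is lower than the right (a bend to the subject's
    left), negative when higher.
    """
    d = np.asarray(shoulder_l, float) - np.asarray(shoulder_r, float)
    horizontal = float(np.hypot(d[0], d[1]))
    if horizontal < _EPS:
        raise DegenerateFrameError("shoulder line is vertical; side-bend angle undefined")
    drop = -float(d[2])  # positive when shoulder_l is lower
    return float(np.degrees(np.arctan2(drop, horizontal)))


def required_keypoints(task: Task) -> tuple[str, ...]:
    """Keypoints a skeleton series must provide for the given task."""
    task = Task(task)
    if task.is_side_dip:
        return ("shoulder_L", "shoulder_R")
    return ("neck", "shoulder_L", "shoulder_R", "hip_R", "knee_R", "ankle_R")


def angle_trace_from_skeleton(skel: Skeleton3DSeries, task: Task) -> AngleTrace:
    """Per-frame task angle from a 3D keypoint series.

    Side dips yield the signed trunk side-bending angle (left positive);
    the Y-balance reach yields the unsigned hip flexion/extension angle of
    the right (moving) leg.  Frames with missing or degenerate required
    keypoints yield NaN samples; a keypoint absent from the series
    altogether raises :class:`MissingKeypointError`.
    """
    task = Task(task)
    needed = required_keypoints(task)
    absent = skel.has(*needed)
    if absent:
        raise MissingKeypointError(absent, task=task)

    n = skel.n_frames
    values = np.full(n, np.nan)
    if task.is_side_dip:
        sl, sr = skel.get("shoulder_L"), skel.get("shoulder_R")
        for i in range(n):
            if np.isnan(sl[i]).any() or np.isnan(sr[i]).any():
                continue
            try:
                values[i] = trunk_side_bend_angle(sl[i], sr[i])
            except DegenerateFrameError:
                continue
        convention = SignConvention.LEFT_POSITIVE
    elif task is Task.YBT_HIP_EXTENSION:
        neck = skel.get("neck")
        sl, sr = skel.get("shoulder_L"), skel.get("shoulder_R")
        hip, knee = skel.get("hip_R"), skel.get("knee_R")
        for i in range(n):
            pts = (neck[i], sl[i], sr[i], hip[i], knee[i])
            if any(np.isnan(p).any() for p in pts):
                continue
            try:
                frame = torso_frame(neck[i], sl[i], sr[i], hip[i])
                values[i] = hip_flexion_angle(frame, hip[i], knee[i])
            except DegenerateFrameError:
                continue
        convention = SignConvention.UNSIGNED
    else:  # pragma: no cover - Task() above rejects unknown strings
        raise ConfigurationError(f"unknown task {task}")

    return AngleTrace(
        values=values,
        rate_hz=skel.rate_hz,
        task=task,
        convention=convention,
        meta={"source": "skeleton3d"},
    )
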