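"""Pinhole camera model, projection, and ring-rig construction.

Conventions
-----------
World frame: right-handed, Z up, meters; the floor is the plane Z = 0.
Camera frame: x right, y down, z forward (points in front of the camera
have positive z).  ``rotation`` maps world to camera coordinates and
``translation`` is expressed in the camera frame, so a world point X
projects through ``K @ [R | t]``.  Pixel origin is the top-left corner,
x right, y down.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["CameraModel", "make_camera_ring"]

_ORTHONORMALITY_TOL = 1e-9


@dataclass
class CameraModel:
    """Intrinsic and extrinsic parameters of one pinhole camera.

    Parameters
    ----------
    name:
        Identifier used to match keypoint files to rig entries.
    focal_px:
        Focal lengths (fx, fy) in pixels.
    principal_point_px:
        Principal point (cx, cy) in pixels; must lie inside the image.
    image_size_px:
        Image (width, height) in pixels.
    rotation:
        3x3 orthonormal world-to-camera rotation (det +1, checked to 1e-9).
    translation:
        Camera-frame translation t such that x_cam = R x_world + t.
    distortion:
        Hook for radial/tangential coefficients; must currently be empty
        (no distortion model is applied).
    """

    name: str
    focal_px: tuple[float, float]
    principal_point_px: tuple[float, float]
    image_size_px: tuple[int, int]
    rotation: np.ndarray
    translation: np.ndarray
    distortion: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.focal_px = (float(self.focal_px[0]), float(self.focal_px[1]))
        self.principal_point_px = (
            float(self.principal_point_px[0]),
            float(self.principal_point_px[1]),
        )
        self.image_size_px = (int(self.image_size_px[0]), int(self.image_size_px[1]))
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.distortion = tuple(float(d) for d in self.distortion)

        if self.focal_px[0] <= 0 or self.focal_px[1] <= 0:
            raise ConfigurationError(f"camera {self.name!r}: focal length must be positive")
        w, h = self.image_size_px
        cx, cy = self.principal_point_px
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ConfigurationError(
                f"camera {self.name!r}: principal point ({cx}, {cy}) outside image {w}x{h}"
            )
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHONORMALITY_TOL):
            raise ConfigurationError(f"camera {self.name!r}: rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ConfigurationError(
                f"camera {self.name!r}: rotation determinant is {np.linalg.det(R):.6f}, "
                "expected +1 (improper rotation)"
            )
        if self.distortion:
            raise ConfigurationError("lens distortion is not implemented; coefficients must be empty")

    @property
    def intrinsics(self) -> np.ndarray:
        """3x3 intrinsic matrix K."""
        fx, fy = self.focal_px
        cx, cy = self.principal_point_px
        return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates, C = -R^T t."""
        return -self.rotation.T @ self.translation

    def projection_matrix(self) -> np.ndarray:
        """3x4 projection matrix P = K [R | t]."""
        return self.intrinsics @ np.hstack([self.rotation, self.translation[:, None]])

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points to pixels.

        Parameters
        ----------
        points:
            (..., 3) world coordinates.

        Returns
        -------
        pixels:
            (..., 2) pixel coordinates; NaN where the point is invalid.
        valid:
            Boolean mask; False where the point is behind the camera, at the
            optical center, or projects outside the image bounds.
        """
        pts = np.asarray(points, dtype=float)
        cam = pts @ self.rotation.T + self.translation
        z = cam[..., 2]
        in_front = z > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.focal_px[0] * cam[..., 0] / z + self.principal_point_px[0]
            v = self.focal_px[1] * cam[..., 1] / z + self.principal_point_px[1]
        pix = np.stack([u, v], axis=-1)
        w, h = self.image_size_px
        in_bounds = (u >= 0) & (u <= w) & (v >= 0) & (v <= h)
        valid = in_front & in_bounds & np.isfinite(u) & np.isfinite(v)
        pix[~valid] = np.nan
        return pix, valid

    def normalized_coords(self, pixel: np.ndarray) -> np.ndarray:
        """Map pixels to normalized image coordinates (K^-1 applied)."""
        px = np.asarray(pixel, dtype=float)
        return np.stack(
            [
                (px[..., 0] - self.principal_point_px[0]) / self.focal_px[0],
                (px[..., 1] - self.principal_point_px[1]) / self.focal_px[1],
            ],
            axis=-1,
        )


def _look_at_rotation(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation for a camera at ``center`` looking at ``target``.

    The camera's x axis is horizontal (parallel to the floor), y points
    broadly downward, z is the optical axis toward the target.
    """
    forward = target - center
    norm = np.linalg.norm(forward)
    if norm < 1e-12:
        raise ConfigurationError("camera center coincides with the look-at target")
    forward = forward / norm
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    rnorm = np.linalg.norm(right)
    if rnorm < 1e-12:
        # looking straight up/down: pick an arbitrary horizontal right axis
        right = np.array([1.0, 0.0, 0.0])
    else:
        right = right / rnorm
    down = np.cross(forward, right)
    return np.vstack([right, down, forward])


def make_camera_ring(
    n_cameras: int = 4,
    radius_m: float = 3.0,
    height_m: float = 1.2,
    focal_px: float = 1000.0,
    image_size_px: tuple[int, int] = (1920, 1080),
    target: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 1.0),
    name_prefix: str = "cam",
) -> list[CameraModel]:
    """Evenly spaced ring of cameras, all aimed at one target point.

    Emulates a multi-view capture rig surrounding the subject: ``n_cameras``
    cameras on a horizontal circle of ``radius_m`` at ``height_m``, each
    oriented at ``target`` (typically the skeleton root).  At least two
    cameras are required for triangulation.
    """
    if n_cameras < 2:
        raise ConfigurationError(
            f"need at least 2 cameras for triangulation, got {n_cameras}"
        )
    if radius_m <= 0:
        raise ConfigurationError("radius_m must be > 0")
    target = np.asarray(target, dtype=float).reshape(3)
    w, h = image_size_px
    cameras = []
    for i in range(n_cameras):
        phi = 2.0 * np.pi * i / n_cameras
        center = np.array(
            [target[0] + radius_m * np.cos(phi), target[1] + radius_m * np.sin(phi), height_m]
        )
        R = _look_at_rotation(center, target)
        t = -R @ center
        cameras.append(
            CameraModel(
                name=f"{name_prefix}{i}",
                focal_px=(focal_px, focal_px),
                principal_point_px=(w / 2.0, h / 2.0),
                image_size_px=(w, h),
                rotation=R,
                translation=t,
            )
        )
    return cameras
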