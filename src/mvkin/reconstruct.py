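"""Linear multi-view triangulation of 2D keypoints to 3D.

Each calibrated view contributes two rows of the direct-linear-transform
(DLT) constraint; the stacked homogeneous system is solved by singular
value decomposition.  For conditioning, pixel observations are first mapped
to normalized image coordinates (the intrinsic matrix inverted per view)
and the DLT rows are built from the pose-only projection ``[R | t]`` and
scaled to unit norm, which plays the role of the usual center-and-scale
normalization when the calibration is known exactly.

No lens distortion is modeled and no bundle adjustment is performed;
cameras are inputs, not estimated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cameras import CameraModel
from .errors import AlignmentError, InsufficientViewsError
from .series import KeypointSeries2D, Skeleton3DSeries

__all__ = ["TriangulatedPoint", "projection_matrix", "triangulate_point", "triangulate_series"]

log = logging.getLogger(__name__)

# Ratio of the two smallest singular values above which the solution is
# considered ambiguous (near-parallel viewing rays).
DEGENERACY_RATIO = 0.9


def projection_matrix(camera: CameraModel) -> np.ndarray:
    """3x4 pinhole projection matrix K [R | t] of a validated camera."""
    return camera.projection_matrix()


@dataclass(frozen=True)
class TriangulatedPoint:
    """One reconstructed 3D point with its fit diagnostics."""

    point: np.ndarray  # (3,) world coordinates, meters
    residual_px: float  # RMS reprojection residual over contributing views
    n_views: int
    degenerate: bool  # True when the ray geometry is near-ambiguous


def triangulate_point(
    observations: list[tuple[CameraModel, np.ndarray]],
) -> TriangulatedPoint:
    """Triangulate one 3D point from >= 2 pixel observations.

    Parameters
    ----------
    observations:
        ``(camera, (u, v))`` pairs; cameras must have distinct centers.

    Returns
    -------
    TriangulatedPoint
        Dehomogenized SVD solution with its RMS reprojection residual in
        pixels.  Near-parallel ray geometry does not raise; the point is
        returned with ``degenerate=True``.
    """
    obs = [(c, np.asarray(p, float).reshape(2)) for c, p in observations]
    obs = [(c, p) for c, p in obs if np.isfinite(p).all()]
    if len(obs) < 2:
        raise InsufficientViewsError(
            f"triangulation needs >= 2 observations, got {len(obs)}"
        )
    centers = np.array([c.center for c, _ in obs])
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    if np.any(dists[np.triu_indices(len(obs), k=1)] < 1e-9):
        raise InsufficientViewsError("observations come from cameras with coincident centers")

    rows = []
    for cam, pix in obs:
        x, y = cam.normalized_coords(pix)
        M = np.hstack([cam.rotation, cam.translation[:, None]])  # pose-only projection
        rows.append(x * M[2] - M[0])
        rows.append(y * M[2] - M[1])
    A = np.array(rows)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(A)
    X = vt[-1]
    degenerate = bool(s.size >= 2 and s[-2] > 0 and s[-1] / s[-2] > DEGENERACY_RATIO)
    if abs(X[3]) < 1e-15:
        # point at infinity; report as degenerate with unnormalizable coords
        return TriangulatedPoint(np.full(3, np.nan), np.inf, len(obs), True)
    point = X[:3] / X[3]

    sq = 0.0
    for cam, pix in obs:
        proj, _ = cam.project(point)
        sq += float(np.sum((proj - pix) ** 2)) if np.isfinite(proj).all() else np.inf
    residual = float(np.sqrt(sq / len(obs)))
    return TriangulatedPoint(point, residual, len(obs), degenerate)


def triangulate_series(
    rig: list[CameraModel],
    views: list[KeypointSeries2D],
    min_views: int = 2,
) -> Skeleton3DSeries:
    """Triangulate a full keypoint series frame by frame.

    Keypoints observed by at least ``min_views`` cameras in a frame are
    reconstructed; the rest are marked missing (NaN).  All views must share
    the same frame grid (count and rate) and the same keypoint set, and
    each view's camera name must appear in the rig.
    """
    if min_views < 2:
        raise ValueError("min_views must be >= 2")
    if not views:
        raise AlignmentError("no views supplied")
    by_name = {c.name: c for c in rig}
    missing_cams = [v.camera for v in views if v.camera not in by_name]
    if missing_cams:
        raise AlignmentError(f"views reference cameras not in the rig: {missing_cams}")

    first = views[0]
    for v in views[1:]:
        if v.n_frames != first.n_frames or not np.isclose(v.rate_hz, first.rate_hz):
            raise AlignmentError(
                f"view {v.camera!r} frame grid ({v.n_frames} @ {v.rate_hz} Hz) does not "
                f"match {first.camera!r} ({first.n_frames} @ {first.rate_hz} Hz)"
            )
        if v.keypoints != first.keypoints:
            raise AlignmentError(f"view {v.camera!r} has a different keypoint set")

    names = first.keypoints
    n_frames, n_kp = first.n_frames, len(names)
    positions = np.full((n_frames, n_kp, 3), np.nan)
    residuals = np.full((n_frames, n_kp), np.nan)
    n_degenerate = n_missing = 0

    for f in range(n_frames):
        for k in range(n_kp):
            observations = [
                (by_name[v.camera], v.coords[f, k])
                for v in views
                if np.isfinite(v.coords[f, k]).all()
            ]
            if len(observations) < min_views:
                n_missing += 1
                continue
            tri = triangulate_point(observations)
            positions[f, k] = tri.point
            residuals[f, k] = tri.residual_px
            n_degenerate += tri.degenerate

    mean_res = float(np.nanmean(residuals)) if np.isfinite(residuals).any() else float("nan")
    log.info(
        "triangulated %d frames x %d keypoints: %d missing, %d degenerate, "
        "mean residual %.3g px",
        n_frames, n_kp, n_missing, n_degenerate, mean_res,
    )
    return Skeleton3DSeries(
        keypoints=names, positions=positions, rate_hz=first.rate_hz, residual_px=residuals
    )
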