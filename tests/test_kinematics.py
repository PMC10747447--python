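"""Joint-angle operations: conventions, endpoints, invariances."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvkin import (
    MotionProfile,
    SkeletonParams,
    Task,
    angle_trace_from_skeleton,
    forward_kinematics,
    generate_angle_profile,
    hip_flexion_angle,
    knee_flexion_angle,
    torso_frame,
    trunk_side_bend_angle,
)
from mvkin.errors import DegenerateFrameError, MissingKeypointError
from mvkin.series import Skeleton3DSeries


def _upright_frame():
    """Symmetric upright pose: hip at the origin, neck 0.5 m above."""
    return torso_frame(
        neck=(0, 0, 0.5), shoulder_l=(0.2, 0, 0.45), shoulder_r=(-0.2, 0, 0.45), hip=(0, 0, 0)
    )


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestTorsoFrame:
    def test_symmetric_upright_pose_gives_canonical_axes(self):
        fr = torso_frame((0, 0, 1), (0.2, 0, 0.9), (-0.2, 0, 0.9), (0, 0, 0))
        np.testing.assert_allclose(fr.z_axis, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(fr.x_axis, [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.y_axis, [1, 0, 0], atol=1e-12)

    def test_orthonormal_right_handed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            try:
                fr = torso_frame(*pts)
            except DegenerateFrameError:
                continue
            basis = np.array([fr.x_axis, fr.y_axis, fr.z_axis])
            np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-9)
            assert np.dot(np.cross(fr.x_axis, fr.y_axis), fr.z_axis) == pytest.approx(1.0, abs=1e-9)

    def test_rotating_all_points_rotates_the_axes(self):
        rng = np.random.default_rng(1)
        q = _random_rotation(rng)
        pts = [(0, 0, 1), (0.2, 0.05, 0.9), (-0.2, -0.02, 0.88), (0.01, 0, 0)]
        fr = torso_frame(*pts)
        fr_rot = torso_frame(*[q @ np.asarray(p, float) for p in pts])
        for axis in ("x_axis", "y_axis", "z_axis"):
            np.testing.assert_allclose(getattr(fr_rot, axis), q @ getattr(fr, axis), atol=1e-9)

    def test_coincident_neck_and_hip_rejected(self):
        with pytest.raises(DegenerateFrameError):
            torso_frame((0, 0, 0), (0.2, 0, 0), (-0.2, 0, 0), (0, 0, 0))


class TestHipFlexion:
    @pytest.mark.parametrize(
        "knee, expected",
        [
            ((0, 0, -0.45), 0.0),     # femur straight down: neutral stance
            ((0, 0, 0.45), 180.0),    # femur straight up: fully raised
            ((0.45, 0, 0), 90.0),     # femur horizontal
            ((0, -0.45, 0), 90.0),    # horizontal in another plane: plane-agnostic
        ],
    )
    def test_endpoint_and_orthogonal_poses(self, knee, expected):
        assert hip_flexion_angle(_upright_frame(), (0, 0, 0), knee) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_length_femur_rejected(self):
        with pytest.raises(DegenerateFrameError):
            hip_flexion_angle(_upright_frame(), (0, 0, 0), (0, 0, 0))


class TestKneeFlexion:
    @pytest.mark.parametrize(
        "ankle, expected",
        [
            ((0, 0, -0.9), 0.0),        # collinear: fully extended
            ((0, 0.45, -0.45), 90.0),   # right angle
            ((0, 0, 0.0), 180.0),       # folded back onto the femur
        ],
    )
    def test_reference_angles(self, ankle, expected):
        assert knee_flexion_angle((0, 0, 0), (0, 0, -0.45), ankle) == pytest.approx(
            expected, abs=1e-9
        )

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateFrameError):
            knee_flexion_angle((0, 0, 0), (0, 0, 0), (0, 0, -0.4))


class TestTrunkSideBend:
    def test_level_shoulders_give_zero(self):
        assert trunk_side_bend_angle((0.2, 0, 1.4), (-0.2, 0, 1.4)) == pytest.approx(0.0)

    def test_left_shoulder_lower_is_positive_thirty(self):
        # drop 0.1 m over 0.1732 m horizontal extent: atan(0.1/0.1732) = 30 deg
        left = (0.1732 / 2, 0, 1.4 - 0.05)
        right = (-0.1732 / 2, 0, 1.4 + 0.05)
        assert trunk_side_bend_angle(left, right) == pytest.approx(30.0, abs=1e-3)

    def test_mirror_image_negates(self):
        left = (0.1732 / 2, 0, 1.35)
        right = (-0.1732 / 2, 0, 1.45)
        mirrored = trunk_side_bend_angle((left[0], 0, 1.45), (right[0], 0, 1.35))
        assert mirrored == pytest.approx(-trunk_side_bend_angle(left, right))

    def test_vertical_shoulder_line_rejected(self):
        with pytest.raises(DegenerateFrameError):
            trunk_side_bend_angle((0, 0, 1.5), (0, 0, 1.3))


def _skeleton_for(task: Task, peak=30.0):
    profile = MotionProfile(task=task, peak_deg=peak, duration_s=2.0)
    trace = generate_angle_profile(profile)
    return trace, forward_kinematics(SkeletonParams(), trace, task)


class TestAngleTraceFromSkeleton:
    def test_noiseless_side_dip_recovers_ground_truth(self):
        trace, skel = _skeleton_for(Task.SIDE_DIP_LEFT)
        out = angle_trace_from_skeleton(skel, Task.SIDE_DIP_LEFT)
        np.testing.assert_allclose(out.values, trace.values, atol=1e-9)

    def test_frame_with_missing_required_keypoint_yields_nan_sample(self):
        _, skel = _skeleton_for(Task.YBT_HIP_EXTENSION)
        skel.positions[3, skel.keypoints.index("knee_R")] = np.nan
        out = angle_trace_from_skeleton(skel, Task.YBT_HIP_EXTENSION)
        assert np.isnan(out.values[3])
        assert np.isfinite(out.values[[0, 1, 2, 4]]).all()

    def test_skeleton_without_ankle_rejected_for_ybt(self):
        _, skel = _skeleton_for(Task.YBT_HIP_EXTENSION)
        keep = [i for i, n in enumerate(skel.keypoints) if n != "ankle_R"]
        reduced = Skeleton3DSeries(
            keypoints=tuple(skel.keypoints[i] for i in keep),
            positions=skel.positions[:, keep],
            rate_hz=skel.rate_hz,
        )
        with pytest.raises(MissingKeypointError, match="ankle_R"):
            angle_trace_from_skeleton(reduced, Task.YBT_HIP_EXTENSION)


@st.composite
def rigid_transforms(draw):
    seed = draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    return _random_rotation(rng), rng.normal(scale=2.0, size=3)


class TestInvariances:
    """Angles depend only on the skeleton's shape, never on where it sits,
    how it is oriented, or its overall size."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rigid_transforms(), st.sampled_from([Task.SIDE_DIP_LEFT, Task.YBT_HIP_EXTENSION]))
    def test_rigid_motion_leaves_unsigned_angles_unchanged(self, transform, task):
        q, d = transform
        trace, skel = _skeleton_for(task)
        moved = skel.transformed(q, d)
        if task is Task.SIDE_DIP_LEFT:
            # side-bend references the world floor plane, so compare the
            # floor-independent hip/knee angles instead
            task = Task.YBT_HIP_EXTENSION
            trace, skel = _skeleton_for(task)
            moved = skel.transformed(q, d)
        before = angle_trace_from_skeleton(skel, task)
        after = angle_trace_from_skeleton(moved, task)
        np.testing.assert_allclose(after.values, before.values, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_uniform_scaling_leaves_all_angles_unchanged(self, scale):
        for task in (Task.SIDE_DIP_LEFT, Task.YBT_HIP_EXTENSION):
            trace, skel = _skeleton_for(task)
            scaled = Skeleton3DSeries(
                keypoints=skel.keypoints, positions=skel.positions * scale, rate_hz=skel.rate_hz
            )
            before = angle_trace_from_skeleton(skel, task)
            after = angle_trace_from_skeleton(scaled, task)
            np.testing.assert_allclose(after.values, before.values, atol=1e-9)

    def test_sagittal_mirror_negates_side_bend_and_preserves_leg_angles(self):
        """Reflect every keypoint across the sagittal plane (x -> -x) and
        swap the left/right roles: the signed side-bend negates while the
        unsigned hip and knee angles are unchanged."""
        rng = np.random.default_rng(9)
        M = np.diag([-1.0, 1.0, 1.0])
        for _ in range(20):
            neck = rng.normal([0, 0, 1.45], 0.05)
            sl = rng.normal([0.18, 0, 1.4], 0.05)
            sr = rng.normal([-0.18, 0, 1.4], 0.05)
            hip = rng.normal([-0.1, 0, 0.95], 0.05)
            knee = rng.normal([-0.1, -0.2, 0.5], 0.08)
            ankle = rng.normal([-0.1, -0.3, 0.1], 0.08)

            bend = trunk_side_bend_angle(sl, sr)
            # mirrored subject: old right shoulder becomes the new left
            bend_mirror = trunk_side_bend_angle(M @ sr, M @ sl)
            assert bend_mirror == pytest.approx(-bend, abs=1e-9)

            frame = torso_frame(neck, sl, sr, hip)
            frame_mirror = torso_frame(M @ neck, M @ sr, M @ sl, M @ hip)
            hip_angle = hip_flexion_angle(frame, hip, knee)
            hip_mirror = hip_flexion_angle(frame_mirror, M @ hip, M @ knee)
            assert hip_mirror == pytest.approx(hip_angle, abs=1e-9)

            knee_angle = knee_flexion_angle(hip, knee, ankle)
            knee_mirror = knee_flexion_angle(M @ hip, M @ knee, M @ ankle)
            assert knee_mirror == pytest.approx(knee_angle, abs=1e-9)
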