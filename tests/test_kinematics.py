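import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpipe.io import LANDMARKS, KeypointTrajectory
from gaitpipe.kinematics import (
    LEFTWARD,
    RIGHTWARD,
    UNKNOWN,
    DegenerateGeometryError,
    JointAngleSeries,
    ankle_angle,
    camera_facing_side,
    compute_angles,
    hip_angle,
    infer_direction,
    knee_angle,
    smooth_and_fill,
)
from gaitpipe.synthetic import default_templates


def enclosed_angle_oracle(u, v):
    """Independent arctangent oracle: absolute angle between two 2D vectors."""
    a = np.degrees(np.arctan2(u[1], u[0]))
    b = np.degrees(np.arctan2(v[1], v[0]))
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# -- knee -------------------------------------------------------------------


@pytest.mark.parametrize(
    "hip,knee,ankle,expected",
    [
        ((0, 0), (0, 50), (0, 100), 0.0),       # collinear: straight leg
        ((0, 0), (0, 50), (50, 50), 90.0),      # right angle
    ],
)
def test_knee_angle_canonical_poses(hip, knee, ankle, expected):
    assert knee_angle(hip, knee, ankle) == pytest.approx(expected, abs=1e-9)


def test_knee_angle_matches_arctangent_oracle():
    hip, knee, ankle = (0, 0), (0, 50), (30, 90)
    u = np.array(hip) - np.array(knee)
    v = np.array(ankle) - np.array(knee)
    expected = 180.0 - enclosed_angle_oracle(u, v)
    assert knee_angle(hip, knee, ankle) == pytest.approx(expected, abs=1e-9)


def test_knee_angle_rejects_coincident_points():
    with pytest.raises(DegenerateGeometryError):
        knee_angle((0, 0), (0, 0), (1, 1))


# -- hip --------------------------------------------------------------------


def test_hip_angle_neutral_and_sign_convention():
    assert hip_angle((0, 0), (0, 50), (0, 100), RIGHTWARD) == pytest.approx(0.0)
    flexion = hip_angle((0, 0), (0, 50), (20, 95), RIGHTWARD)
    assert flexion > 0
    # same knee position, walking the other way -> extension of equal size
    assert hip_angle((0, 0), (0, 50), (20, 95), LEFTWARD) == pytest.approx(-flexion)


def test_hip_angle_degenerate_trunk():
    with pytest.raises(DegenerateGeometryError):
        hip_angle((0, 50), (0, 50), (0, 100), RIGHTWARD)


# -- ankle ------------------------------------------------------------------


@pytest.mark.parametrize("direction", [RIGHTWARD, LEFTWARD])
def test_ankle_angle_neutral(direction):
    knee, ankle = (0, 0), (0, 150)
    heel = (-direction * 20, 150)
    toe = (direction * 40, 150)
    assert ankle_angle(knee, ankle, heel, toe, direction) == pytest.approx(0.0)


def test_ankle_angle_plantarflexion_sign():
    # foot rotated 20 degrees toes-down (y-down: toe y increases)
    theta = np.radians(20)
    heel = (-20 * np.cos(theta), 150 - 20 * np.sin(theta))
    toe = (40 * np.cos(theta), 150 + 40 * np.sin(theta))
    value = ankle_angle((0, 0), (0, 150), heel, toe, RIGHTWARD)
    assert value == pytest.approx(-20.0, abs=1e-9)


def test_ankle_angle_matches_signed_cross_oracle(rng):
    for _ in range(50):
        knee, ankle, heel, toe = rng.uniform(-100, 100, (4, 2))
        if np.allclose(heel, toe) or np.allclose(knee, ankle):
            continue
        shank, foot = ankle - knee, toe - heel
        enclosed = enclosed_angle_oracle(shank, foot)
        cross = shank[0] * foot[1] - shank[1] * foot[0]
        sign = 1.0 if -cross >= 0 else -1.0  # y-down: toes-up has negative cross
        expected = sign * enclosed - 90.0
        if expected <= -180.0:
            expected += 360.0
        assert ankle_angle(knee, ankle, heel, toe, RIGHTWARD) == pytest.approx(
            expected, abs=1e-9
        )


# -- invariances ------------------------------------------------------------


@settings(max_examples=50, deadline=None)
@given(
    dx=st.floats(-500, 500),
    dy=st.floats(-500, 500),
    scale=st.floats(0.1, 10.0),
)
def test_angles_invariant_to_translation_and_scale(dx, dy, scale):
    shoulder, hip, knee, ankle = (0.0, 0.0), (2.0, 50.0), (20.0, 95.0), (10.0, 140.0)
    heel, toe = (0.0, 150.0), (45.0, 148.0)

    def transform(p):
        return (scale * p[0] + dx, scale * p[1] + dy)

    assert knee_angle(hip, knee, ankle) == pytest.approx(
        knee_angle(*map(transform, (hip, knee, ankle))), abs=1e-8
    )
    assert hip_angle(shoulder, hip, knee, RIGHTWARD) == pytest.approx(
        hip_angle(*map(transform, (shoulder, hip, knee)), RIGHTWARD), abs=1e-8
    )
    assert ankle_angle(knee, ankle, heel, toe, RIGHTWARD) == pytest.approx(
        ankle_angle(*map(transform, (knee, ankle, heel, toe)), RIGHTWARD), abs=1e-8
    )


def test_mirror_invariance_of_full_series(clean_subject):
    # reflecting x flips handedness: left and right landmarks swap labels
    trajectory, _ = clean_subject
    swap = np.array([LANDMARKS.index(n.replace("left", "R").replace("right", "left")
                                     .replace("R", "right")) for n in LANDMARKS])
    mirrored = KeypointTrajectory(
        trajectory.frame_index,
        np.stack([-trajectory.xy[:, swap, 0], trajectory.xy[:, swap, 1]], axis=-1),
        trajectory.confidence[:, swap],
        fps=trajectory.fps,
    )
    a = compute_angles(trajectory)
    b = compute_angles(mirrored)
    np.testing.assert_array_equal(a.frame_index, b.frame_index)
    np.testing.assert_array_equal(a.direction, -b.direction)
    for joint in ("hip", "knee", "ankle"):
        np.testing.assert_allclose(a.joint(joint), b.joint(joint), atol=1e-9)


# -- direction / side -------------------------------------------------------


def _hip_only_trajectory(hip_x):
    n = len(hip_x)
    xy = np.full((n, 12, 2), np.nan)
    for name in ("left_hip", "right_hip"):
        xy[:, LANDMARKS.index(name), 0] = hip_x
        xy[:, LANDMARKS.index(name), 1] = 400.0
    return KeypointTrajectory(np.arange(n), xy, np.ones((n, 12)))


@pytest.mark.parametrize(
    "slope,expected", [(2.0, RIGHTWARD), (-2.0, LEFTWARD), (0.0, UNKNOWN)]
)
def test_infer_direction_from_hip_displacement(slope, expected):
    trajectory = _hip_only_trajectory(100.0 + slope * np.arange(60))
    assert np.all(infer_direction(trajectory) == expected)


def test_infer_direction_requires_hip_data():
    n = 10
    xy = np.full((n, 12, 2), np.nan)
    xy[:, LANDMARKS.index("left_knee"), :] = 1.0
    trajectory = KeypointTrajectory(np.arange(n), xy, np.ones((n, 12)))
    with pytest.raises(ValueError):
        infer_direction(trajectory)


def test_camera_facing_side_mapping():
    assert camera_facing_side(RIGHTWARD) == "left"
    assert camera_facing_side(LEFTWARD) == "right"
    assert camera_facing_side(RIGHTWARD, camera_on_left=False) == "right"
    assert camera_facing_side(LEFTWARD, camera_on_left=False) == "left"
    with pytest.raises(ValueError):
        camera_facing_side(UNKNOWN)


# -- smoothing and gap filling ----------------------------------------------


def _series(values, frames=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    frames = np.arange(n) if frames is None else np.asarray(frames)
    return JointAngleSeries(
        frames, values, values, values,
        np.full(n, RIGHTWARD, dtype=np.int8), np.full(n, "left"),
    )


def test_gap_filled_by_linear_midpoint():
    series = smooth_and_fill(_series([10.0, np.nan, 14.0]), window=1)
    assert series.hip_deg[1] == pytest.approx(12.0)


def test_constant_series_unchanged_by_smoothing():
    series = smooth_and_fill(_series([5.0] * 20), window=3)
    np.testing.assert_allclose(series.knee_deg, 5.0)


def test_long_gap_left_missing():
    values = [1.0] * 5 + [np.nan] * 8 + [2.0] * 5
    series = smooth_and_fill(_series(values), max_gap=5, window=1)
    assert np.isnan(series.hip_deg[5:13]).all()


def test_smoothing_idempotent_on_gap_free_series_with_window_one(rng):
    values = rng.normal(0, 10, 50)
    once = smooth_and_fill(_series(values), window=1)
    twice = smooth_and_fill(once, window=1)
    np.testing.assert_array_equal(once.hip_deg, twice.hip_deg)


def test_all_missing_joint_is_error():
    with pytest.raises(ValueError, match="missing"):
        smooth_and_fill(_series([np.nan, np.nan, np.nan]))


# -- full computation -------------------------------------------------------


def test_standing_straight_gives_zero_angles():
    """Neutral pose: vertical trunk/leg, horizontal foot -> all angles 0."""
    n = 30
    xy = np.full((n, 12, 2), np.nan)
    pose = {
        "shoulder": (100.0, 100.0), "hip": (100.0, 280.0), "knee": (100.0, 440.0),
        "ankle": (100.0, 590.0), "heel": (82.0, 590.0), "toe": (142.0, 590.0),
    }
    for side in ("left", "right"):
        for part, (x, y) in pose.items():
            xy[:, LANDMARKS.index(f"{side}_{part}"), :] = (x, y)
    trajectory = KeypointTrajectory(
        np.arange(n), xy, np.ones((n, 12)),
        direction_labels=np.full(n, RIGHTWARD, dtype=np.int8),
    )
    series = compute_angles(trajectory)
    for joint in ("hip", "knee", "ankle"):
        np.testing.assert_allclose(series.joint(joint), 0.0, atol=1e-9)


def test_zero_noise_simulation_recovers_templates(clean_subject, clean_series):
    """compute_angles inverts the simulator's forward kinematics to <1 deg RMS."""
    trajectory, truth = clean_subject
    templates = default_templates()
    # interior frames of the first pass: between first and last IC of the pass
    lo, hi = truth.ic_frames[0], truth.ic_frames[3]
    mask = (clean_series.frame_index >= lo) & (clean_series.frame_index <= hi)
    frames = clean_series.frame_index[mask]
    phase = (frames - lo) / 50.0  # 1.0 s cycles at 50 Hz
    for joint in ("hip", "knee", "ankle"):
        recovered = clean_series.joint(joint)[mask]
        expected = templates[joint].evaluate(phase)
        rms = np.sqrt(np.nanmean((recovered - expected) ** 2))
        assert rms < 1.0, f"{joint} RMS {rms:.3f} deg"


def test_angle_series_csv_round_trip(tmp_path, clean_series):
    path = tmp_path / "angles.csv"
    clean_series.to_csv(path)
    restored = JointAngleSeries.from_csv(path)
    np.testing.assert_array_equal(restored.frame_index, clean_series.frame_index)
    np.testing.assert_allclose(restored.knee_deg, clean_series.knee_deg)
    np.testing.assert_array_equal(restored.direction, clean_series.direction)
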