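"""Sagittal-plane joint angles from 2D keypoints.

Angles are computed for the camera-facing side only (the limb nearer the
camera during a pass, continuously visible and never occluded by the
contralateral leg).  Conventions, in the y-down pixel frame of
``gaitpipe.io``:

* **knee** -- flexion of the knee, ``180 deg - enclosed(hip-knee, ankle-knee)``;
  a straight leg gives 0, values in [0, 180).
* **hip** -- signed angle between the downward extension of the trunk segment
  (hip - shoulder) and the thigh segment (knee - hip); flexion (knee ahead of
  the trunk line, on the walking-direction side) positive, extension negative.
* **ankle** -- signed deviation from the 90 deg neutral between the shank
  (ankle - knee) and the foot (toe - heel); dorsiflexion (toes up) positive,
  plantarflexion negative.

All three are invariant to translation and uniform scaling of the keypoints
and to mirroring (x -> -x with the walking direction reversed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import LANDMARK_INDEX, JOINTS, KeypointTrajectory

logger = logging.getLogger(__name__)

#: walking-direction codes (sign of image-x motion)
RIGHTWARD, LEFTWARD, UNKNOWN = 1, -1, 0
DIRECTION_NAMES = {RIGHTWARD: "rightward", LEFTWARD: "leftward", UNKNOWN: "unknown"}
DIRECTION_CODES = {v: k for k, v in DIRECTION_NAMES.items()}


class DegenerateGeometryError(ValueError):
    """Raised when keypoints coincide and no angle is defined."""


@dataclass
class JointAngleSeries:
    """Per-frame hip/knee/ankle angles (degrees) of the camera-facing side.

    ``direction`` holds +1 (rightward) / -1 (leftward) per frame; frames with
    unknown direction are excluded at construction.  ``side`` is the
    camera-facing side actually used per frame ("left"/"right").  Angles may
    be NaN where landmarks were missing and the gap was too long to fill.
    """

    frame_index: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    direction: np.ndarray
    side: np.ndarray
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in ("hip_deg", "knee_deg", "ankle_deg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.direction = np.asarray(self.direction, dtype=np.int8)
        self.side = np.asarray(self.side)

    def __len__(self) -> int:
        return len(self.frame_index)

    def joint(self, name: str) -> np.ndarray:
        return getattr(self, f"{name}_deg")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "direction": [DIRECTION_NAMES[d] for d in self.direction],
                "side_used": self.side,
                "hip_deg": self.hip_deg,
                "knee_deg": self.knee_deg,
                "ankle_deg": self.ankle_deg,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float = 50.0) -> "JointAngleSeries":
        df = pd.read_csv(path)
        return cls(
            df["frame_index"].to_numpy(),
            df["hip_deg"].to_numpy(),
            df["knee_deg"].to_numpy(),
            df["ankle_deg"].to_numpy(),
            np.array([DIRECTION_CODES[d] for d in df["direction"]], dtype=np.int8),
            df["side_used"].to_numpy(),
            fps=fps,
        )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def _as_point(p) -> np.ndarray:
    return np.asarray(p, dtype=float)


def _signed_angle_deg(u: np.ndarray, v: np.ndarray, direction: int) -> np.ndarray:
    """Signed angle (degrees) of v relative to u, positive when v leans toward
    the walking direction.  In y-down coordinates the 2D cross product
    ``ux*vy - uy*vx`` is negative when v is rotated toward +x from a downward
    u, hence the sign flip; multiplying by the direction code makes the
    convention mirror-invariant."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.degrees(np.arctan2(-direction * cross, dot))


def _check_nonzero(*vectors, what: str = "segment"):
    for v in vectors:
        if np.hypot(v[0], v[1]) == 0:
            raise DegenerateGeometryError(f"degenerate {what}: coincident keypoints")


def knee_angle(hip, knee, ankle) -> float:
    """Knee flexion in degrees: 180 - enclosed(hip-knee, ankle-knee).

    Collinear hip/knee/ankle (straight leg) gives 0; returned in [0, 180).
    """
    hip, knee, ankle = _as_point(hip), _as_point(knee), _as_point(ankle)
    u, v = hip - knee, ankle - knee
    _check_nonzero(u, v, what="leg segment")
    cross = u[0] * v[1] - u[1] * v[0]
    enclosed = np.degrees(np.arctan2(abs(cross), u @ v))
    return 180.0 - enclosed


def hip_angle(shoulder, hip, knee, direction: int) -> float:
    """Signed hip flexion(+)/extension(-) between the downward trunk
    extension (hip - shoulder) and the thigh (knee - hip), in (-180, 180)."""
    if direction == UNKNOWN:
        raise ValueError("hip_angle requires a known walking direction")
    shoulder, hip, knee = _as_point(shoulder), _as_point(hip), _as_point(knee)
    trunk, thigh = hip - shoulder, knee - hip
    _check_nonzero(trunk, what="trunk segment")
    _check_nonzero(thigh, what="thigh segment")
    return float(_signed_angle_deg(trunk, thigh, direction))


def ankle_angle(knee, ankle, heel, toe, direction: int) -> float:
    """Signed ankle dorsiflexion(+)/plantarflexion(-): deviation from the
    90-degree neutral between shank (ankle - knee) and foot (toe - heel)."""
    if direction == UNKNOWN:
        raise ValueError("ankle_angle requires a known walking direction")
    knee, ankle, heel, toe = map(_as_point, (knee, ankle, heel, toe))
    shank, foot = ankle - knee, toe - heel
    _check_nonzero(shank, what="shank segment")
    _check_nonzero(foot, what="foot segment")
    value = float(_signed_angle_deg(shank, foot, direction)) - 90.0
    if value <= -180.0:
        value += 360.0
    return value


# ---------------------------------------------------------------------------
# walking direction and camera-facing side
# ---------------------------------------------------------------------------


def infer_direction(
    trajectory: KeypointTrajectory,
    window: int = 25,
    min_speed_px: float = 1.0,
) -> np.ndarray:
    """Per-frame walking direction from mean hip-x displacement.

    The per-frame hip x velocity (pixels/frame, gradient over the actual
    frame indices so dropped frames do not distort it) is averaged over a
    centered window of ``window`` samples; frames whose mean displacement
    magnitude falls below ``min_speed_px`` are labeled unknown.
    """
    hips = np.stack(
        [trajectory.landmark("left_hip")[:, 0], trajectory.landmark("right_hip")[:, 0]]
    )
    counts = np.isfinite(hips).sum(axis=0)
    hip_x = np.where(counts > 0, np.nansum(hips, axis=0) / np.maximum(counts, 1), np.nan)
    valid = np.isfinite(hip_x)
    if valid.sum() < 2:
        raise ValueError("direction inference requires hip data in at least 2 frames")
    frames = trajectory.frame_index.astype(float)
    # fill isolated hip dropouts so the gradient stays defined everywhere
    hip_x = np.interp(frames, frames[valid], hip_x[valid])
    velocity = np.gradient(hip_x, frames)
    smoothed = uniform_filter1d(velocity, size=max(1, window), mode="nearest")
    direction = np.zeros(len(hip_x), dtype=np.int8)
    direction[smoothed >= min_speed_px] = RIGHTWARD
    direction[smoothed <= -min_speed_px] = LEFTWARD
    return direction


def camera_facing_side(direction: int, camera_on_left: bool = True) -> str:
    """Map walking direction to the side facing the camera.

    Default convention: a rightward walk presents the *left* body side to the
    camera; ``camera_on_left=False`` flips both mappings.
    """
    if direction == UNKNOWN:
        raise ValueError("camera_facing_side requires a known walking direction")
    mapping = {RIGHTWARD: "left", LEFTWARD: "right"}
    side = mapping[int(direction)]
    if not camera_on_left:
        side = "right" if side == "left" else "left"
    return side


# ---------------------------------------------------------------------------
# smoothing / gap filling
# ---------------------------------------------------------------------------


def _fill_gaps(frames: np.ndarray, values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs spanning <= max_gap frames."""
    out = values.copy()
    valid = np.isfinite(values)
    if valid.sum() < 2:
        return out
    idx = np.flatnonzero(valid)
    for left, right in zip(idx[:-1], idx[1:]):
        if right - left <= 1:
            continue
        gap_frames = frames[right] - frames[left] - 1
        if gap_frames <= max_gap:
            inner = slice(left + 1, right)
            out[inner] = np.interp(
                frames[inner], [frames[left], frames[right]], [values[left], values[right]]
            )
        else:
            logger.debug(
                "gap of %d frames after frame %d exceeds max_gap=%d; left missing",
                gap_frames, frames[left], max_gap,
            )
    return out


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that ignores NaNs and preserves NaN positions."""
    if window <= 1:
        return values.copy()
    smoothed = (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    smoothed[~np.isfinite(values)] = np.nan
    return smoothed


def smooth_and_fill(
    series: JointAngleSeries, max_gap: int = 5, window: int = 3
) -> JointAngleSeries:
    """Fill short gaps by linear interpolation, then apply a centered moving
    average (``window=1`` disables smoothing).  Gaps longer than ``max_gap``
    frames stay missing.  Idempotent on gap-free series with window 1.
    """
    updates = {}
    for joint in JOINTS:
        values = series.joint(joint)
        if np.isfinite(values).sum() == 0:
            raise ValueError(f"all {joint} angles missing; nothing to smooth")
        if np.isfinite(values).sum() < 2:
            raise ValueError(f"need at least 2 valid {joint} frames")
        filled = _fill_gaps(series.frame_index, values, max_gap)
        updates[f"{joint}_deg"] = _moving_average(filled, window)
    return replace(series, **updates)


# ---------------------------------------------------------------------------
# full angle computation
# ---------------------------------------------------------------------------

_SIDE_LM = {
    side: {part: LANDMARK_INDEX[f"{side}_{part}"] for part in
           ("shoulder", "hip", "knee", "ankle", "heel", "toe")}
    for side in ("left", "right")
}


def compute_angles(
    trajectory: KeypointTrajectory,
    window: int = 3,
    max_gap: int = 5,
    direction_window: int = 25,
    min_speed_px: float = 1.0,
    camera_on_left: bool = True,
) -> JointAngleSeries:
    """Hip/knee/ankle angle series for the camera-facing side.

    Walking direction comes from ``trajectory.direction_labels`` when
    present, otherwise from :func:`infer_direction`.  Frames with unknown
    direction are excluded; per-frame angles are then gap-filled and smoothed
    via :func:`smooth_and_fill`.
    """
    if trajectory.direction_labels is not None:
        direction = np.asarray(trajectory.direction_labels, dtype=np.int8)
    else:
        direction = infer_direction(trajectory, direction_window, min_speed_px)
    known = direction != UNKNOWN
    if not np.any(known):
        logger.warning("no frames with known walking direction; empty angle series")
        empty = np.empty(0)
        return JointAngleSeries(
            np.empty(0, dtype=np.int64), empty, empty, empty,
            np.empty(0, dtype=np.int8), np.empty(0, dtype="<U5"), fps=trajectory.fps,
        )

    frames = trajectory.frame_index[known]
    direction = direction[known]
    xy = trajectory.xy[known]
    n = len(frames)
    sides = np.array(
        [camera_facing_side(d, camera_on_left) for d in direction], dtype="<U5"
    )

    hip = np.full(n, np.nan)
    knee = np.full(n, np.nan)
    ankle = np.full(n, np.nan)
    for side in ("left", "right"):
        mask = sides == side
        if not np.any(mask):
            continue
        lm = _SIDE_LM[side]
        pts = {part: xy[mask][:, idx, :] for part, idx in lm.items()}
        d = direction[mask].astype(float)

        trunk = pts["hip"] - pts["shoulder"]
        thigh = pts["knee"] - pts["hip"]
        shank = pts["ankle"] - pts["knee"]
        foot = pts["toe"] - pts["heel"]
        u, v = pts["hip"] - pts["knee"], pts["ankle"] - pts["knee"]

        with np.errstate(invalid="ignore"):
            cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
            dot = np.einsum("ij,ij->i", u, v)
            knee[mask] = 180.0 - np.degrees(np.arctan2(np.abs(cross), dot))

            cross_h = trunk[:, 0] * thigh[:, 1] - trunk[:, 1] * thigh[:, 0]
            dot_h = np.einsum("ij,ij->i", trunk, thigh)
            hip[mask] = np.degrees(np.arctan2(-d * cross_h, dot_h))

            cross_a = shank[:, 0] * foot[:, 1] - shank[:, 1] * foot[:, 0]
            dot_a = np.einsum("ij,ij->i", shank, foot)
            ank = np.degrees(np.arctan2(-d * cross_a, dot_a)) - 90.0
            ank[ank <= -180.0] += 360.0
            ankle[mask] = ank

        # degenerate geometry (zero-length segments) -> missing, not garbage
        for name, seg in (("knee", u), ("knee", v), ("hip", trunk), ("hip", thigh),
                          ("ankle", shank), ("ankle", foot)):
            bad = np.hypot(seg[:, 0], seg[:, 1]) == 0
            if np.any(bad):
                target = {"knee": knee, "hip": hip, "ankle": ankle}[name]
                rows = np.flatnonzero(mask)[bad]
                target[rows] = np.nan

    series = JointAngleSeries(frames, hip, knee, ankle, direction, sides, fps=trajectory.fps)
    return smooth_and_fill(series, max_gap=max_gap, window=window)
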