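"""Containers and readers/writers for 2D keypoint trajectories and derived tables.

Coordinate convention used throughout the package: image pixels with the
origin at the top-left corner and the y axis pointing *down*, 0-based frame
indices.  All downstream sign conventions (``gaitpipe.kinematics``) are
defined against this single convention.

Twelve landmarks are tracked: shoulder, hip, knee, ankle, heel and toe on
each body side.  Landmark names are case-insensitive on read and written in
canonical lower-case ``<side>_<part>`` form.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIDES = ("left", "right")
BODY_PARTS = ("shoulder", "hip", "knee", "ankle", "heel", "toe")
#: canonical ordering of the 12 tracked landmarks
LANDMARKS = tuple(f"{side}_{part}" for side in SIDES for part in BODY_PARTS)
LANDMARK_INDEX = {name: i for i, name in enumerate(LANDMARKS)}

JOINTS = ("hip", "knee", "ankle")


class KeypointParseError(ValueError):
    """Raised when a keypoint file cannot be parsed; names the offending line."""


@dataclass
class KeypointTrajectory:
    """Per-frame pixel positions of the 12 landmarks with confidences.

    Attributes
    ----------
    frame_index : (n,) int array, strictly increasing.
    xy : (n, 12, 2) float array, pixels; NaN marks a missing landmark.
    confidence : (n, 12) float array in [0, 1]; NaN where the landmark is
        missing.  Absent confidence on read is treated as 1.0.
    fps : sampling rate in Hz (> 0).
    subject_id : free-form identifier.
    direction_labels : optional (n,) int8 array of per-frame walking
        direction (+1 rightward, -1 leftward, 0 unknown); ``None`` when
        direction must be inferred downstream.
    """

    frame_index: np.ndarray
    xy: np.ndarray
    confidence: np.ndarray
    fps: float = 50.0
    subject_id: str = ""
    direction_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.frame_index), 12, 2)
        self.confidence = np.asarray(self.confidence, dtype=float).reshape(
            len(self.frame_index), 12
        )
        self.validate()

    # -- basic contracts ---------------------------------------------------
    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if len(self.frame_index) and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if len(self.frame_index) and self.frame_index[0] < 0:
            raise ValueError("frame indices must be non-negative")
        present = ~np.isnan(self.xy)
        if not np.all(np.isfinite(self.xy[present])):
            raise ValueError("present coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def timestamps_s(self) -> np.ndarray:
        return self.frame_index / self.fps

    def landmark(self, name: str) -> np.ndarray:
        """(n, 2) pixel coordinates of one landmark (NaN where missing)."""
        return self.xy[:, LANDMARK_INDEX[name], :]


@dataclass(frozen=True)
class EventAnnotation:
    """A manually labeled gait event (initial contact) with walking direction."""

    frame_index: int
    event: str = "initial_contact"
    direction: str = "rightward"

    def __post_init__(self) -> None:
        if self.direction not in ("leftward", "rightward"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass
class WaveformRecord:
    """One time-normalized gait-cycle waveform (101 nodes, 0-100% cycle)."""

    subject_id: str
    joint: str
    side: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError(
                f"waveform must have exactly 101 values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")


# ---------------------------------------------------------------------------
# keypoint serialization
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer keypoint format from suffix {suffix!r}")


def _normalize_landmark(name: str) -> str | None:
    canonical = name.strip().lower()
    return canonical if canonical in LANDMARK_INDEX else None


def read_keypoints(
    path: str | Path,
    format: str | None = None,
    fps: float = 50.0,
    subject_id: str | None = None,
) -> KeypointTrajectory:
    """Read a keypoint trajectory from JSONL or CSV.

    Frames are returned sorted by frame index; landmarks not among the 12
    tracked ones are dropped with a warning; absent landmarks stay missing
    (NaN).  Duplicate frame indices and malformed records raise with the
    offending line number.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if subject_id is None:
        subject_id = path.stem
    if fmt == "jsonl":
        frames = _read_jsonl(path)
    elif fmt == "csv":
        frames = _read_csv(path)
    else:
        raise ValueError(f"unknown keypoint format {fmt!r}")

    frames.sort(key=lambda rec: rec[0])
    index = np.array([rec[0] for rec in frames], dtype=np.int64)
    if len(index) and np.any(np.diff(index) == 0):
        dup = int(index[np.where(np.diff(index) == 0)[0][0]])
        raise KeypointParseError(f"{path}: duplicate frame_index {dup}")

    xy = np.full((len(frames), 12, 2), np.nan)
    conf = np.full((len(frames), 12), np.nan)
    for row, (_, coords) in enumerate(frames):
        for lm_i, (x, y, c) in coords.items():
            xy[row, lm_i] = (x, y)
            conf[row, lm_i] = c
    return KeypointTrajectory(index, xy, conf, fps=fps, subject_id=subject_id)


def _read_jsonl(path: Path) -> list[tuple[int, dict]]:
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                frame = int(record["frame_index"])
                landmarks = record["landmarks"]
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise KeypointParseError(f"{path}:{lineno}: malformed record ({exc})")
            coords = {}
            for name, values in landmarks.items():
                lm = _normalize_landmark(name)
                if lm is None:
                    logger.warning("%s:%d: dropping unknown landmark %r", path, lineno, name)
                    continue
                try:
                    x, y = float(values[0]), float(values[1])
                    c = float(values[2]) if len(values) > 2 else 1.0
                except (TypeError, ValueError, IndexError) as exc:
                    raise KeypointParseError(
                        f"{path}:{lineno}: bad coordinates for {name!r} ({exc})"
                    )
                if np.isfinite(x) and np.isfinite(y):
                    coords[LANDMARK_INDEX[lm]] = (x, y, c)
            if not coords:
                raise KeypointParseError(f"{path}:{lineno}: record has no landmarks")
            frames.append((frame, coords))
    return frames


def _read_csv(path: Path) -> list[tuple[int, dict]]:
    frames = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "frame_index" not in reader.fieldnames:
            raise KeypointParseError(f"{path}: missing frame_index column")
        known, unknown = set(), set()
        for name in reader.fieldnames:
            if name == "frame_index":
                continue
            base = name.rsplit("_", 1)
            if len(base) == 2 and base[1] in ("x", "y", "c"):
                lm = _normalize_landmark(base[0])
                if lm is not None:
                    known.add(lm)
                    continue
            unknown.add(name)
        if unknown:
            logger.warning("%s: dropping unknown columns %s", path, sorted(unknown))
        for lineno, row in enumerate(reader, start=2):
            try:
                frame = int(row["frame_index"])
            except (TypeError, ValueError) as exc:
                raise KeypointParseError(f"{path}:{lineno}: bad frame_index ({exc})")
            coords = {}
            for lm in known:
                raw_x, raw_y = row.get(f"{lm}_x", ""), row.get(f"{lm}_y", "")
                if raw_x in ("", None) or raw_y in ("", None):
                    continue
                try:
                    x, y = float(raw_x), float(raw_y)
                    raw_c = row.get(f"{lm}_c", "")
                    c = float(raw_c) if raw_c not in ("", None) else 1.0
                except ValueError as exc:
                    raise KeypointParseError(f"{path}:{lineno}: bad value for {lm} ({exc})")
                if np.isfinite(x) and np.isfinite(y):
                    coords[LANDMARK_INDEX[lm]] = (x, y, c)
            frames.append((frame, coords))
    return frames


def write_keypoints(
    trajectory: KeypointTrajectory, path: str | Path, format: str | None = None
) -> None:
    """Write a trajectory so that :func:`read_keypoints` reproduces it exactly
    (coordinates to 6 decimals).  Missing landmarks are omitted / left blank."""
    path = Path(path)
    fmt = _infer_format(path, format)
    present = ~np.isnan(trajectory.xy[:, :, 0])
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for row in range(trajectory.n_frames):
                landmarks = {
                    LANDMARKS[lm]: [
                        round(float(trajectory.xy[row, lm, 0]), 6),
                        round(float(trajectory.xy[row, lm, 1]), 6),
                        round(float(trajectory.confidence[row, lm]), 6),
                    ]
                    for lm in range(12)
                    if present[row, lm]
                }
                fh.write(
                    json.dumps(
                        {"frame_index": int(trajectory.frame_index[row]), "landmarks": landmarks}
                    )
                    + "\n"
                )
    elif fmt == "csv":
        header = ["frame_index"]
        for lm in LANDMARKS:
            header += [f"{lm}_x", f"{lm}_y", f"{lm}_c"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for row in range(trajectory.n_frames):
                out = [int(trajectory.frame_index[row])]
                for lm in range(12):
                    if present[row, lm]:
                        out += [
                            f"{trajectory.xy[row, lm, 0]:.6f}",
                            f"{trajectory.xy[row, lm, 1]:.6f}",
                            f"{trajectory.confidence[row, lm]:.6f}",
                        ]
                    else:
                        out += ["", "", ""]
                writer.writerow(out)
    else:
        raise ValueError(f"unknown keypoint format {fmt!r}")


# ---------------------------------------------------------------------------
# event annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation CSV with columns ``frame_index,event,direction``."""
    df = pd.read_csv(path)
    required = {"frame_index", "event", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    return [
        EventAnnotation(int(r.frame_index), str(r.event), str(r.direction))
        for r in df.itertuples()
    ]


def write_annotations(annotations: list[EventAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": [a.frame_index for a in annotations],
            "event": [a.event for a in annotations],
            "direction": [a.direction for a in annotations],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# waveform tables (101-node, 0-100% gait cycle)
# ---------------------------------------------------------------------------

_NODE_COLUMNS = [f"node_{k}" for k in range(101)]


def read_waveform_table(path: str | Path) -> list[WaveformRecord]:
    """Read a waveform CSV: ``subject,joint,side,node_0..node_100``.

    Each row becomes one 101-node waveform; any row with a missing or
    non-numeric node value is rejected, naming the row.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    needed = ["subject", "joint", "side"] + _NODE_COLUMNS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing[:4]}...")
    records = []
    for i, row in df.iterrows():
        values = pd.to_numeric(row[_NODE_COLUMNS], errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{path}: row {i} ({row['subject']}) has non-numeric node values")
        records.append(WaveformRecord(str(row["subject"]), row["joint"], row["side"], values))
    return records


def write_waveform_table(records: list[WaveformRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"subject": rec.subject_id, "joint": rec.joint, "side": rec.side}
        row.update({f"node_{k}": rec.values[k] for k in range(101)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
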