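"""Gait-cycle segmentation, time normalization, and kinematic summaries.

A gait cycle is the interval between two successive initial contacts of the
same limb.  Cycles are cut between consecutive same-direction events with no
direction change in between, filtered to plausible durations, linearly
resampled onto 101 nodes (0-100% of the cycle, endpoints inclusive -- the
standard time base of the gait literature), averaged into participant-level
mean waveforms, and summarized as minimum angle, maximum angle, range of
motion (ROM = Max - Min), and mean cycle time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import JOINTS, WaveformRecord
from .kinematics import JointAngleSeries, camera_facing_side
from .events import GaitEvent, _event_frame_direction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle between same-direction initial contacts."""

    start_frame: int
    end_frame: int
    direction: int
    side: str
    fps: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps


@dataclass
class ParticipantSummary:
    """Per-joint/side mean waveforms and scalar kinematic parameters."""

    subject_id: str
    mean_waveforms: dict[tuple[str, str], WaveformRecord] = field(default_factory=dict)
    n_cycles: dict[tuple[str, str], int] = field(default_factory=dict)
    kinematics: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    mean_cycle_time_s: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (joint, side), (lo, hi, rom) in sorted(self.kinematics.items()):
            rows.append(
                {
                    "subject": self.subject_id,
                    "joint": joint,
                    "side": side,
                    "n_cycles": self.n_cycles[(joint, side)],
                    "min_deg": lo,
                    "max_deg": hi,
                    "rom_deg": rom,
                    "mean_cycle_time_s": self.mean_cycle_time_s,
                }
            )
        return pd.DataFrame(rows)


def segment_cycles(
    series: JointAngleSeries,
    events: list,
    min_duration_s: float = 0.4,
    max_duration_s: float = 2.5,
    camera_on_left: bool = True,
) -> list[GaitCycle]:
    """Cut cycles between consecutive same-direction events.

    Only *consecutive* event pairs count, so a direction change between two
    same-direction events voids the pair.  Cycles with implausible duration
    (outside [min_duration_s, max_duration_s]) are discarded and logged.
    Fewer than two usable events yields an empty list, not an error.
    """
    pairs = sorted(_event_frame_direction(e) for e in events)
    cycles: list[GaitCycle] = []
    for (f0, d0), (f1, d1) in zip(pairs[:-1], pairs[1:]):
        if d0 != d1:
            continue
        cycle = GaitCycle(
            f0, f1, d0, camera_facing_side(d0, camera_on_left), series.fps
        )
        if not (min_duration_s <= cycle.duration_s <= max_duration_s):
            logger.debug(
                "discarding cycle %d-%d: duration %.3f s outside [%.1f, %.1f]",
                f0, f1, cycle.duration_s, min_duration_s, max_duration_s,
            )
            continue
        cycles.append(cycle)
    if len(pairs) < 2:
        logger.warning("fewer than 2 events; no cycles segmented")
    return cycles


def time_normalize(
    series: JointAngleSeries,
    cycle: GaitCycle,
    joint: str,
    n_nodes: int = 101,
) -> WaveformRecord:
    """Resample one cycle's joint-angle segment onto ``n_nodes`` equally
    spaced points spanning [start_frame, end_frame] by linear interpolation.

    Node 0 is the angle at the starting initial contact, the last node the
    angle at the ending one.
    """
    mask = (series.frame_index >= cycle.start_frame) & (
        series.frame_index <= cycle.end_frame
    )
    frames = series.frame_index[mask].astype(float)
    values = series.joint(joint)[mask]
    finite = np.isfinite(values)
    frames, values = frames[finite], values[finite]
    if len(frames) < 4:
        raise ValueError(
            f"cycle {cycle.start_frame}-{cycle.end_frame} has only {len(frames)} "
            f"usable {joint} frames (need >= 4)"
        )
    nodes = np.linspace(cycle.start_frame, cycle.end_frame, n_nodes)
    resampled = np.interp(nodes, frames, values)
    return WaveformRecord("", joint, cycle.side, resampled)


def mean_waveform(waveforms: list[WaveformRecord]) -> WaveformRecord:
    """Node-wise arithmetic mean of same-joint/side waveforms."""
    if not waveforms:
        raise ValueError("cannot average an empty waveform list")
    joints = {w.joint for w in waveforms}
    sides = {w.side for w in waveforms}
    if len(joints) > 1 or len(sides) > 1:
        raise ValueError(f"mixed joints/sides in average: {joints}, {sides}")
    stacked = np.stack([w.values for w in waveforms])
    return WaveformRecord(
        waveforms[0].subject_id, joints.pop(), sides.pop(), stacked.mean(axis=0)
    )


def kinematic_summary(waveform: WaveformRecord) -> tuple[float, float, float]:
    """(Min, Max, ROM) over the 101 nodes of a mean waveform; ROM = Max - Min."""
    lo = float(waveform.values.min())
    hi = float(waveform.values.max())
    return lo, hi, hi - lo


def mean_cycle_time(cycles: list[GaitCycle]) -> float:
    """Arithmetic mean of cycle durations in seconds."""
    if not cycles:
        raise ValueError("cannot average an empty cycle list")
    return float(np.mean([c.duration_s for c in cycles]))


def participant_summary(
    series: JointAngleSeries,
    events: list,
    subject_id: str = "",
    n_nodes: int = 101,
    min_duration_s: float = 0.4,
    max_duration_s: float = 2.5,
    camera_on_left: bool = True,
) -> ParticipantSummary:
    """Full per-participant reduction: cycles -> normalized waveforms ->
    per-joint/side means -> Min/Max/ROM and mean cycle time."""
    cycles = segment_cycles(series, events, min_duration_s, max_duration_s, camera_on_left)
    summary = ParticipantSummary(subject_id=subject_id)
    if not cycles:
        logger.warning("subject %s: no usable cycles", subject_id)
        return summary
    summary.mean_cycle_time_s = mean_cycle_time(cycles)
    for joint in JOINTS:
        for side in ("left", "right"):
            selected = []
            for cycle in cycles:
                if cycle.side != side:
                    continue
                try:
                    selected.append(time_normalize(series, cycle, joint, n_nodes))
                except ValueError as exc:
                    logger.debug("skipping cycle: %s", exc)
            if not selected:
                continue
            mean = mean_waveform(selected)
            mean.subject_id = subject_id
            summary.mean_waveforms[(joint, side)] = mean
            summary.n_cycles[(joint, side)] = len(selected)
            summary.kinematics[(joint, side)] = kinematic_summary(mean)
    return summary
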