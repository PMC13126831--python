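"""End-to-end orchestration: angles -> events -> cycles -> summaries, the
method-agreement validation analysis, and the group comparison."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cycles as cycles_mod
from . import kinematics, spm
from .agreement import (
    PairedScalarTest,
    difference_waveforms,
    dtw_align,
    mean_correlation,
    paired_ttest,
    waveform_correlation,
)
from .events import InitialContactDetector
from .io import JOINTS, KeypointTrajectory, WaveformRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the per-subject pipeline, all seeds explicit."""

    fps: float = 50.0
    smoothing_window: int = 3
    max_gap: int = 5
    direction_window: int = 25
    min_speed_px: float = 1.0
    camera_on_left: bool = True
    min_sep_fraction: float = 0.5
    min_duration_s: float = 0.4
    max_duration_s: float = 2.5
    n_nodes: int = 101
    alpha: float = 0.05
    spm_method: str = "rft"
    detector_seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    subject_id: str
    series: kinematics.JointAngleSeries
    events: list
    cycles: list
    summary: cycles_mod.ParticipantSummary


def run_pipeline(
    trajectory: KeypointTrajectory,
    detector: InitialContactDetector,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Angles -> detected events -> cycles -> participant summary.

    Each stage's intermediate is retained on the result; stage counts are
    logged.  A stationary subject yields zero cycles and an empty summary
    with a warning, not an error.
    """
    series = kinematics.compute_angles(
        trajectory,
        window=config.smoothing_window,
        max_gap=config.max_gap,
        direction_window=config.direction_window,
        min_speed_px=config.min_speed_px,
        camera_on_left=config.camera_on_left,
    )
    logger.info("%s: %d/%d frames with known direction",
                trajectory.subject_id, len(series), trajectory.n_frames)
    if len(series) == 0:
        logger.warning("%s: no walking detected; empty summary", trajectory.subject_id)
        return PipelineResult(
            trajectory.subject_id, series, [], [],
            cycles_mod.ParticipantSummary(subject_id=trajectory.subject_id),
        )
    events = detector.predict(series)
    cycle_list = cycles_mod.segment_cycles(
        series, events, config.min_duration_s, config.max_duration_s,
        config.camera_on_left,
    )
    summary = cycles_mod.participant_summary(
        series, events, trajectory.subject_id, config.n_nodes,
        config.min_duration_s, config.max_duration_s, config.camera_on_left,
    )
    logger.info("%s: %d events -> %d cycles", trajectory.subject_id,
                len(events), len(cycle_list))
    return PipelineResult(trajectory.subject_id, series, events, cycle_list, summary)


# ---------------------------------------------------------------------------
# validation against a reference method
# ---------------------------------------------------------------------------


def run_validation(
    reference: list[WaveformRecord],
    proposed: list[WaveformRecord],
    cycle_times: pd.DataFrame | None = None,
    alpha: float = 0.05,
    align: bool = True,
) -> dict:
    """Method-agreement report: DTW-aligned per-subject waveform pairs, mean
    Pearson r per joint, difference waveforms (reference minus proposed),
    one-sample SPM per joint, and a paired t-test on cycle times
    (proposed minus reference, the usual direction for method bias).

    ``cycle_times`` needs columns subject, group, reference_s, proposed_s.
    """
    ref_map = {(w.subject_id, w.joint, w.side): w for w in reference}
    qry_map = {(w.subject_id, w.joint, w.side): w for w in proposed}
    if set(ref_map) != set(qry_map):
        unmatched = sorted(set(ref_map) ^ set(qry_map))
        raise ValueError(f"subject sets do not match; unpaired: {unmatched}")

    aligned: list[WaveformRecord] = []
    for key in sorted(qry_map):
        query = qry_map[key]
        if align:
            alignment = dtw_align(ref_map[key].values, query.values)
            aligned.append(WaveformRecord(key[0], key[1], key[2], alignment.aligned_query))
        else:
            aligned.append(query)

    report: dict = {"schema": "gaitpipe.validation/1", "alpha": alpha,
                    "mean_r": {}, "spm": {}}
    aligned_map = {(w.subject_id, w.joint, w.side): w for w in aligned}
    diffs = difference_waveforms(reference, aligned, "reference_minus_query")
    for joint in JOINTS:
        keys = [k for k in sorted(ref_map) if k[1] == joint]
        if not keys:
            continue
        r_values = [
            waveform_correlation(ref_map[k].values, aligned_map[k].values) for k in keys
        ]
        report["mean_r"][joint] = mean_correlation(r_values)
        diff_stack = np.stack([diffs[k] for k in sorted(diffs) if k[1] == joint])
        if diff_stack.shape[0] >= 2:
            if np.any(diff_stack.std(axis=0, ddof=1) == 0):
                # methods agree exactly (or degenerately) at some node: no
                # t field is defined, and there is nothing to flag
                logger.info("%s: zero-variance difference waveforms; "
                            "reporting no significant difference", joint)
                report["spm"][joint] = {
                    "t_star": None, "fwhm": None, "df": diff_stack.shape[0] - 1,
                    "significant": False, "clusters": [],
                }
            else:
                result = spm.spm_test(diff_stack, "one_sample", alpha)
                report["spm"][joint] = {
                    "t_star": result.t_star,
                    "fwhm": result.field.fwhm,
                    "df": result.field.df,
                    "significant": result.significant,
                    "clusters": result.clusters,
                }
    report["difference_waveforms"] = {
        "|".join(k): v.tolist() for k, v in diffs.items()
    }

    if cycle_times is not None:
        test = paired_ttest(
            cycle_times["proposed_s"].to_numpy(),
            cycle_times["reference_s"].to_numpy(),
            orientation="x_minus_y",
        )
        group_means = {}
        for group, sub in cycle_times.groupby("group"):
            group_means[group] = {
                "proposed_s": float(sub["proposed_s"].mean()),
                "reference_s": float(sub["reference_s"].mean()),
            }
        report["cycle_time"] = {
            "n": test.n,
            "mean_diff_s": test.mean_diff,
            "sd_diff_s": test.sd_diff,
            "t": test.t_stat,
            "df": test.df,
            "p": test.p_two_sided,
            "ci95_s": list(test.ci95),
            "group_means": group_means,
        }
    return report


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def run_group_comparison(
    group_a: list[WaveformRecord],
    group_b: list[WaveformRecord],
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Two-sample SPM per joint/side plus a Min/Max/ROM group-means table."""
    report: dict = {"schema": "gaitpipe.group_comparison/1", "alpha": alpha,
                    "spm": {}, "summary": []}
    combos = sorted({(w.joint, w.side) for w in group_a + group_b})
    for joint, side in combos:
        a = np.stack([w.values for w in group_a if (w.joint, w.side) == (joint, side)])
        b = np.stack([w.values for w in group_b if (w.joint, w.side) == (joint, side)])
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError(f"group size < 2 for {joint}/{side}")
        result = spm.spm_test((a, b), "two_sample", alpha)
        report["spm"][f"{joint}/{side}"] = {
            "t_star": result.t_star,
            "fwhm": result.field.fwhm,
            "df": result.field.df,
            "significant": result.significant,
            "clusters": result.clusters,
        }
        for label, stack in zip(labels, (a, b)):
            per_subject = [
                (row.min(), row.max(), row.max() - row.min()) for row in stack
            ]
            mins, maxs, roms = (np.mean([p[i] for p in per_subject]) for i in range(3))
            report["summary"].append(
                {
                    "group": label,
                    "joint": joint,
                    "side": side,
                    "n": int(stack.shape[0]),
                    "min_deg": float(mins),
                    "max_deg": float(maxs),
                    "rom_deg": float(roms),
                }
            )
    return report
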