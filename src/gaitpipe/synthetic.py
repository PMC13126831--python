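"""Synthetic sagittal-plane gait with known ground truth.

The simulator emulates the study protocol this package targets: a child
walks back and forth past a fixed sagittal camera (50 Hz), producing
alternating-direction passes of a few gait cycles each.  Joint-angle
waveforms are low-order Fourier series over the 0-100% gait cycle whose
default ranges approximate typically developing pediatric sagittal
kinematics (hip about -7..25 deg, knee about 6..56 deg, ankle about
-15..8 deg).  A forward-kinematic chain places the 12 tracked landmarks in
y-down pixel coordinates such that :mod:`gaitpipe.kinematics` recovers the
generating angles exactly at zero noise; the contralateral leg is rendered
half a cycle out of phase for realism but is never used by the pipeline
(camera-facing rule).

Noise model: per-cycle lognormal cycle durations, per-cycle multiplicative
amplitude jitter on the Fourier harmonics, i.i.d. Gaussian pixel noise on
every coordinate, and random frame drops emulating occlusion.  Group-level
effects are injected by scaling the harmonic amplitudes of a joint, which
scales its true range of motion by exactly that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import LANDMARK_INDEX, EventAnnotation, KeypointTrajectory
from .kinematics import LEFTWARD, RIGHTWARD, camera_facing_side

# ---------------------------------------------------------------------------
# angle templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitTemplate:
    """Periodic joint-angle template: a0 + sum_k a_k cos(2 pi k phase + phi_k).

    At most 5 harmonics; ``phase`` lives on [0, 1) (one gait cycle, phase 0 =
    initial contact) and is wrapped if outside.
    """

    a0: float
    harmonics: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.harmonics) > 5:
            raise ValueError("at most 5 harmonics supported")

    def evaluate(self, phase) -> np.ndarray:
        phase = np.asarray(phase, dtype=float) % 1.0
        value = np.full_like(phase, self.a0, dtype=float)
        for k, (amp, phi) in enumerate(self.harmonics, start=1):
            value += amp * np.cos(2 * np.pi * k * phase + phi)
        return value

    def scaled(self, factor: float) -> "GaitTemplate":
        """Scale all harmonic amplitudes; scales the true ROM by ``factor``."""
        return GaitTemplate(
            self.a0, tuple((amp * factor, phi) for amp, phi in self.harmonics)
        )

    def extrema(self, n_scan: int = 10001) -> tuple[float, float]:
        values = self.evaluate(np.linspace(0.0, 1.0, n_scan))
        return float(values.min()), float(values.max())

    @property
    def rom(self) -> float:
        lo, hi = self.extrema()
        return hi - lo


def default_templates() -> dict[str, GaitTemplate]:
    """Templates approximating typically developing pediatric sagittal gait."""
    return {
        "hip": GaitTemplate(9.0, ((16.4, 0.0),)),
        "knee": GaitTemplate(
            25.0, ((23.0, -1.4 * np.pi), (8.0, -0.7 * np.pi))
        ),
        "ankle": GaitTemplate(
            -4.8, ((8.0, -1.25 * np.pi), (5.0, -0.2 * np.pi))
        ),
    }


# ---------------------------------------------------------------------------
# configuration / ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentLengths:
    """Body segment lengths in pixels (child at ~2.5 m from a 1080p camera)."""

    trunk: float = 180.0
    thigh: float = 160.0
    shank: float = 150.0
    foot: float = 60.0
    heel_fraction: float = 0.3  # of foot length behind the ankle

    def __post_init__(self) -> None:
        for name in ("trunk", "thigh", "shank", "foot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    fps 50 Hz matches the recording protocol; cycle time 1.0 s with 5% CV
    and ~3 cycles per pass, 4 alternating passes, match a short pediatric
    walkway trial.  Pixel noise sd 2 px and a 1% frame-drop rate represent
    moderate pose-estimation error; amplitude jitter 3% gives natural
    stride-to-stride variability.
    """

    fps: float = 50.0
    n_passes: int = 4
    n_cycles_per_pass: int = 3
    cycle_time_mean_s: float = 1.0
    cycle_time_cv: float = 0.05
    amplitude_jitter_sd: float = 0.03
    pixel_noise_sd: float = 2.0
    missing_frame_rate: float = 0.01
    stride_px: float = 340.0
    turn_gap_s: float = 1.0
    lead_cycles: float = 0.3
    pelvis_y_px: float = 400.0
    lengths: SegmentLengths = field(default_factory=SegmentLengths)
    camera_on_left: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_frame_rate < 1.0):
            raise ValueError("missing_frame_rate must be in [0, 1)")
        if self.cycle_time_cv < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("variability parameters must be non-negative")
        if self.fps <= 0 or self.cycle_time_mean_s <= 0:
            raise ValueError("fps and cycle_time_mean_s must be positive")


@dataclass
class GroundTruth:
    """True events and generating kinematics for one simulated subject."""

    ic_frames: np.ndarray          # frame indices of true initial contacts
    ic_directions: np.ndarray      # +1 / -1 per IC
    cycle_durations_s: np.ndarray  # one per true cycle
    templates: dict[str, GaitTemplate]
    template_summary: dict[str, tuple[float, float, float]]  # joint -> (min,max,rom)

    def annotations(self) -> list[EventAnnotation]:
        names = {RIGHTWARD: "rightward", LEFTWARD: "leftward"}
        return [
            EventAnnotation(int(f), "initial_contact", names[int(d)])
            for f, d in zip(self.ic_frames, self.ic_directions)
        ]


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def _leg_points(
    hip_deg, knee_deg, ankle_deg, direction, lengths: SegmentLengths, pelvis_xy
):
    """Landmark positions of one leg chain (vectorized over frames).

    Angles follow the package conventions exactly; the chain hangs from the
    pelvis with a vertical trunk, so the kinematics module inverts it."""
    h = np.radians(np.asarray(hip_deg, dtype=float))
    k = np.radians(np.asarray(knee_deg, dtype=float))
    a = np.radians(np.asarray(ankle_deg, dtype=float))
    d = np.asarray(direction, dtype=float)
    px, py = np.asarray(pelvis_xy[0], dtype=float), np.asarray(pelvis_xy[1], dtype=float)
    L = lengths

    def unit(alpha):  # direction-leaning angular coordinate, y-down
        return np.stack([d * np.sin(alpha), np.cos(alpha)], axis=-1)

    pelvis = np.stack([px, py], axis=-1)
    shoulder = pelvis + np.stack([np.zeros_like(px), -L.trunk * np.ones_like(py)], axis=-1)
    knee_pt = pelvis + L.thigh * unit(h)
    ankle_pt = knee_pt + L.shank * unit(h - k)
    foot_dir = unit(h - k + np.pi / 2.0 + a)
    heel_pt = ankle_pt - L.heel_fraction * L.foot * foot_dir
    toe_pt = heel_pt + L.foot * foot_dir
    return {
        "shoulder": shoulder,
        "hip": pelvis,
        "knee": knee_pt,
        "ankle": ankle_pt,
        "heel": heel_pt,
        "toe": toe_pt,
    }


def forward_kinematics(
    angles: dict[str, tuple[float, float, float]],
    direction: int,
    lengths: SegmentLengths = SegmentLengths(),
    pelvis_xy: tuple[float, float] = (0.0, 400.0),
) -> dict[str, np.ndarray]:
    """Place all 12 landmarks for one frame.

    ``angles`` maps side ("left"/"right") to (hip, knee, ankle) degrees.
    The camera-facing rule is honoured implicitly: both legs hang from the
    same pelvis, so whichever side the kinematics module selects recovers its
    own generating angles exactly.
    """
    if direction not in (LEFTWARD, RIGHTWARD):
        raise ValueError("direction must be leftward or rightward")
    out: dict[str, np.ndarray] = {}
    for side, (h, k, a) in angles.items():
        pts = _leg_points([h], [k], [a], [direction], lengths, ([pelvis_xy[0]], [pelvis_xy[1]]))
        for part, arr in pts.items():
            out[f"{side}_{part}"] = arr[0]
    return out


# ---------------------------------------------------------------------------
# subject / cohort simulation
# ---------------------------------------------------------------------------


def _lognormal(rng, mean, cv, size):
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_subject(
    config: SimulationConfig,
    templates: dict[str, GaitTemplate] | None = None,
    subject_id: str = "sim",
    seed: int = 0,
) -> tuple[KeypointTrajectory, GroundTruth]:
    """Simulate one subject's keypoint trajectory with ground truth.

    All randomness flows from ``seed``; identical seeds give bit-identical
    output.
    """
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(seed)
    fps, L = config.fps, config.lengths
    n_cycles = config.n_cycles_per_pass

    frame_chunks, xy_chunks = [], []
    ic_frames, ic_directions, cycle_durs = [], [], []
    t0 = 0.0
    pelvis_x = 200.0
    for p in range(config.n_passes):
        direction = RIGHTWARD if p % 2 == 0 else LEFTWARD
        durations = _lognormal(rng, config.cycle_time_mean_s, config.cycle_time_cv, n_cycles)
        cycle_durs.extend(durations)
        lead_in = config.lead_cycles * durations[0]
        lead_out = config.lead_cycles * durations[-1]
        pass_duration = lead_in + durations.sum() + lead_out

        # phase(t): piecewise linear, phase i at the i-th initial contact
        knots_t = np.concatenate([[0.0], lead_in + np.concatenate([[0.0], np.cumsum(durations)])])
        knots_t = np.append(knots_t, pass_duration)
        knots_phase = np.concatenate(
            [[-config.lead_cycles], np.arange(n_cycles + 1.0), [n_cycles + config.lead_cycles]]
        )

        first_frame = int(np.ceil(t0 * fps))
        last_frame = int(np.floor((t0 + pass_duration) * fps))
        frames = np.arange(first_frame, last_frame + 1)
        t_local = frames / fps - t0
        phase = np.interp(t_local, knots_t, knots_phase)

        # true ICs at integer phase crossings
        for j in range(n_cycles + 1):
            ic_frames.append(int(round((t0 + knots_t[j + 1]) * fps)))
            ic_directions.append(direction)

        # per-cycle amplitude jitter, indexed by floor(phase) per leg
        jitter = {
            joint: 1.0 + rng.normal(0.0, config.amplitude_jitter_sd, n_cycles + 2)
            for joint in templates
        }

        def jittered(joint, ph):
            tmpl = templates[joint]
            base = tmpl.evaluate(ph)
            cyc = np.clip(np.floor(ph).astype(int) + 1, 0, n_cycles + 1)
            return tmpl.a0 + jitter[joint][cyc] * (base - tmpl.a0)

        facing = camera_facing_side(direction, config.camera_on_left)
        other = "right" if facing == "left" else "left"
        leg_angles = {
            facing: {j: jittered(j, phase) for j in templates},
            other: {j: jittered(j, phase + 0.5) for j in templates},
        }

        # pelvis advances phase-locked: one stride length per cycle
        px = pelvis_x + direction * config.stride_px * (phase - phase[0])
        py = np.full_like(px, config.pelvis_y_px)
        xy = np.full((len(frames), 12, 2), np.nan)
        for side, ang in leg_angles.items():
            pts = _leg_points(
                ang["hip"], ang["knee"], ang["ankle"],
                np.full(len(frames), direction), L, (px, py),
            )
            for part, arr in pts.items():
                xy[:, LANDMARK_INDEX[f"{side}_{part}"], :] = arr

        frame_chunks.append(frames)
        xy_chunks.append(xy)
        pelvis_x = px[-1]
        t0 += pass_duration + config.turn_gap_s

    frame_index = np.concatenate(frame_chunks)
    xy = np.concatenate(xy_chunks)
    if config.pixel_noise_sd > 0:
        xy = xy + rng.normal(0.0, config.pixel_noise_sd, xy.shape)
    keep = rng.random(len(frame_index)) >= config.missing_frame_rate
    # never drop a true IC frame's record entirely? occlusion does not care:
    # drops are uniform, matching real pose-estimation failures.
    frame_index, xy = frame_index[keep], xy[keep]
    confidence = np.ones((len(frame_index), 12))

    trajectory = KeypointTrajectory(
        frame_index, xy, confidence, fps=fps, subject_id=subject_id
    )
    summary = {}
    for joint, tmpl in templates.items():
        lo, hi = tmpl.extrema()
        summary[joint] = (lo, hi, hi - lo)
    truth = GroundTruth(
        np.array(ic_frames), np.array(ic_directions, dtype=np.int8),
        np.array(cycle_durs), dict(templates), summary,
    )
    return trajectory, truth


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    trajectory: KeypointTrajectory
    truth: GroundTruth


def simulate_cohort(
    config: SimulationConfig,
    n_subjects: tuple[int, int] = (6, 6),
    group_effects: dict[str, float] | None = None,
    seed: int = 0,
    group_names: tuple[str, str] = ("control", "affected"),
) -> list[SimulatedSubject]:
    """Two-group cohort with known group effects.

    ``group_effects`` maps joint name to a ROM scaling factor applied to the
    second group's template harmonics (e.g. ``{"knee": 0.93}`` injects a 7%
    knee-ROM deficit, exactly, by construction).
    """
    group_effects = group_effects or {}
    base = default_templates()
    affected = {
        joint: tmpl.scaled(group_effects.get(joint, 1.0)) for joint, tmpl in base.items()
    }
    root = np.random.default_rng(seed)
    subjects = []
    for g, (name, templates, n) in enumerate(
        zip(group_names, (base, affected), n_subjects)
    ):
        for i in range(n):
            sid = f"{name}_{i:02d}"
            sub_seed = int(root.integers(0, 2**31 - 1))
            traj, truth = simulate_subject(config, templates, sid, seed=sub_seed)
            subjects.append(SimulatedSubject(sid, name, traj, truth))
    return subjects


def simulate_sequences(
    n: int, config: SimulationConfig, seed: int = 0, prefix: str = "seq"
) -> list[SimulatedSubject]:
    """A flat list of single-group sequences (for event-detector training)."""
    root = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub_seed = int(root.integers(0, 2**31 - 1))
        traj, truth = simulate_subject(config, None, f"{prefix}_{i:02d}", seed=sub_seed)
        out.append(SimulatedSubject(f"{prefix}_{i:02d}", "sim", traj, truth))
    return out
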