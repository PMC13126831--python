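# Methods

This note documents the models, conventions, defaults and numerical
choices behind `gaitpipe`, and what the synthetic tests do and do not
demonstrate about real video data.

## Coordinate and angle conventions

All positions are image pixels with the origin top-left and y pointing
down, 0-based frame indices. Walking direction is the sign of image-x
motion (+1 rightward, −1 leftward).

Only the camera-facing side is analyzed: with the default camera placement
a rightward walk presents the left body side (`camera_on_left=False` flips
the mapping). This mirrors single-camera sagittal recording practice,
where the near limb is continuously visible while the far limb is
periodically occluded during swing.

Angles, in degrees:

- **Knee**: `180° − ∠(hip−knee, ankle−knee)`; a straight leg is 0°,
  flexion positive, range [0°, 180°). Unsigned, because sagittal knee
  hyperextension beyond the straight line is not distinguishable in this
  2-segment convention.
- **Hip**: signed angle between the downward extension of the trunk
  segment (hip − shoulder) and the thigh (knee − hip). Flexion (knee on
  the walking-direction side of the trunk line) positive, extension
  negative, range (−180°, 180°). The shoulder–hip line stands in for the
  trunk because no pelvis landmarks exist in the 12-point set; with a
  vertical reference instead, hip curves would shift by the trunk lean.
- **Ankle**: signed deviation from the 90° neutral between shank
  (ankle − knee) and foot (toe − heel); dorsiflexion (toes toward the
  shank) positive.

These conventions make flexion/dorsiflexion positive so that outputs read
like conventional clinical gait reports, and they are exactly inverted by
the simulator's forward kinematics (verified to 1e-6° in the tests). All
three angles are invariant to translation, uniform scaling, and mirroring
(x → −x with sides and direction relabeled).

## Direction inference and smoothing

Walking direction per frame is the sign of the mean hip-x velocity
(gradient over true frame indices, so dropped frames do not distort it)
averaged over a centered 25-frame window; below 1 px/frame the direction
is *unknown* and the frame is excluded from further analysis. The window
(0.5 s at 50 Hz) is long enough to bridge the brief mid-stance hip
slowdown and short enough to resolve turns between passes.

Missing angles inside gaps of ≤ 5 frames are linearly interpolated; longer
gaps stay missing. A centered moving average of 3 frames (window 1 = off)
then suppresses frame-to-frame pose-estimation jitter. At 50 Hz this is
deliberately minimal smoothing; heavier filtering visibly attenuates the
knee flexion peak.

## Initial-contact detection

A three-class `GradientBoostingClassifier` (none / IC-leftward /
IC-rightward; 300 trees, depth 3, learning rate 0.1, seed 0) classifies
every frame. A single argmax over three classes was chosen over two
separate detectors so that event presence and direction are decided
coherently. Features per frame: the three camera-facing angles, their
first differences (gradient over frame indices; one-sided at boundaries),
and the signed walking-direction indicator. The indicator is needed
because the angle waveforms themselves are direction-symmetric; it is
derived from hip displacement, i.e. from the same kinematic record, not
from any annotation. Both the differences and the indicator can be
disabled to run a raw three-angle feature set.

Training labels mark a ±1-frame window around each annotated initial
contact as the event class (`label_halfwidth`, set to 0 for strict
single-frame labels). A heel strike is visible across adjacent frames, and
the window makes the classifier fire on short runs around the true event —
the behaviour the collapse rule below is designed for. Because event
frames are ~50× rarer than background frames, balanced sample weights are
applied by default; without them the argmax rule can remain silent at
genuine events whose probability peak stays below the majority class.

Post-processing:

1. **Run collapsing.** Each maximal run of consecutive frames with the
   same IC class becomes one event at the middle frame; for even-length
   runs (including length 2) one of the two central frames is chosen
   uniformly at random with a fixed seed, so detection is reproducible.
2. **Minimum separation.** The mean frame count between successive labeled
   events in the training sequences is learned at fit time; a detection
   closer than a configurable fraction (default 0.5) of that mean to the
   previous kept event *of the same direction* is discarded. The fraction
   exists because a literal full-mean threshold also suppresses true
   events of cycles slightly shorter than average; setting it to 1.0
   reproduces the strict rule.

Evaluation: a ground-truth event counts as detected when a prediction of
matching direction lies within ±4 frames, each prediction matched at most
once, greedily in frame order (the tolerance protocol standard for gait
events at 50 Hz).

## Cycles and summaries

Cycles run between consecutive same-direction initial contacts with no
direction change in between, and must last 0.4–2.5 s (guarding against
residual false or missed events; both bounds configurable). Each cycle is
linearly resampled onto 101 nodes spanning 0–100% inclusive — the standard
time base in the gait literature — so node 0 and node 100 equal the angle
at the bounding contacts exactly. Participant-level mean waveforms are
node-wise arithmetic means over cycles of the same joint and side; cycles
inherit the camera-facing side of their pass, so left/right summaries pool
cycles from opposite-direction passes. Min, Max and ROM = Max − Min come
from the mean waveform; mean cycle time averages cycle durations. Note
that a missed intermediate contact merges two cycles into one ~2 s
"cycle" that passes the duration filter but dilutes the mean waveform —
detector quality, not the filter, is the real guard.

## Agreement statistics

DTW uses squared-difference local cost, the symmetric step set
{(1,0),(0,1),(1,1)}, boundary constraints and no warping window — the
simplest standard form, which an exhaustive path-enumeration oracle can
verify on short sequences. The aligned query at reference node i is the
mean of all query values matched to i, preserving the 101-node domain for
downstream SPM. Pearson correlations are computed per participant after
alignment (a pre-alignment option exists) and averaged arithmetically per
joint without Fisher transform, matching how such agreement values are
conventionally reported. Difference waveforms default to reference minus
proposed; the scalar cycle-time t-test defaults to proposed minus
reference — both orientations are exposed by a flag because method
comparisons in the literature use both.

The paired t-test is the textbook statistic: d = x − y, t = mean(d) /
(sd(d)/√n) with the n−1 sd, two-sided p on n−1 df, CI from the 0.975 t
quantile. A fully degenerate zero-difference sample returns t = 0, p = 1.

## One-dimensional SPM

The t field over the 101 nodes is the pointwise one-sample (paired) or
pooled-variance two-sample t statistic. Smoothness is estimated with the
gradient-based estimator standard in 1D SPM: on residuals normalized to
unit variance per node, `fwhm = sqrt(4 ln 2 / mean squared node-to-node
gradient)` (one-sided differences at nodes 0 and 100), and
`resels = 100 / fwhm`. The critical threshold solves the 1D
Euler-characteristic expectation for t fields,

    P(max t > u) ≈ S_ν(u) + resels · (√(4 ln 2)/(2π)) · (1 + u²/ν)^(−(ν−1)/2),

by bracketed root finding to 1e-6; two-tailed inference solves at α/2 and
thresholds |t|. In the zero-resel limit this reduces to the pointwise t
quantile, and Monte-Carlo calibration on smooth Gaussian nulls (n = 12,
FWHM 15–25 nodes, 5000 replicates) puts the familywise type-I error at
≈ 0.04–0.05. Supra-threshold clusters are reported as (start, end,
extent, peak |t|); cluster-level p-values are not computed — presence,
location and extent carry the interpretation. A seeded permutation
threshold (sign flips for paired designs, label shuffles for two-sample;
at least 10/α permutations) provides a nonparametric check; on Gaussian
nulls it agrees with the RFT threshold within ~10%.

## The simulator

Joint-angle templates are Fourier series (≤ 5 harmonics) over one cycle,
phase 0 at initial contact. The defaults approximate typically developing
pediatric sagittal gait: hip −7.4–25.4°, knee ≈ 6.2–55.8°, ankle
≈ −14.5–7.6°. Closed-form templates were preferred over resampled
normative curves because Min/Max/ROM ground truth is then exact (dense
scan over 10⁴ phases), and a group effect injected by scaling a joint's
harmonic amplitudes scales its true ROM *exactly* by that factor.

A subject walks 4 alternating-direction passes of 3 cycles each past the
camera, with 0.3 cycles of lead-in/out per pass and a 1 s turn gap.
Cycle durations are lognormal with mean 1.0 s and 5% CV; per-cycle
amplitude jitter (3% sd) gives stride-to-stride variability; the pelvis
advances one stride length (340 px) per cycle. Forward kinematics places
both legs (contralateral leg phase-shifted by half a cycle — rendered for
realism, never analyzed, per the camera-facing rule), with segment
lengths of a child at ~2.5 m from a 1080p camera (trunk 180, thigh 160,
shank 150, foot 60 px). Gaussian pixel noise (sd 2 px) and uniform frame
drops (1%) model pose-estimation error and occlusion. All randomness
descends from a single seed; output is bit-reproducible.

What the simulator does *not* emulate: perspective distortion and camera
tilt, pose-estimator failure modes that are correlated over time or
landmark-specific (e.g. heel/toe confusion at heel strike), soft-tissue
and clothing artifacts, children stopping or veering mid-pass, and any
difference between true joint centers and pose-estimator landmark
definitions. Passing synthetic tests therefore demonstrates the internal
correctness and statistical calibration of the analysis chain — not the
keypoint accuracy of any particular pose estimator on real video.

## Problem sizes in the tests

The event-detection check trains on 20 simulated sequences and scores 12
held-out sequences (~190 ground-truth events) under the default noise
model — the scale of the study design this pipeline targets. SPM
calibration uses 5000 null replicates; cohort effect recovery uses 8 + 8
subjects with a 7% knee-ROM deficit and a detector trained on 6 separate
sequences. These sizes keep the full suite under a minute of CPU while
leaving the statistical assertions well-powered.

## Known limitations

- Hip angle depends on the shoulder landmark; trunk lean and shoulder
  estimation error propagate directly into hip curves.
- No 3D or frontal/transverse-plane kinematics, no kinetics, no spatial
  parameters in metres (no camera calibration).
- The knee convention cannot represent hyperextension as negative angles.
- The minimum-separation rule runs per direction and does not reset at
  pass boundaries; extremely short passes (< 2 cycles) yield no cycles.
- `run_validation` treats exactly-zero difference waveforms as "no
  significant difference" rather than an error, which is the intended
  reading for identical inputs but hides genuinely degenerate data.
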