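"""Agreement analysis between two waveform sets (e.g. marker-based
reference vs markerless estimate).

Dynamic time warping (symmetric steps, squared-difference local cost,
boundary-constrained, no window) aligns each query waveform to its
reference before node-wise comparison, so that agreement metrics reflect
waveform morphology rather than small phase shifts.  Agreement is then
summarized by per-participant Pearson correlations (averaged arithmetically
per joint), participant-level difference waveforms, and a paired t-test on
scalar cycle times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import WaveformRecord


@dataclass
class DTWAlignment:
    """Optimal monotone boundary-constrained alignment of query to reference.

    ``path`` is the ordered list of (i_ref, i_query) index pairs from (0,0)
    to (n-1, m-1) with step increments in {(1,0),(0,1),(1,1)}; ``cost`` the
    summed squared differences along it; ``aligned_query`` the query mapped
    onto the reference time base (mean of query values matched to each
    reference node).
    """

    path: list[tuple[int, int]]
    cost: float
    aligned_query: np.ndarray


def dtw_align(reference, query) -> DTWAlignment:
    """Align ``query`` to ``reference`` by dynamic time warping."""
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query, dtype=float)
    if not (np.all(np.isfinite(reference)) and np.all(np.isfinite(query))):
        raise ValueError("DTW inputs must be finite")
    n, m = len(reference), len(query)
    local = (reference[:, None] - query[None, :]) ** 2
    acc = np.full((n, m), np.inf)
    acc[0, 0] = local[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = local[i, j] + best

    # backtrack, preferring the diagonal step on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()

    aligned = np.zeros(n)
    counts = np.zeros(n)
    for pi, pj in path:
        aligned[pi] += query[pj]
        counts[pi] += 1
    aligned /= counts
    return DTWAlignment(path, float(acc[n - 1, m - 1]), aligned)


def waveform_correlation(a, b) -> float:
    """Pearson r between two equal-length waveforms; constant input is an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant waveform")
    return float(stats.pearsonr(a, b).statistic)


def mean_correlation(r_values) -> float:
    """Arithmetic mean of participant-level r values (no Fisher transform)."""
    r_values = np.asarray(list(r_values), dtype=float)
    if len(r_values) == 0:
        raise ValueError("no correlation values to average")
    return float(r_values.mean())


def difference_waveforms(
    reference: list[WaveformRecord],
    query: list[WaveformRecord],
    orientation: str = "reference_minus_query",
) -> dict[tuple[str, str, str], np.ndarray]:
    """Node-wise per-participant differences, keyed by (subject, joint, side).

    Records are matched by (subject, joint, side); a mismatch between the
    two sets is an error.  ``orientation`` may be flipped to
    "query_minus_reference".
    """
    if orientation not in ("reference_minus_query", "query_minus_reference"):
        raise ValueError(f"unknown orientation {orientation!r}")
    ref_map = {(w.subject_id, w.joint, w.side): w for w in reference}
    qry_map = {(w.subject_id, w.joint, w.side): w for w in query}
    if set(ref_map) != set(qry_map):
        missing = set(ref_map) ^ set(qry_map)
        raise ValueError(f"waveform sets do not match; unpaired keys: {sorted(missing)}")
    sign = 1.0 if orientation == "reference_minus_query" else -1.0
    return {
        key: sign * (ref_map[key].values - qry_map[key].values) for key in sorted(ref_map)
    }


@dataclass
class PairedScalarTest:
    """Paired t-test result on per-subject scalars."""

    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_two_sided: float
    ci95: tuple[float, float]


def paired_ttest(x, y, orientation: str = "x_minus_y") -> PairedScalarTest:
    """Two-sided paired t-test on subject-paired scalars.

    Differences are ``x - y`` (or ``y - x`` with the flipped orientation);
    t = mean / (sd / sqrt(n)) with the sample sd (n-1 denominator), p from
    the t distribution with n-1 df, and the 95% CI from the t quantile.
    A fully degenerate zero-difference sample yields t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if orientation == "x_minus_y":
        d = x - y
    elif orientation == "y_minus_x":
        d = y - x
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    se = sd / np.sqrt(n)
    if sd == 0:
        t_stat = 0.0 if mean == 0 else np.inf * np.sign(mean)
    else:
        t_stat = mean / se
    p = float(2.0 * stats.t.sf(abs(t_stat), df)) if np.isfinite(t_stat) else 0.0
    half = stats.t.ppf(0.975, df) * se
    return PairedScalarTest(
        n, mean, sd, float(t_stat), df, p, (mean - half, mean + half)
    )
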