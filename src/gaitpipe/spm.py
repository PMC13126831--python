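"""One-dimensional statistical parametric mapping over the gait cycle.

A pointwise t statistic is computed at each of the 101 nodes of the 0-100%
gait-cycle domain, and the familywise critical threshold t* is obtained
from random field theory (RFT): the estimated smoothness (FWHM, in nodes)
of the normalized residual field converts the domain into ``resels =
(n_nodes - 1) / fwhm`` resolution elements, and t* solves the 1D
Euler-characteristic expectation for t fields

    P(max t > u)  ~  S_nu(u) + resels * (sqrt(4 ln 2) / (2 pi))
                                * (1 + u^2 / nu) ** (-(nu - 1) / 2)

where ``S_nu`` is the t survival function with nu degrees of freedom.
Two-tailed inference thresholds |t| at alpha/2.  Supra-threshold clusters
(maximal runs of |t| > t*) are reported with extent and peak |t|; a
seeded permutation alternative (sign flips for one-sample designs, label
shuffles for two-sample) provides a nonparametric threshold when the
Gaussian random-field assumptions are in doubt.

Smoothness is estimated with the standard gradient-based estimator: on
unit-variance residuals, ``fwhm = sqrt(4 ln 2 / mean squared node-to-node
gradient)`` (one-sided differences at the domain endpoints).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_SQRT_4LN2 = np.sqrt(4.0 * np.log(2.0))


@dataclass
class TField:
    """Pointwise t statistic field with its estimated smoothness."""

    t: np.ndarray
    df: int
    fwhm: float

    @property
    def resels(self) -> float:
        return (len(self.t) - 1) / self.fwhm


@dataclass
class SPMResult:
    field: TField
    alpha: float
    t_star: float
    clusters: list[tuple[int, int, int, float]]  # (start, end, extent, max |t|)

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _estimate_fwhm(residuals: np.ndarray, sd: np.ndarray) -> float:
    """Gradient-based smoothness of the residual field, in nodes."""
    normalized = residuals / sd
    gradients = np.gradient(normalized, axis=1)
    msg = float(np.mean(gradients**2))
    if msg == 0.0:
        return np.inf
    return float(np.sqrt(4.0 * np.log(2.0) / msg))


def one_sample_t_field(diffs: np.ndarray) -> TField:
    """One-sample (paired) t field over subject-level waveforms.

    ``diffs`` is (n_subjects, n_nodes); t(q) = mean_q / (sd_q / sqrt(n)),
    df = n - 1.  A zero-variance node is an error (named).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_nodes) array")
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero variance at node(s) {zero.tolist()[:5]}")
    t = mean / (sd / np.sqrt(n))
    fwhm = _estimate_fwhm(diffs - mean, sd)
    return TField(t, n - 1, fwhm)


def two_sample_t_field(group_a: np.ndarray, group_b: np.ndarray) -> TField:
    """Pooled-variance two-sample t field, df = nA + nB - 2.

    Positive t means group A exceeds group B; swapping groups negates the
    field.  Smoothness comes from the pooled within-group residuals.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2D with matching node counts")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    df = na + nb - 2
    pooled_var = (
        (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
    ) / df
    zero = np.flatnonzero(pooled_var == 0)
    if len(zero):
        raise ValueError(f"zero variance at node(s) {zero.tolist()[:5]}")
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    residuals = np.vstack([a - mean_a, b - mean_b])
    fwhm = _estimate_fwhm(residuals, np.sqrt(pooled_var))
    return TField(t, df, fwhm)


def _excursion_probability(u: float, df: int, resels: float) -> float:
    """1D Euler-characteristic expectation for a t field above u."""
    tail = stats.t.sf(u, df)
    density = (_SQRT_4LN2 / (2.0 * np.pi)) * (1.0 + u**2 / df) ** (-(df - 1) / 2.0)
    return tail + resels * density


def rft_threshold(field: TField, alpha: float = 0.05, two_tailed: bool = True) -> float:
    """Critical threshold t* at familywise level alpha via RFT, solved by
    root finding to 1e-6.  In the zero-resel limit this reduces to the
    pointwise t quantile."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    target = alpha / 2.0 if two_tailed else alpha
    resels = field.resels
    if resels < 0:
        raise ValueError("resels must be non-negative")
    f = lambda u: _excursion_probability(u, field.df, resels) - target
    lo, hi = 0.0, 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"alpha={alpha} unattainable for this field")
    if f(lo) < 0:
        raise ValueError(f"alpha={alpha} unattainable for this field")
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _clusters(t: np.ndarray, t_star: float) -> list[tuple[int, int, int, float]]:
    """Maximal runs of |t| > t_star as (start, end, extent, max |t|)."""
    above = np.abs(t) > t_star
    clusters = []
    i = 0
    n = len(t)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            clusters.append((i, j, j - i + 1, float(np.abs(t[i : j + 1]).max())))
            i = j + 1
        else:
            i += 1
    return clusters


def spm_test(
    data,
    design: str = "one_sample",
    alpha: float = 0.05,
    two_tailed: bool = True,
) -> SPMResult:
    """Assemble a full SPM inference: t field, RFT threshold, clusters.

    ``data`` is a (n, nodes) array for the one-sample design, or a tuple of
    two such arrays for the two-sample design.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if design == "one_sample":
        field = one_sample_t_field(data)
    elif design == "two_sample":
        field = two_sample_t_field(*data)
    else:
        raise ValueError(f"unknown design {design!r}")
    t_star = rft_threshold(field, alpha, two_tailed)
    return SPMResult(field, alpha, t_star, _clusters(field.t, t_star))


def permutation_threshold(
    data,
    design: str = "one_sample",
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Nonparametric critical threshold: the (1 - alpha) quantile of the
    max-|t| distribution under sign flips (one-sample) or group-label
    shuffles (two-sample), with a fixed seed."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_permutations < max(100, int(np.ceil(10.0 / alpha))):
        raise ValueError(
            f"n_permutations={n_permutations} too small for alpha={alpha}"
        )
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations)
    if design == "one_sample":
        diffs = np.asarray(data, dtype=float)
        n = diffs.shape[0]
        sq_sum = (diffs**2).sum(axis=0)
        for k in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)
            mean = (signs[:, None] * diffs).mean(axis=0)
            var = (sq_sum - n * mean**2) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / np.sqrt(var / n)
            maxima[k] = np.nanmax(np.abs(t)) if np.any(np.isfinite(t)) else 0.0
    elif design == "two_sample":
        a, b = (np.asarray(g, dtype=float) for g in data)
        pooled = np.vstack([a, b])
        na = a.shape[0]
        for k in range(n_permutations):
            perm = rng.permutation(pooled.shape[0])
            pa, pb = pooled[perm[:na]], pooled[perm[na:]]
            try:
                t = two_sample_t_field(pa, pb).t
            except ValueError:
                t = np.zeros(pooled.shape[1])
            maxima[k] = np.abs(t).max()
    else:
        raise ValueError(f"unknown design {design!r}")
    if np.all(maxima == 0):
        logger.warning("degenerate permutation distribution; threshold set to 0")
        return 0.0
    return float(np.quantile(maxima, 1.0 - alpha))
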