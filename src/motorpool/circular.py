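"""Circular descriptive statistics and angular hypothesis tests.

Phase estimates from coherency analysis are directions on the circle, one
per animal. This module provides the circular mean with a 95% confidence
interval, the paired-sample Hotelling test for a shift in paired angles
(pre/post drug or stimulation), and the Watson-Williams F-test for equality
of mean directions across independent groups (e.g. genotypes).

The paired test follows the standard second-order construction for paired
circular data (Zar, Biostatistical Analysis): each pair contributes a
rectangular difference vector (cos a - cos b, sin a - sin b), and a
one-sample Hotelling T-squared tests whether the mean difference vector is
(0, 0); under the null (n-2)/(2(n-1)) * T^2 ~ F(2, n-2).

The Watson-Williams test uses the classical concentration-corrected F
statistic; the correction assumes reasonably concentrated samples, so a
warning flag is set when the pooled mean resultant length drops below 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .angles import wrap_degrees

__all__ = [
    "AngleSample",
    "PairedAngleSample",
    "CircularSummary",
    "CircularTestResult",
    "circular_mean",
    "hotelling_paired_test",
    "watson_williams_test",
]


@dataclass
class AngleSample:
    """Directions in degrees, one per animal/preparation."""

    angles: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if arr.size < 1:
            raise ValueError("AngleSample needs n >= 1 angles")
        if not np.all(np.isfinite(arr)):
            raise ValueError("angles must be finite")
        self.angles = wrap_degrees(arr)

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass
class PairedAngleSample:
    """Two angle samples with matched ordering of animals."""

    condition_a: AngleSample
    condition_b: AngleSample

    def __post_init__(self) -> None:
        if self.condition_a.n != self.condition_b.n:
            raise ValueError("paired samples must have equal length")

    @property
    def n(self) -> int:
        return self.condition_a.n


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction, mean resultant length and 95% CI half-width.

    ``mean_direction`` is NaN and ``mean_defined`` False when the resultant
    length is numerically zero; ``ci95_halfwidth`` is None when the
    resultant-length-based CI formula does not apply (too dispersed).
    """

    mean_direction: float
    resultant_length: float
    ci95_halfwidth: float | None
    n: int
    mean_defined: bool = True


@dataclass(frozen=True)
class CircularTestResult:
    test_name: str
    statistic: float
    df: tuple[int, int]
    p_value: float
    flags: tuple[str, ...] = ()


def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """(mean direction in degrees, mean resultant length r-bar)."""
    rad = np.radians(angles_deg)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    return float(np.degrees(np.arctan2(s, c))), float(np.hypot(c, s))


def _ci95_halfwidth(n: int, rbar: float) -> float | None:
    """95% CI half-width for the mean direction (Fisher/Zar, chi-square form).

    Returns None when the formula is inapplicable (sample too dispersed for
    the stated resultant length).
    """
    if n < 2 or rbar <= 0:
        return None
    R = n * rbar
    chi = stats.chi2.ppf(0.95, 1)
    if rbar <= 0.9:
        num = 2.0 * n * (2.0 * R**2 - n * chi)
        den = 4.0 * n - chi
        if num <= 0:
            return None
        arg = np.sqrt(num / den) / R
    else:
        inner = n**2 - (n**2 - R**2) * np.exp(chi / n)
        if inner <= 0:
            return None
        arg = np.sqrt(inner) / R
    if arg > 1.0:
        arg = 1.0
    return float(np.degrees(np.arccos(arg)))


def circular_mean(sample: AngleSample) -> CircularSummary:
    """Circular mean direction with resultant length and 95% CI."""
    mean_dir, rbar = _resultant(sample.angles)
    if rbar < 1e-12 and sample.n > 1:
        return CircularSummary(
            mean_direction=float("nan"),
            resultant_length=0.0,
            ci95_halfwidth=None,
            n=sample.n,
            mean_defined=False,
        )
    return CircularSummary(
        mean_direction=wrap_degrees(mean_dir),
        resultant_length=rbar,
        ci95_halfwidth=_ci95_halfwidth(sample.n, rbar),
        n=sample.n,
    )


def hotelling_paired_test(sample: PairedAngleSample) -> CircularTestResult:
    """Paired-sample test for an angular shift between two conditions.

    Rejects when the mean rectangular difference vector across pairs departs
    from the origin. Degenerate difference covariance (all pairs identical)
    reports p = 1 with a ``"degenerate"`` flag instead of raising, so that
    multi-segment pipelines survive pathological pairs.
    """
    n = sample.n
    if n < 3:
        raise ValueError(f"paired Hotelling test needs n >= 3, got {n}")
    a = np.radians(sample.condition_a.angles)
    b = np.radians(sample.condition_b.angles)
    d = np.column_stack([np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)])
    mean_d = d.mean(axis=0)
    if np.max(np.abs(d)) < 1e-12:
        return CircularTestResult(
            "hotelling-paired", 0.0, (2, n - 2), 1.0, ("degenerate",)
        )
    cov = np.cov(d, rowvar=False, ddof=1)
    scale = float(np.trace(cov))
    if scale <= 0 or np.linalg.det(cov) < 1e-14 * max(scale, 1.0) ** 2:
        return CircularTestResult(
            "hotelling-paired", 0.0, (2, n - 2), 1.0, ("degenerate",)
        )
    t2 = float(n * mean_d @ np.linalg.solve(cov, mean_d))
    f_stat = (n - 2) / (2.0 * (n - 1)) * t2
    p = float(stats.f.sf(f_stat, 2, n - 2))
    return CircularTestResult("hotelling-paired", f_stat, (2, n - 2), p)


def _kappa_ml(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant
    length (Fisher's piecewise approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams_test(groups: list[AngleSample]) -> CircularTestResult:
    """Watson-Williams F-test for equality of mean directions across groups.

    Sets a ``"low-concentration"`` flag (p still returned) when the weighted
    mean resultant length falls below the conventional 0.45 validity bound.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 3:
            raise ValueError("each group needs n >= 3")
    N = sum(g.n for g in groups)
    R_groups = []
    cs_total = np.zeros(2)
    for g in groups:
        rad = np.radians(g.angles)
        c, s = np.sum(np.cos(rad)), np.sum(np.sin(rad))
        R_groups.append(float(np.hypot(c, s)))
        cs_total += (c, s)
    sum_R = float(np.sum(R_groups))
    R_all = float(np.hypot(*cs_total))
    rbar_w = sum_R / N
    flags: tuple[str, ...] = ()
    if rbar_w < 0.45:
        flags = ("low-concentration",)
    kappa = _kappa_ml(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - sum_R
    if denom <= 0:  # all angles within each group identical
        f_stat = float("inf") if sum_R - R_all > 1e-12 else 0.0
        p = 0.0 if np.isinf(f_stat) else 1.0
        return CircularTestResult(
            "watson-williams", f_stat, (k - 1, N - k), p, flags + ("degenerate",)
        )
    f_stat = correction * ((N - k) * (sum_R - R_all)) / ((k - 1) * denom)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, k - 1, N - k))
    return CircularTestResult("watson-williams", float(f_stat), (k - 1, N - k), p, flags)
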