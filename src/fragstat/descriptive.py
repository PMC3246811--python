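"""Linear and circular descriptive statistics.

Torsion angles are periodic: by chemical convention they live on
−180° … +180°, and the arithmetic mean of a distribution centred on the
±180° seam is meaningless (two values 175° and −175° average to 0°).  The
circular functions here work on the mean resultant vector instead:

    C = (1/n) Σ cos θᵢ,  S = (1/n) Σ sin θᵢ,
    R = √(C² + S²),      μ = atan2(S, C),

with circular variance V = 1 − R, circular standard deviation
σ = √(−2 ln R), and second-trigonometric-moment skewness and kurtosis as
defined in the circular-statistics literature.  All interfaces take and
return degrees; mean directions are reported on [−180°, 180°) with −180°
canonical for the seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LinearSummary",
    "CircularSummary",
    "linear_summary",
    "circular_mean",
    "circular_summary",
    "circular_median",
    "wrap_degrees",
    "circular_distance",
]

#: resultant lengths below this leave the mean direction undefined
R_UNDEFINED_EPS = 1e-12

DEFAULT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def wrap_degrees(angle, period: float = 360.0):
    """Wrap angle(s) into [−period/2, period/2); −period/2 is canonical."""
    a = np.asarray(angle, dtype=float)
    half = period / 2.0
    wrapped = np.mod(a + half, period) - half
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_distance(a, b, period: float = 360.0):
    """Shortest-arc distance |a − b| on the circle, in degrees (≥ 0)."""
    return np.abs(wrap_degrees(np.asarray(a, float) - np.asarray(b, float), period))


@dataclass
class LinearSummary:
    """Moment/quantile summary of an ordinary real-valued descriptor.

    ``variance`` is the unbiased sample variance (divisor n−1) and ``sem``
    the standard deviation of the mean, √(variance/n).  Skewness is the
    moment coefficient g₁ = m₃/m₂^{3/2} and kurtosis the excess
    g₂ = m₄/m₂² − 3, both from central *sample* moments.  Undefined
    quantities (n < 2 for spread, n < 2 for shape) are NaN, never zero.
    """

    n: int
    mean: float
    variance: float
    sem: float
    median: float
    quantiles: Mapping[float, float]
    skewness: float
    kurtosis: float
    minimum: float
    maximum: float


def _clean(values) -> np.ndarray:
    v = np.asarray(getattr(values, "values", values), dtype=float).ravel()
    return v[~np.isnan(v)]


def linear_summary(
    values, quantiles: Sequence[float] = DEFAULT_QUANTILES
) -> LinearSummary:
    """Summarise a numeric sample (missing values already excluded).

    Quantiles interpolate linearly between order statistics at position
    (n−1)·q, so quantile(0) is the minimum and quantile(1) the maximum.
    """
    v = _clean(values)
    n = v.size
    if n == 0:
        raise ValueError("empty input: need at least one non-missing value")
    mean = float(v.mean())
    if n >= 2:
        variance = float(v.var(ddof=1))
        sem = math.sqrt(variance / n)
    else:
        variance = math.nan
        sem = math.nan
    centred = v - mean
    m2 = float(np.mean(centred**2))
    if n >= 2 and m2 > 0:
        skewness = float(np.mean(centred**3)) / m2**1.5
        kurtosis = float(np.mean(centred**4)) / m2**2 - 3.0
    else:
        skewness = math.nan
        kurtosis = math.nan
    qmap = {float(q): float(np.quantile(v, q)) for q in quantiles}
    return LinearSummary(
        n=n,
        mean=mean,
        variance=variance,
        sem=sem,
        median=float(np.quantile(v, 0.5)),
        quantiles=qmap,
        skewness=skewness,
        kurtosis=kurtosis,
        minimum=float(v.min()),
        maximum=float(v.max()),
    )


@dataclass
class CircularSummary:
    """Resultant-vector summary of a periodic (torsion-like) descriptor.

    Angles in degrees.  ``mean_direction`` lies on [−180, 180); when the
    resultant length R vanishes (e.g. antipodal data) the mean direction is
    undefined: ``mean_undefined`` is set and ``mean_direction`` is NaN.
    ``circ_std`` is √(−2 ln R) expressed in degrees (+∞ at R = 0).
    ``circ_skewness``/``circ_kurtosis`` are the uncorrected second
    trigonometric moments about μ, b = mean sin 2(θ−μ) and
    k = mean cos 2(θ−μ); the bias-corrected variants built from the second
    central trigonometric moment are exposed separately as
    ``circ_skewness_corrected``/``circ_kurtosis_corrected``.
    """

    n: int
    mean_direction: float
    resultant_length: float
    circ_variance: float
    circ_std: float
    circ_skewness: float
    circ_kurtosis: float
    circ_skewness_corrected: float = math.nan
    circ_kurtosis_corrected: float = math.nan
    mean_undefined: bool = False
    circ_median: float = math.nan


def circular_mean(angles) -> tuple[float, float]:
    """Mean direction μ and resultant length R of angles in degrees.

    Returns ``(μ, R)`` with μ on [−180, 180).  When R < 1e−12 the mean
    direction is undefined and μ is NaN; R is still returned.
    """
    v = _clean(angles)
    if v.size == 0:
        raise ValueError("empty input: need at least one angle")
    rad = np.deg2rad(v)
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    r = math.hypot(c, s)
    if r < R_UNDEFINED_EPS:
        return math.nan, r
    mu = wrap_degrees(math.degrees(math.atan2(s, c)))
    return mu, r


def circular_summary(angles) -> CircularSummary:
    """Full circular summary of a torsion-like sample (degrees, n ≥ 2)."""
    v = _clean(angles)
    if v.size < 2:
        raise ValueError("circular summary requires at least two angles")
    mu, r = circular_mean(v)
    variance = 1.0 - r
    if r < R_UNDEFINED_EPS:
        return CircularSummary(
            n=v.size,
            mean_direction=math.nan,
            resultant_length=r,
            circ_variance=1.0,
            circ_std=math.inf,
            circ_skewness=math.nan,
            circ_kurtosis=math.nan,
            mean_undefined=True,
            circ_median=circular_median(v),
        )
    sigma = math.degrees(math.sqrt(-2.0 * math.log(r))) if r > 0 else math.inf
    dev = np.deg2rad(v - mu)
    b = float(np.mean(np.sin(2.0 * dev)))
    k = float(np.mean(np.cos(2.0 * dev)))
    # second trigonometric moment of the raw angles, for the corrected forms
    rad2 = 2.0 * np.deg2rad(v)
    c2, s2 = float(np.mean(np.cos(rad2))), float(np.mean(np.sin(rad2)))
    rho2 = math.hypot(c2, s2)
    mu2 = math.atan2(s2, c2)
    mu_rad = math.radians(mu)
    if variance > 0:
        b0 = rho2 * math.sin(mu2 - 2.0 * mu_rad) / variance**1.5
        k0 = (rho2 * math.cos(mu2 - 2.0 * mu_rad) - r**4) / variance**2
    else:
        b0 = math.nan
        k0 = math.nan
    return CircularSummary(
        n=v.size,
        mean_direction=mu,
        resultant_length=r,
        circ_variance=variance,
        circ_std=sigma,
        circ_skewness=b,
        circ_kurtosis=k,
        circ_skewness_corrected=b0,
        circ_kurtosis_corrected=k0,
        mean_undefined=False,
        circ_median=circular_median(v),
    )


def circular_median(angles, period: float = 360.0) -> float:
    """Circular median: the data point minimising mean shortest-arc deviation.

    Ties are broken by the smallest angle on [−period/2, period/2).  O(n²);
    geometry tables are small enough that this is never a bottleneck.
    """
    v = _clean(angles)
    if v.size == 0:
        raise ValueError("empty input: need at least one angle")
    scale = 360.0 / period
    srt = np.sort(wrap_degrees(v * scale))  # work in degrees on [-180, 180)
    n = srt.size
    cs = np.concatenate(([0.0], np.cumsum(srt)))
    c = srt
    # partition the sorted angles by which side of the circle is shorter:
    # [0,i1) wraps up past -180, [i1,i2] lies below c, (i2,i3) above,
    # [i3,n) wraps down past +180
    i1 = np.searchsorted(srt, c - 180.0, side="left")
    i2 = np.searchsorted(srt, c, side="right")
    i3 = np.searchsorted(srt, c + 180.0, side="left")
    s1 = cs[i1] + (360.0 - c) * i1
    s2 = c * (i2 - i1) - (cs[i2] - cs[i1])
    s3 = (cs[i3] - cs[i2]) - c * (i3 - i2)
    s4 = (360.0 + c) * (n - i3) - (cs[n] - cs[i3])
    dev = (s1 + s2 + s3 + s4) / n
    best = np.min(dev)
    ties = c[np.isclose(dev, best, rtol=0, atol=1e-9)]
    return float(np.min(ties)) / scale
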