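"""Histograms, polar histograms and the cone-angle correction.

A histogram of hydrogen-bond D—H⋯A angles θ binned uniformly in θ is
geometrically biased: for a donor approaching an acceptor, the set of
orientations achieving a given θ is a cone whose measure is proportional to
sin θ, so exactly linear approaches (θ = 180°) are measure-zero and the raw
mode sits well below 180° even for strongly linear interactions.  Dividing
each bin frequency by sin θ (or, exactly, by the solid angle
cos θ_lo − cos θ_hi subtended by the bin) removes the bias and typically
moves the corrected mode to the 180° bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptive import wrap_degrees

__all__ = ["Histogram", "build_histogram", "build_circular_histogram", "cone_angle_correct"]


@dataclass
class Histogram:
    """Binned counts over strictly increasing edges.

    Bins are half-open [eᵢ, eᵢ₊₁) with the final bin closed, so the maximum
    lands in the last bin.  ``corrected`` holds cone-angle-corrected weights
    (same length as ``counts``) when the correction has been applied;
    ``n_excluded`` counts values outside the requested range (excluded, not
    clipped).
    """

    edges: np.ndarray
    counts: np.ndarray
    corrected: np.ndarray | None = None
    polar: bool = False
    units: str = ""
    n_excluded: int = 0
    correction_method: str | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.size != self.edges.size - 1:
            raise ValueError("len(counts) must equal len(edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mode_bin(self, use_corrected: bool = False) -> tuple[float, float]:
        """(lo, hi) edges of the highest bin (first on ties)."""
        w = self.corrected if (use_corrected and self.corrected is not None) else self.counts
        i = int(np.argmax(w))
        return float(self.edges[i]), float(self.edges[i + 1])


def build_histogram(values, bins=10, range=None, units: str = "") -> Histogram:
    """Bin a numeric sample.

    ``bins`` is a bin count or an explicit strictly increasing edge array;
    ``range`` restricts the span when a count is given.  Values outside the
    span are excluded and reported via ``n_excluded``.
    """
    v = np.asarray(getattr(values, "values", values), dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty input: nothing to bin")
    if np.isscalar(bins):
        if int(bins) < 1:
            raise ValueError("need at least one bin")
        lo, hi = range if range is not None else (float(v.min()), float(v.max()))
        if not hi > lo:
            hi = lo + 1.0  # degenerate sample: one unit-width bin
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(v, bins=edges)
    return Histogram(
        edges=edges,
        counts=counts,
        units=units,
        n_excluded=int(v.size - counts.sum()),
    )


def build_circular_histogram(angles, bins: int = 36) -> Histogram:
    """Polar histogram over [−180°, 180°) with uniform bins; angles wrapped."""
    if int(bins) < 2:
        raise ValueError("a polar histogram needs at least two bins")
    v = np.asarray(getattr(angles, "values", angles), dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty input: nothing to bin")
    wrapped = wrap_degrees(v)
    edges = np.linspace(-180.0, 180.0, int(bins) + 1)
    counts, _ = np.histogram(wrapped, bins=edges)
    return Histogram(edges=edges, counts=counts, polar=True, units="deg")


def cone_angle_correct(hist: Histogram, method: str = "midpoint-sine") -> Histogram:
    """Correct a θ histogram for the sin θ orientational bias.

    ``midpoint-sine`` divides each bin count by sin of the bin midpoint —
    the textbook rule — and fails when a midpoint sits exactly at 0° or
    180° where sin vanishes.  ``solid-angle`` divides by the exact measure
    cos θ_lo − cos θ_hi of the bin's cone and is safe at the boundaries.
    Either way the corrected weights are rescaled to preserve the total
    count, so raw and corrected histograms share a y-scale.
    """
    if hist.total == 0:
        raise ValueError("cannot correct an empty histogram")
    edges = hist.edges
    if edges[0] < -1e-9 or edges[-1] > 180.0 + 1e-9:
        raise ValueError("cone-angle correction applies to angles on [0°, 180°]")
    counts = hist.counts.astype(float)
    if method == "midpoint-sine":
        mids = hist.midpoints
        denom = np.sin(np.deg2rad(mids))
        if np.any(denom <= 1e-12):
            raise ValueError(
                "a bin midpoint lies at 0° or 180° where sin θ = 0; "
                "use method='solid-angle' instead"
            )
    elif method == "solid-angle":
        rad = np.deg2rad(edges)
        denom = np.cos(rad[:-1]) - np.cos(rad[1:])
    else:
        raise ValueError(f"unknown correction method {method!r}")
    weights = counts / denom
    weights *= counts.sum() / weights.sum()  # shape-preserving renormalisation
    return Histogram(
        edges=edges,
        counts=hist.counts,
        corrected=weights,
        polar=hist.polar,
        units=hist.units,
        n_excluded=hist.n_excluded,
        correction_method=method,
    )
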