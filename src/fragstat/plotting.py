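"""Static rendering of the analysis chart types to PNG/SVG files.

Supported kinds: histogram, polar_histogram, scatter, polar_scatter and
heatmap, plus PCA score plots.  Scatterplots can colour symbols on a
sequential heat scale by a third descriptor; hidden rows are never drawn
and an optional selection is overlaid in a highlight colour.  SVG output is
byte-deterministic for identical inputs, which is the surface the tests
compare; PNG is offered for convenience but not byte-compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data_model import GeometryTable, Selection
from .histograms import Histogram
from .pca import PCAResult

__all__ = ["PlotSpec", "render", "heatmap_bin"]

PLOT_KINDS = ("histogram", "polar_histogram", "scatter", "polar_scatter", "heatmap", "pca_scores")

# deterministic SVG: fixed hash salt, no embedded creation date
matplotlib.rcParams["svg.hashsalt"] = "fragstat"
_SAVEFIG_METADATA = {"svg": {"Date": None}, "png": {}}

HIGHLIGHT = "#d62728"


@dataclass
class PlotSpec:
    """Declarative description of one chart.

    ``x``/``y``/``colour`` name descriptors of the table (``colour``
    optional: maps a third variable onto the heat scale).  ``bins`` applies
    to histograms and heat maps.  ``colour_scale`` is any sequential
    matplotlib colormap name; the default is perceptually uniform.
    """

    kind: str
    x: str | None = None
    y: str | None = None
    colour: str | None = None
    bins: int = 20
    background: str = "white"
    xlabel: str | None = None
    ylabel: str | None = None
    title: str | None = None
    symbol: str = "o"
    colour_scale: str = "viridis"

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")


def heatmap_bin(
    table: GeometryTable, x: str, y: str, bins_x: int = 20, bins_y: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """2D count grid over two numeric descriptors.

    Returns ``(grid, x_edges, y_edges, n_excluded)`` with
    ``grid[i, j]`` the count in x-bin i, y-bin j; counts conserve the
    number of visible complete rows.  A degenerate range (max = min)
    falls back to a single bin with a warning.
    """
    vx = table.values(x)
    vy = table.values(y)
    both = ~np.isnan(vx) & ~np.isnan(vy)
    vx, vy = vx[both], vy[both]
    if vx.size == 0:
        raise ValueError("no complete rows to bin")

    def _edges(v: np.ndarray, bins: int) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        if not hi > lo:
            warnings.warn(
                "degenerate range (max = min): falling back to a single bin",
                stacklevel=3,
            )
            return np.array([lo - 0.5, lo + 0.5])
        return np.linspace(lo, hi, bins + 1)

    ex, ey = _edges(vx, bins_x), _edges(vy, bins_y)
    grid, _, _ = np.histogram2d(vx, vy, bins=[ex, ey])
    excluded = int(vx.size - grid.sum())
    return grid, ex, ey, excluded


def _scatter(ax, table, spec, selection, polar=False):
    vx = table.values(spec.x)
    vy = table.values(spec.y)
    keep = ~np.isnan(vx) & ~np.isnan(vy)
    colour_vals = None
    if spec.colour is not None:
        cv = table.values(spec.colour)
        keep &= ~np.isnan(cv)
        colour_vals = cv
    idx = np.flatnonzero(keep)
    if polar:
        # angular descriptor on the azimuth, paired linear one on the radius
        px, py = np.deg2rad(vx[idx]), vy[idx]
    else:
        px, py = vx[idx], vy[idx]
    if colour_vals is not None:
        sc = ax.scatter(
            px, py, c=colour_vals[idx], cmap=spec.colour_scale,
            marker=spec.symbol, s=18,
        )
        cb = ax.figure.colorbar(sc, ax=ax)
        cb.set_label(spec.colour)
    else:
        ax.scatter(px, py, marker=spec.symbol, s=18, color="#1f77b4")
    if selection is not None and selection.mask.any():
        hi = np.flatnonzero(keep & selection.mask & ~table.hidden)
        if hi.size:
            hx = np.deg2rad(vx[hi]) if polar else vx[hi]
            ax.scatter(hx, vy[hi], marker=spec.symbol, s=26,
                       facecolors="none", edgecolors=HIGHLIGHT, linewidths=1.2)


def _bar_hist(ax, hist: Histogram, polar: bool):
    widths = np.diff(hist.edges)
    if polar:
        ax.bar(np.deg2rad(hist.midpoints), hist.counts,
               width=np.deg2rad(widths), color="#1f77b4", edgecolor="black",
               linewidth=0.4, align="center")
    else:
        ax.bar(hist.edges[:-1], hist.counts, width=widths, align="edge",
               color="#1f77b4", edgecolor="black", linewidth=0.4,
               label="raw counts")
        if hist.corrected is not None:
            ax.step(hist.edges, np.append(hist.corrected, hist.corrected[-1]),
                    where="post", color=HIGHLIGHT, linewidth=1.4,
                    label=f"cone-angle corrected ({hist.correction_method})")
            ax.legend(frameon=False)


def render(
    obj: "GeometryTable | Histogram | PCAResult",
    spec: PlotSpec,
    path: str | Path,
    selection: Selection | None = None,
) -> Path:
    """Render one chart to ``path`` (extension .png or .svg).

    Pure with respect to its inputs: tables, selections and histograms are
    never mutated.  Hidden rows are not drawn; a non-empty ``selection`` is
    overlaid in the highlight colour.
    """
    path = Path(path)
    ext = path.suffix.lstrip(".").lower()
    if ext not in ("png", "svg"):
        raise ValueError(f"unsupported image format {ext!r} (use png or svg)")

    polar_axes = spec.kind in ("polar_histogram", "polar_scatter")
    fig = plt.figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111, polar=polar_axes)
    ax.set_facecolor(spec.background)

    if spec.kind in ("histogram", "polar_histogram"):
        if isinstance(obj, Histogram):
            hist = obj
        else:
            from .histograms import build_circular_histogram, build_histogram

            vals = obj.values(spec.x)
            hist = (
                build_circular_histogram(vals, spec.bins)
                if spec.kind == "polar_histogram"
                else build_histogram(vals, spec.bins)
            )
        _bar_hist(ax, hist, polar=polar_axes)
    elif spec.kind in ("scatter", "polar_scatter"):
        if not isinstance(obj, GeometryTable):
            raise TypeError("scatter plots need a GeometryTable")
        _scatter(ax, obj, spec, selection, polar=polar_axes)
    elif spec.kind == "heatmap":
        if not isinstance(obj, GeometryTable):
            raise TypeError("heat maps need a GeometryTable")
        grid, ex, ey, _ = heatmap_bin(obj, spec.x, spec.y, spec.bins, spec.bins)
        mesh = ax.pcolormesh(ex, ey, grid.T, cmap=spec.colour_scale)
        fig.colorbar(mesh, ax=ax, label="count")
    elif spec.kind == "pca_scores":
        if not isinstance(obj, PCAResult):
            raise TypeError("pca_scores plots need a PCAResult")
        s = obj.scores
        ax.scatter(s[:, 0], s[:, 1], marker=spec.symbol, s=18, color="#1f77b4")
        if selection is not None and selection.mask.any():
            in_fit = np.isin(obj.row_indices, np.flatnonzero(selection.mask))
            ax.scatter(s[in_fit, 0], s[in_fit, 1], marker=spec.symbol, s=26,
                       facecolors="none", edgecolors=HIGHLIGHT, linewidths=1.2)
        # axis labels carry the explained-variance percentage in brackets
        ax.set_xlabel(f"PC1 ({obj.pct_variance[0]:.2f}%)")
        ax.set_ylabel(f"PC2 ({obj.pct_variance[1]:.2f}%)")

    if spec.kind != "pca_scores" and not polar_axes:
        if spec.xlabel or spec.x:
            ax.set_xlabel(spec.xlabel or spec.x)
        if spec.ylabel or spec.y:
            ax.set_ylabel(spec.ylabel or spec.y)
    if spec.title:
        ax.set_title(spec.title)
    fig.savefig(path, format=ext, metadata=_SAVEFIG_METADATA[ext] or None)
    plt.close(fig)
    return path
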