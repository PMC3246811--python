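"""Principal components analysis of geometry-descriptor matrices.

PCA rotates a set of correlated descriptors (e.g. the five endocyclic
torsions of a furanose ring) into uncorrelated, mutually orthogonal
components ordered by explained variance.  For five-membered-ring torsions
the pseudorotation model τⱼ = τₘ·cos(P + 144°·j) confines the data to an
exact 2-plane, so the first two components carry essentially all of the
conformational variance and the PC1–PC2 score plot separates the ring
pucker clusters (C2′-endo vs C3′-endo for furanosides); points between
clusters are unusual conformers worth inspecting individually.

Torsions straddling the ±180° seam would corrupt a naive linear PCA; the
``unwrap`` option re-expresses each circular column within half a period of
its own circular mean direction before centring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import GeometryTable, Selection
from .descriptive import circular_mean, wrap_degrees

__all__ = ["PCAResult", "run_pca", "project", "flag_outliers"]


@dataclass
class PCAResult:
    """Eigendecomposition of a descriptor covariance/correlation matrix.

    ``loadings`` has orthonormal columns (one per component), eigenvalues
    are sorted non-increasing, and ``scores`` are the centred (and, in
    correlation mode, scaled) data expressed in the component basis.  Sign
    convention: the largest-magnitude entry of each loading column is
    positive, making output deterministic across platforms.
    """

    columns: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    mode: str
    circular_centres: dict[str, float] = field(default_factory=dict)
    row_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_rows_total: int = 0
    n_dropped: int = 0
    n_le_p_warning: bool = False

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _unwrap_column(values: np.ndarray, period: float) -> tuple[np.ndarray, float]:
    """Shift periodic values to within ±period/2 of their circular mean."""
    scale = 360.0 / period
    mu, _ = circular_mean(values * scale)
    mu /= scale
    if np.isnan(mu):
        mu = 0.0
    return mu + wrap_degrees((values - mu) * scale) / scale, mu


def run_pca(
    table: GeometryTable,
    columns: Sequence[str],
    mode: str | None = None,
    circular_handling: str = "unwrap",
) -> PCAResult:
    """PCA over the chosen linear/circular descriptors.

    Parameters
    ----------
    mode : {"covariance", "correlation"}, optional
        ``covariance`` analyses the raw covariance of the centred columns,
        ``correlation`` additionally divides each column by its standard
        deviation.  Default: covariance when all chosen columns share units
        (e.g. five torsions in degrees), correlation otherwise.
    circular_handling : {"unwrap", "raw"}
        ``unwrap`` re-expresses each circular column within ±period/2 of its
        circular mean before centring; ``raw`` uses values as stored.

    Rows with a missing value in any chosen column (or hidden rows) are
    dropped listwise; the count is recorded on the result.
    """
    if len(columns) < 2:
        raise ValueError("PCA needs at least two descriptor columns")
    if circular_handling not in ("unwrap", "raw"):
        raise ValueError(f"unknown circular_handling {circular_handling!r}")
    descs = [table.descriptor(c) for c in columns]
    for d in descs:
        if d.kind not in ("linear", "circular"):
            raise TypeError(f"column {d.name!r} is {d.kind}; PCA needs numeric kinds")
    if mode is None:
        mode = "covariance" if len({d.units for d in descs}) == 1 else "correlation"
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown mode {mode!r}")

    raw = np.column_stack([table.values(c) for c in columns])
    complete = ~np.isnan(raw).any(axis=1)
    rows = np.flatnonzero(complete)
    x = raw[complete].copy()
    n, p = x.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 complete rows; got {n}")

    circ_centres: dict[str, float] = {}
    for j, d in enumerate(descs):
        if d.kind == "circular" and circular_handling == "unwrap":
            x[:, j], circ_centres[d.name] = _unwrap_column(x[:, j], d.period)

    means = x.mean(axis=0)
    if mode == "correlation":
        scales = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column in correlation mode: {columns[zero[0]]!r}"
            )
    else:
        scales = np.ones(p)
    z = (x - means) / scales

    cov = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|entry| of each loading made positive
    for j in range(p):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]

    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.full(p, np.nan)
    n_le_p = n <= p
    if n_le_p:
        warnings.warn(
            f"n = {n} rows <= p = {p} columns: covariance is rank-deficient",
            stacklevel=2,
        )
    return PCAResult(
        columns=list(columns),
        loadings=evecs,
        scores=z @ evecs,
        eigenvalues=evals,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        column_means=means,
        column_scales=scales,
        mode=mode,
        circular_centres=circ_centres,
        row_indices=rows,
        n_rows_total=table.n_rows,
        n_dropped=int(table.n_rows - n),
        n_le_p_warning=n_le_p,
    )


def project(result: PCAResult, new_rows, columns: Sequence[str] | None = None) -> np.ndarray:
    """Project new observations into the fitted component basis.

    ``new_rows`` is an (m, p) array (or a single row) over the same columns
    in the same order; circular columns are unwrapped with the *stored*
    circular centres so projections are consistent with the fit.
    """
    if columns is not None and list(columns) != result.columns:
        raise ValueError(
            f"column mismatch: expected {result.columns}, got {list(columns)}"
        )
    x = np.atleast_2d(np.asarray(new_rows, dtype=float)).copy()
    if x.shape[1] != len(result.columns):
        raise ValueError(
            f"expected {len(result.columns)} columns, got {x.shape[1]}"
        )
    for j, name in enumerate(result.columns):
        if name in result.circular_centres:
            mu = result.circular_centres[name]
            x[:, j] = mu + wrap_degrees(x[:, j] - mu)
    z = (x - result.column_means) / result.column_scales
    return z @ result.loadings


def reconstruct(result: PCAResult, scores: np.ndarray) -> np.ndarray:
    """Back-transform full-rank scores to the original descriptor space."""
    z = np.atleast_2d(scores) @ result.loadings.T
    return z * result.column_scales + result.column_means


def flag_outliers(
    result: PCAResult,
    k: int = 2,
    threshold: float = np.inf,
    centres: Sequence[Sequence[float]] | None = None,
) -> Selection:
    """Select rows far from every declared cluster centre in score space.

    Distance is Euclidean in the first ``k`` components, measured from the
    nearest of the user-declared cluster ``centres`` (each a length-k score
    vector); with no centres, from the score-space origin.  Returns a
    full-length row selection over the originating table (rows dropped from
    the fit are never flagged).
    """
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k must be between 1 and {result.n_components}")
    s = result.scores[:, :k]
    if centres is None:
        dist = np.linalg.norm(s, axis=1)
    else:
        cen = np.atleast_2d(np.asarray(centres, dtype=float))
        if cen.shape[1] != k:
            raise ValueError(f"cluster centres must have {k} coordinates")
        dist = np.min(
            np.linalg.norm(s[:, None, :] - cen[None, :, :], axis=2), axis=1
        )
    mask = np.zeros(result.n_rows_total, dtype=bool)
    mask[result.row_indices[dist > threshold]] = True
    return Selection(mask)
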