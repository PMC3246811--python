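"""Correlation, covariance and selected-vs-rest significance testing.

The association matrix reports Pearson correlation, Spearman rank
correlation (Pearson on mid-ranks, ties averaged) or unbiased covariance
for every descriptor pair, on pairwise complete cases with the per-pair n
recorded so imbalance is visible.

The hypothesis test is the classic pooled-variance two-sample Student
t-test of a selection against its complement:

    H0: μ1 = μ2    vs    H1: μ1 ≠ μ2

with μ1 the mean of the selected rows and μ2 the mean of the rest, at a
user-fixed significance level α.  The two-sided p value is always reported
so the user can weigh the evidence themselves.  No multiple-testing
correction is applied when several descriptors are tested; p values are
per-descriptor and raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import GeometryTable, PooledColumn, Selection

__all__ = [
    "AssociationMatrix",
    "TestResult",
    "association_matrix",
    "two_sample_ttest",
    "pooled_ttest",
]


@dataclass
class AssociationMatrix:
    """Symmetric pairwise association of named descriptors.

    ``values[i, j]`` is the statistic between ``labels[i]`` and
    ``labels[j]``; ``n_used[i, j]`` the number of complete cases behind it.
    Correlation entries of a zero-variance column are NaN (undefined);
    its covariance entries are 0.
    """

    labels: list[str]
    values: np.ndarray
    method: str
    n_used: np.ndarray

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class TestResult:
    """Outcome of the selected-vs-rest pooled two-sample t-test."""

    descriptor: str
    mean_selected: float
    mean_rest: float
    n_selected: int
    n_rest: int
    t_statistic: float
    df: int
    p_value: float
    alpha: float
    reject: bool

    def summary(self) -> str:
        verdict = "REJECT H0" if self.reject else "retain H0"
        return (
            f"{self.descriptor}: mu1={self.mean_selected:.4g} (n={self.n_selected})"
            f"  mu2={self.mean_rest:.4g} (n={self.n_rest})"
            f"  t={self.t_statistic:.4g}  df={self.df}"
            f"  p={self.p_value:.4g}  alpha={self.alpha:g}  -> {verdict}"
        )


def _pair_stat(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "covariance":
        return float(np.cov(x, y, ddof=1)[0, 1])
    if method == "spearman":
        x = stats.rankdata(x)  # mid-ranks, ties averaged
        y = stats.rankdata(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def association_matrix(
    table: GeometryTable,
    columns: Sequence[str],
    method: str = "pearson",
) -> AssociationMatrix:
    """Pairwise association over the named numeric descriptors.

    Pairwise complete-case: each entry uses the rows where *both* columns
    are present (and not hidden), needing at least 3 such rows.
    """
    if method not in ("pearson", "spearman", "covariance"):
        raise ValueError(f"unknown method {method!r}")
    if len(columns) < 2:
        raise ValueError("need at least two columns")
    cols = [table.values(c) for c in columns]
    p = len(columns)
    vals = np.full((p, p), np.nan)
    n_used = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i, p):
            both = ~np.isnan(cols[i]) & ~np.isnan(cols[j])
            n = int(both.sum())
            n_used[i, j] = n_used[j, i] = n
            if n < 3:
                raise ValueError(
                    f"pair ({columns[i]!r}, {columns[j]!r}) has only {n} "
                    "complete cases; need at least 3"
                )
            x, y = cols[i][both], cols[j][both]
            if i == j:
                if method == "covariance":
                    v = float(np.var(x, ddof=1))
                else:
                    v = 1.0 if np.std(x) > 0 else math.nan
            else:
                v = _pair_stat(x, y, method)
                if method == "covariance" and (np.std(x) == 0 or np.std(y) == 0):
                    v = 0.0
            vals[i, j] = vals[j, i] = v
    return AssociationMatrix(list(columns), vals, method, n_used)


def pooled_ttest(x, y, alpha: float = 0.05, descriptor: str = "") -> TestResult:
    """Pooled-variance Student t-test on two raw samples.

    t = (x̄ − ȳ) / (s_p √(1/n1 + 1/n2)),
    s_p² = ((n1−1)s1² + (n2−1)s2²) / (n1 + n2 − 2),

    with a two-sided p from the t distribution on n1+n2−2 degrees of
    freedom.  Degenerate pooled variance with equal means yields t = 0,
    p = 1 (not an error).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs at least 2 non-missing values (got {n1} and {n2})"
        )
    df = n1 + n2 - 2
    m1, m2 = float(x.mean()), float(y.mean())
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
    else:
        t = (m1 - m2) / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(
        descriptor=descriptor,
        mean_selected=m1,
        mean_rest=m2,
        n_selected=n1,
        n_rest=n2,
        t_statistic=t,
        df=df,
        p_value=p,
        alpha=alpha,
        reject=p < alpha,
    )


def two_sample_ttest(
    table: GeometryTable,
    descriptor: "str | PooledColumn",
    selection: Selection,
    alpha: float = 0.05,
) -> TestResult:
    """Test a selection's mean against the rest of the visible rows.

    Hidden rows are excluded from both groups; rows missing the descriptor
    are dropped.  ``descriptor`` may be a column name or a
    :class:`PooledColumn` (group membership then follows the source row of
    each pooled value).
    """
    mask = np.asarray(selection.mask, dtype=bool)
    if mask.shape != (table.n_rows,):
        raise ValueError("selection mask length must equal the table row count")
    if not (mask & ~table.hidden).any():
        raise ValueError("empty selection: nothing to test")
    visible = ~table.hidden
    if isinstance(descriptor, PooledColumn):
        rows = np.array([r for r, _ in descriptor.provenance], dtype=int)
        v = descriptor.values
        sel = mask[rows] & visible[rows]
        rest = ~mask[rows] & visible[rows]
        name = descriptor.name
        x, y = v[sel], v[rest]
    else:
        v = table.values(descriptor)
        x = v[mask & visible]
        y = v[~mask & visible]
        name = descriptor
    return pooled_ttest(x, y, alpha=alpha, descriptor=name)
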