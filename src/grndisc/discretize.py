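"""Five unsupervised discretizers mapping an expression matrix to integer levels.

All methods share the signature ``(ExpressionMatrix, k, ...) -> DiscreteMatrix``
with output levels in ``1..k``:

* :func:`ewd` — per-gene equal-width bins between the row min and max.
* :func:`efd` — per-gene equal-frequency bins over the sorted row.
* :func:`row_kmeans` — per-gene 1-D k-means intervals.
* :func:`col_kmeans` — per-time-point 1-D k-means intervals.
* :func:`bikmeans` — row and column k-means each at ``k+1`` levels, combined
  per cell by the product rule ``x**2 <= rowlabel*collabel < (x+1)**2``.

The 1-D k-means subproblem is solved *exactly* by dynamic programming over
the sorted distinct values (optimal 1-D clusters are contiguous), so every
method here is deterministic; ``seed`` arguments are accepted for API
uniformity but ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    DegenerateDiscretizationWarning,
    DiscreteMatrix,
    ExpressionMatrix,
    ValidationError,
)

__all__ = [
    "KmeansSolution1D",
    "ewd",
    "efd",
    "kmeans_1d",
    "row_kmeans",
    "col_kmeans",
    "bikmeans",
    "combine_product_level",
    "get_discretizer",
    "DISCRETIZERS",
]


def _validate_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValidationError(f"interval count k must be an integer >= 2, got {k!r}")


# ---------------------------------------------------------------------------
# Equal width


def _ewd_row(row: np.ndarray, k: int) -> Tuple[np.ndarray, bool]:
    lo, hi = row.min(), row.max()
    if hi == lo:
        return np.ones(row.size, dtype=int), True
    w = (hi - lo) / k
    # cut points at lo + j*w; a value exactly on an interior cut point goes
    # to the lower interval, so levels are ceil((v - lo)/w) clipped to 1..k
    lvl = np.ceil((row - lo) / w).astype(int)
    return np.clip(lvl, 1, k), False


def ewd(m: ExpressionMatrix, k: int) -> DiscreteMatrix:
    """Equal-width discretization, per gene row.

    Interval width is ``(max - min)/k`` per row.  Constant rows are
    degenerate: every value gets level 1 and a warning is emitted.
    """
    _validate_k(k)
    out = np.empty(m.values.shape, dtype=int)
    for i, gid in enumerate(m.gene_ids):
        out[i], degen = _ewd_row(m.values[i], k)
        if degen:
            warnings.warn(
                f"gene {gid!r} is constant; all values assigned level 1",
                DegenerateDiscretizationWarning,
                stacklevel=2,
            )
    return DiscreteMatrix(out, k, "ewd", m.gene_ids, m.time_labels)


# ---------------------------------------------------------------------------
# Equal frequency


def _efd_row(row: np.ndarray, k: int) -> np.ndarray:
    m = row.size
    order = np.argsort(row, kind="stable")
    q, r = divmod(m, k)
    sizes = [q + 1] * r + [q] * (k - r)  # larger intervals first (lowest values)
    lvl_sorted = np.repeat(np.arange(1, k + 1), sizes)
    out = np.empty(m, dtype=int)
    out[order] = lvl_sorted
    return out


def efd(m: ExpressionMatrix, k: int) -> DiscreteMatrix:
    """Equal-frequency discretization, per gene row.

    Each interval holds ``ceil(M/k)`` or ``floor(M/k)`` values (larger
    intervals first); ties keep stable sort order, so equal values may
    straddle an interval boundary.
    """
    _validate_k(k)
    if k > m.n_timepoints:
        raise ValidationError(f"k={k} exceeds the number of time points ({m.n_timepoints})")
    out = np.vstack([_efd_row(m.values[i], k) for i in range(m.n_genes)])
    return DiscreteMatrix(out, k, "efd", m.gene_ids, m.time_labels)


# ---------------------------------------------------------------------------
# Exact 1-D k-means


@dataclass(frozen=True)
class KmeansSolution1D:
    """Labels (1..c, ascending by center) and centers for one 1-D clustering.

    ``degenerate`` is set when fewer distinct values than requested clusters
    were available; labels then span ``1..len(centers)`` only.
    """

    labels: np.ndarray
    centers: np.ndarray
    c: int
    degenerate: bool


def _group_stats(values: np.ndarray):
    """Sorted distinct values with counts, plus prefix sums for SSQ costs."""
    uniq, counts = np.unique(values, return_counts=True)
    w = counts.astype(float)
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cwx = np.concatenate(([0.0], np.cumsum(w * uniq)))
    cwx2 = np.concatenate(([0.0], np.cumsum(w * uniq * uniq)))

    def cost(i: int, j: int) -> float:
        # weighted SSQ of groups i..j-1 around their mean
        n = cw[j] - cw[i]
        s = cwx[j] - cwx[i]
        s2 = cwx2[j] - cwx2[i]
        return max(s2 - s * s / n, 0.0)

    return uniq, counts, cost


def kmeans_1d(values, c: int, seed: Optional[int] = None) -> KmeansSolution1D:
    """Globally optimal 1-D k-means via dynamic programming.

    Optimal 1-D clusters are contiguous intervals of the sorted values, and
    an optimal solution never splits a run of equal values when at least
    ``c`` distinct values exist, so the DP runs over distinct-value groups
    in O(d^2 c).  With ``d < c`` distinct values, each distinct value gets
    its own cluster and the result is flagged degenerate.  ``seed`` is
    ignored (the solution is exact and deterministic).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("kmeans_1d requires at least one value")
    if not isinstance(c, (int, np.integer)) or c < 2:
        raise ValidationError(f"cluster count must be an integer >= 2, got {c!r}")
    uniq, counts, cost = _group_stats(values)
    d = uniq.size
    if d <= c:
        # one cluster per distinct value (degenerate if d < c)
        group_label = np.arange(1, d + 1)
        centers = uniq.copy()
        degenerate = d < c
    else:
        # dp[j][i] = min cost of splitting groups 0..i-1 into j clusters
        INF = math.inf
        dp = np.full((c + 1, d + 1), INF)
        split = np.zeros((c + 1, d + 1), dtype=int)
        dp[0][0] = 0.0
        for j in range(1, c + 1):
            # cluster j covers groups t..i-1; t >= j-1 to keep clusters non-empty
            for i in range(j, d - (c - j) + 1):
                best, best_t = INF, j - 1
                for t in range(j - 1, i):
                    if dp[j - 1][t] == INF:
                        continue
                    v = dp[j - 1][t] + cost(t, i)
                    if v < best - 1e-12:
                        best, best_t = v, t
                dp[j][i] = best
                split[j][i] = best_t
        bounds = [d]
        i = d
        for j in range(c, 0, -1):
            i = split[j][i]
            bounds.append(i)
        bounds = bounds[::-1]  # [0, b1, ..., d]
        group_label = np.empty(d, dtype=int)
        centers = np.empty(c, dtype=float)
        for j in range(c):
            lo, hi = bounds[j], bounds[j + 1]
            group_label[lo:hi] = j + 1
            centers[j] = np.average(uniq[lo:hi], weights=counts[lo:hi])
        degenerate = False
    labels = group_label[np.searchsorted(uniq, values)]
    return KmeansSolution1D(labels, centers, int(c), degenerate)


def _kmeans_vector(vec: np.ndarray, c: int, what: str) -> np.ndarray:
    sol = kmeans_1d(vec, c)
    if sol.degenerate:
        warnings.warn(
            f"{what} has only {len(sol.centers)} distinct value(s) for {c} clusters",
            DegenerateDiscretizationWarning,
            stacklevel=3,
        )
    return sol.labels


def row_kmeans(m: ExpressionMatrix, k: int, seed: Optional[int] = None) -> DiscreteMatrix:
    """Per-gene 1-D k-means intervals, level 1 = lowest-center cluster."""
    _validate_k(k)
    out = np.vstack(
        [_kmeans_vector(m.values[i], k, f"gene {gid!r}") for i, gid in enumerate(m.gene_ids)]
    )
    return DiscreteMatrix(out, k, "kmeans", m.gene_ids, m.time_labels)


def col_kmeans(m: ExpressionMatrix, k: int, seed: Optional[int] = None) -> DiscreteMatrix:
    """Per-time-point 1-D k-means intervals (column-wise :func:`row_kmeans`)."""
    _validate_k(k)
    out = np.column_stack(
        [
            _kmeans_vector(m.values[:, j], k, f"time point {lab!r}")
            for j, lab in enumerate(m.time_labels)
        ]
    )
    return DiscreteMatrix(out, k, "cokmeans", m.gene_ids, m.time_labels)


# ---------------------------------------------------------------------------
# Bikmeans


def combine_product_level(row_label: int, col_label: int, k: int) -> int:
    """Final level x with x**2 <= row_label*col_label < (x+1)**2, clamped to 1..k.

    The clamp only matters for the corner product ``(k+1)**2``, which falls
    outside every stated window; it is mapped to ``k``.
    """
    p = int(row_label) * int(col_label)
    return min(max(math.isqrt(p), 1), k)


def bikmeans(m: ExpressionMatrix, k: int, seed: Optional[int] = None) -> DiscreteMatrix:
    """Bidirectional k-means: row and column k-means at ``k+1`` levels combined.

    Each cell's two labels are multiplied and the product mapped through
    :func:`combine_product_level`, yielding levels in ``1..k`` that are high
    only where the value is high both within its gene and within its time
    point.
    """
    _validate_k(k)
    r = row_kmeans(m, k + 1)
    c = col_kmeans(m, k + 1)
    p = r.levels * c.levels
    lvl = np.floor(np.sqrt(p.astype(float))).astype(int)  # exact for p <= (k+1)^2
    lvl = np.clip(lvl, 1, k)
    return DiscreteMatrix(lvl, k, "bikmeans", m.gene_ids, m.time_labels)


DISCRETIZERS = {
    "ewd": ewd,
    "efd": efd,
    "kmeans": row_kmeans,
    "cokmeans": col_kmeans,
    "bikmeans": bikmeans,
}


def get_discretizer(name: str):
    try:
        return DISCRETIZERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown discretizer {name!r}; choose from {sorted(DISCRETIZERS)}"
        ) from None


def discretize(m: ExpressionMatrix, method: str, k: int, seed: Optional[int] = None) -> DiscreteMatrix:
    """Dispatch to a discretizer by name."""
    fn = get_discretizer(method)
    if method in ("ewd", "efd"):
        return fn(m, k)
    return fn(m, k, seed)
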