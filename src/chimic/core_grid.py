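"""Rank handling, axis partitions, contingency counting and grid mutual information.

These are the arithmetic primitives shared by both grid optimizers: a paired
sample with its per-axis rank orders, partitions of one axis into consecutive
rank bins, the cell counts of a (row x column) grid, and the (normalized)
mutual information of such a grid.  All scores downstream are functions of
rank order only, so every statistic in this package is invariant under
strictly increasing transforms of either margin.

Conventions
-----------
* Logarithms are base 2 throughout: mutual information is in bits and the
  normalized score lies in [0, 1].
* Points sharing a raw value on an axis are *atomic*: no cut may separate
  them.  Rank orders use a stable sort so duplicate handling is
  deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedSample",
    "AxisPartition",
    "ContingencyTable",
    "equipartition",
    "count_contingency",
    "mutual_information",
    "normalized_score",
]


@dataclass(frozen=True)
class PairedSample:
    """A data set of n ordered (x, y) pairs with cached rank orders.

    Parameters
    ----------
    xs, ys : array-like of float, shape (n,)
        The two paired series.  Must have equal length n >= 2 and contain
        only finite values.

    Attributes
    ----------
    x_order, y_order : ndarray of int
        Stable permutations sorting each axis ascending.
    """

    xs: np.ndarray
    ys: np.ndarray
    x_order: np.ndarray = field(init=False, repr=False, compare=False)
    y_order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if xs.ndim != 1 or ys.ndim != 1:
            raise ValueError("xs and ys must be one-dimensional")
        if xs.shape[0] != ys.shape[0]:
            raise ValueError(
                f"xs and ys must have equal length, got {xs.shape[0]} and {ys.shape[0]}"
            )
        if xs.shape[0] < 2:
            raise ValueError("a paired sample needs at least 2 points")
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            raise ValueError("xs and ys must be finite")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)
        object.__setattr__(self, "x_order", np.argsort(xs, kind="stable"))
        object.__setattr__(self, "y_order", np.argsort(ys, kind="stable"))

    @property
    def n(self) -> int:
        return self.xs.shape[0]

    def swapped(self) -> "PairedSample":
        """The same sample with the axes exchanged."""
        return PairedSample(self.ys, self.xs)


@dataclass(frozen=True)
class AxisPartition:
    """An ordered set of cut positions splitting rank-sorted points into bins.

    ``cuts`` are strictly increasing integers in [1, n-1]; a cut at position
    ``p`` separates the p rank-smallest points from the rest.  ``bins``
    equals ``len(cuts) + 1`` and bin sizes sum to n.
    """

    cuts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cuts, dtype=np.int64)
        if cuts.size and (
            (np.diff(cuts) <= 0).any() or cuts[0] < 1 or cuts[-1] > self.n - 1
        ):
            raise ValueError("cuts must be strictly increasing within [1, n-1]")
        object.__setattr__(self, "cuts", cuts)

    @property
    def bins(self) -> int:
        return self.cuts.size + 1

    @property
    def edges(self) -> np.ndarray:
        """Bin edges including 0 and n: ``edges[i]..edges[i+1]`` is bin i."""
        return np.concatenate(([0], self.cuts, [self.n]))

    def bin_sizes(self) -> np.ndarray:
        return np.diff(self.edges)

    def assign(self) -> np.ndarray:
        """Bin index of each *rank* position (length n)."""
        ids = np.zeros(self.n, dtype=np.int64)
        ids[self.cuts] = 1
        return np.cumsum(ids)


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of a (row-partition x column-partition) grid with margins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _legal_cuts(sorted_values: np.ndarray) -> np.ndarray:
    """Positions where a cut does not split a run of tied values."""
    return np.flatnonzero(sorted_values[1:] != sorted_values[:-1]) + 1


def equipartition(values, r: int) -> AxisPartition:
    """Partition one axis into ``r`` bins of (near-)equal point counts.

    Each ideal cut position ``k*n/r`` is moved to the nearest position that
    does not split a run of tied values; when two legal positions are
    equidistant the smaller index wins.  With distinct values the bin sizes
    differ by at most one; ties can force unequal bins and may reduce the
    achieved bin count below ``r``.

    Raises
    ------
    ValueError
        If ``r < 2`` or ``r > n``.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if not 2 <= r <= n:
        raise ValueError(f"bin count r={r} must satisfy 2 <= r <= n={n}")
    v = np.sort(values, kind="stable")
    legal = _legal_cuts(v)
    if legal.size == 0:  # all values tied: a single bin
        return AxisPartition(np.empty(0, dtype=np.int64), n)
    cuts = []
    for k in range(1, r):
        ideal = k * n / r
        dist = np.abs(legal - ideal)
        nearest = legal[dist <= dist.min() + 1e-12]
        cuts.append(int(nearest.min()))  # tie toward the smaller index
    return AxisPartition(np.unique(np.asarray(cuts, dtype=np.int64)), n)


def _ranks(order: np.ndarray) -> np.ndarray:
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return ranks


def count_contingency(
    sample: PairedSample, xpart: AxisPartition, ypart: AxisPartition
) -> ContingencyTable:
    """Count points per (y-bin, x-bin) cell; ``counts[i][j]`` is y-bin i, x-bin j."""
    if xpart.n != sample.n or ypart.n != sample.n:
        raise ValueError("partitions must refer to the same sample")
    col = xpart.assign()[_ranks(sample.x_order)]
    row = ypart.assign()[_ranks(sample.y_order)]
    counts = np.zeros((ypart.bins, xpart.bins), dtype=np.int64)
    np.add.at(counts, (row, col), 1)
    return ContingencyTable(counts)


def mutual_information(table: ContingencyTable) -> float:
    """Grid mutual information in bits, with 0*log(0) terms taken as 0.

    ``I = sum_ij (f_ij/N) log2( (f_ij/N) / ((n_i/N)(T_j/N)) )``; always
    non-negative and bounded by ``log2(min(rows, cols))``.
    """
    counts = table.counts.astype(float)
    N = counts.sum()
    if N < 1:
        raise ValueError("table total must be at least 1")
    outer = np.outer(table.row_sums, table.col_sums).astype(float)
    pos = counts > 0
    terms = counts[pos] / N * np.log2(counts[pos] * N / outer[pos])
    return max(float(terms.sum()), 0.0)


def normalized_score(I: float, nx: int, ny: int) -> float:
    """``I / log2(min(nx, ny))`` -- the characteristic-matrix normalization."""
    if nx < 2 or ny < 2:
        raise ValueError("normalization needs at least 2 bins on each axis")
    if I < 0:
        raise ValueError("mutual information must be non-negative")
    return I / np.log2(min(nx, ny))
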