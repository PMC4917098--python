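"""The ApproxMaxMI baseline: clump candidates, axis DP, characteristic-matrix sweep.

Given an equipartition of one axis into rows, the only x-cut positions that
can increase mutual information are *clump* boundaries -- transitions between
maximal runs of consecutive (in x-order) points lying in the same row.  The
dynamic program below finds, for every column budget l, the partition of the
x-axis with cuts drawn from those candidates that maximizes the grid mutual
information against the fixed rows.  Sweeping the row count r over both axis
orientations under the grid-size bound B(n) = n^a fills the characteristic
matrix; its maximum entry is the MIC.

When there are many more clumps than ``c`` times the column budget, clumps
are coarsened into *superclumps* of near-equal point counts (clumps stay
atomic), which bounds the DP cost at the price of a slightly restricted
candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_grid import AxisPartition, PairedSample, equipartition

__all__ = [
    "OptimizerConfig",
    "CharacteristicMatrix",
    "build_clumps",
    "optimize_x_axis",
    "approx_max_mi",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Search-bound parameters of the ApproxMaxMI sweep.

    a : exponent of the maximal-grid-size bound B(n) = n^a.
    c : superclump multiplier; at most ``c * column_budget`` candidate cuts
        are kept per row count.
    rounding : how B(n) is turned into an integer cap ("floor" or "ceil").
    strict : if True grids must satisfy l*r < b_cap, otherwise l*r <= b_cap.

    The default is floor(n^a) with a non-strict bound; the ceil/strict
    variants are provided so both readings of the bound are reproducible.
    """

    a: float = 0.6
    c: int = 5
    rounding: str = "floor"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("exponent a must be positive")
        if self.c < 1:
            raise ValueError("superclump multiplier c must be >= 1")
        if self.rounding not in ("ceil", "floor"):
            raise ValueError("rounding must be 'ceil' or 'floor'")

    def b_cap(self, n: int) -> int:
        b = n**self.a
        return int(math.ceil(b) if self.rounding == "ceil" else math.floor(b))

    def max_cells(self, n: int) -> int:
        """Largest admissible cell count l*r."""
        b = self.b_cap(n)
        return b - 1 if self.strict else b

    def col_budget(self, n: int, rows: int) -> int:
        """Largest column count l admissible with ``rows`` rows."""
        return self.max_cells(n) // rows


class CharacteristicMatrix:
    """Normalized mutual-information scores indexed by grid shape (l, r).

    ``l`` counts x bins (columns), ``r`` counts y bins (rows); both >= 2.
    Entries not visited by the generating algorithm are absent, not zero.
    ``record`` keeps the per-shape maximum over repeated visits (e.g. the
    two axis orientations).
    """

    def __init__(self, b: int):
        self.b = int(b)
        self.entries: dict[tuple[int, int], float] = {}

    def record(self, l: int, r: int, score: float) -> None:
        score = min(float(score), 1.0)
        if score < 0:
            raise ValueError("normalized scores must be non-negative")
        key = (int(l), int(r))
        if score > self.entries.get(key, -1.0):
            self.entries[key] = score

    def get(self, l: int, r: int) -> float | None:
        return self.entries.get((l, r))

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def max_entry(self) -> tuple[float, tuple[int, int]]:
        """Maximum score and its shape (ties: smallest l*r, then smallest l)."""
        if not self.entries:
            raise ValueError("characteristic matrix has no computed entries")
        best = max(self.entries.values())
        shape = min(
            (k for k, v in self.entries.items() if v == best),
            key=lambda k: (k[0] * k[1], k[0]),
        )
        return best, shape


# ---------------------------------------------------------------------------
# clump machinery


def _row_ids(sample: PairedSample, ypart: AxisPartition) -> np.ndarray:
    """Row index of each point under the y-partition."""
    ranks = np.empty(sample.n, dtype=np.int64)
    ranks[sample.y_order] = np.arange(sample.n)
    return ypart.assign()[ranks]


def _clump_ends(sample: PairedSample, ypart: AxisPartition) -> np.ndarray:
    """End positions (in x-rank space, exclusive) of clumps, including n.

    Points tied in x are atomic.  A boundary between adjacent tie-groups is
    a clump end unless both groups are pure and lie in the same row.
    """
    n = sample.n
    xs = sample.xs[sample.x_order]
    rows = _row_ids(sample, ypart)[sample.x_order]
    legal = np.concatenate([np.flatnonzero(xs[1:] != xs[:-1]) + 1, [n]])
    # per tie-group: first row, last row, purity
    starts = np.concatenate([[0], legal[:-1]])
    boundary = []
    prev_last = None
    prev_pure = True
    for s, e in zip(starts, legal):
        grp = rows[s:e]
        pure = bool((grp == grp[0]).all())
        if s > 0 and not (prev_pure and pure and prev_last == grp[0]):
            boundary.append(s)
        prev_last = grp[-1]
        prev_pure = pure
    return np.concatenate([np.asarray(boundary, dtype=np.int64), [n]])


def build_clumps(
    sample: PairedSample, ypart: AxisPartition, max_clumps: int | None = None
) -> np.ndarray:
    """Candidate x-cut positions: clump boundaries, optionally coarsened.

    Returns the boundaries between maximal same-row runs of x-consecutive
    points (excluding 0 and n).  If ``max_clumps`` is given and there are
    more clumps than that, boundaries are coarsened to at most
    ``max_clumps`` superclumps of near-equal point counts (each ideal
    equal-count position snaps to the nearest clump boundary, ties toward
    the smaller position).
    """
    ends = _clump_ends(sample, ypart)
    if max_clumps is not None and ends.size > max_clumps:
        n = sample.n
        ideal = np.arange(1, max_clumps) * n / max_clumps
        snapped = np.empty(ideal.size, dtype=np.int64)
        for i, t in enumerate(ideal):
            dist = np.abs(ends - t)
            snapped[i] = ends[dist <= dist.min() + 1e-12].min()
        ends = np.unique(np.concatenate([snapped, [n]]))
        ends = ends[ends > 0]
    return ends[:-1]


# ---------------------------------------------------------------------------
# dynamic program


def _cumulative_rows(sample: PairedSample, ypart: AxisPartition) -> np.ndarray:
    """cum[p, q] = number of points among the p x-smallest lying in row q."""
    rows = _row_ids(sample, ypart)[sample.x_order]
    onehot = np.zeros((sample.n, ypart.bins))
    onehot[np.arange(sample.n), rows] = 1.0
    return np.vstack([np.zeros(ypart.bins), np.cumsum(onehot, axis=0)])


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    nz = counts[counts > 0]
    return float(-(nz / tot * np.log2(nz / tot)).sum())


def _dp_best_I(cum: np.ndarray, ends: np.ndarray, max_bins: int) -> np.ndarray:
    """Max grid MI for column budgets 2..max_bins over cut subsets of ``ends``.

    ``P[t, l]`` is the maximal value of
    ``sum_bins (1/c_t) sum_q n_bq log2(n_bq / |b|)`` over partitions of the
    first t clumps into l columns; the mutual information of the full-axis
    partition is ``H(rows) + P[k, l]``.  Returned sequence is the running
    maximum over ``<= l`` columns.
    """
    k = ends.size
    C = cum[np.concatenate([[0], ends])]  # (k+1, rows)
    csz = np.concatenate([[0], ends]).astype(float)
    maxl = min(max_bins, k)
    P = np.full((k + 1, maxl + 1), -np.inf)
    for t in range(1, k + 1):
        cnt = C[t]
        nz = cnt[cnt > 0]
        P[t, 1] = (nz * np.log2(nz / csz[t])).sum() / csz[t]
    for l in range(2, maxl + 1):
        for t in range(l, k + 1):
            s = np.arange(l - 1, t)
            cnt = C[t] - C[s]
            width = (csz[t] - csz[s])[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                tail = np.where(cnt > 0, cnt * np.log2(cnt / width), 0.0).sum(axis=1)
            P[t, l] = ((csz[s] * P[s, l - 1] + tail) / csz[t]).max()
    HQ = _entropy(C[k])
    I = HQ + P[k, 2 : maxl + 1]
    return np.maximum.accumulate(np.maximum(I, 0.0))


def optimize_x_axis(
    sample: PairedSample,
    ypart: AxisPartition,
    max_bins: int,
    cfg: OptimizerConfig | None = None,
) -> np.ndarray:
    """Optimal grid MI (bits) for x-bin counts 2..max_bins given fixed y rows.

    Entry ``i`` is the maximum mutual information achievable with at most
    ``i + 2`` columns whose cuts are drawn from the superclump candidates;
    the sequence is non-decreasing.  Returns an empty array when the sample
    admits no cut (e.g. a single clump).
    """
    if max_bins < 2:
        raise ValueError("max_bins must be >= 2")
    if ypart.n != sample.n:
        raise ValueError("partition must refer to the same sample")
    cfg = cfg or OptimizerConfig()
    bnd = build_clumps(sample, ypart, max_clumps=cfg.c * max_bins)
    if bnd.size == 0:
        return np.empty(0)
    cum = _cumulative_rows(sample, ypart)
    ends = np.concatenate([bnd, [sample.n]])
    return _dp_best_I(cum, ends, max_bins)


def approx_max_mi(sample: PairedSample, cfg: OptimizerConfig | None = None):
    """MIC of a sample by the ApproxMaxMI characteristic-matrix sweep.

    For every row count r with a 2-column grid inside the bound, the x-axis
    is optimized by dynamic programming up to the per-r column budget; the
    sweep is repeated with the axes swapped and the per-shape maximum is
    kept.  Returns a :class:`~chimic.mine_stats.MicResult`.
    """
    from .mine_stats import MicResult, mic_from_matrix

    cfg = cfg or OptimizerConfig()
    n = sample.n
    if n < 4:
        raise ValueError("need n >= 4 to form a 2x2 grid")
    matrix = CharacteristicMatrix(cfg.b_cap(n))
    for swap in (False, True):
        view = sample.swapped() if swap else sample
        seen_rows: set[int] = set()
        for r in range(2, cfg.max_cells(n) // 2 + 1):
            ypart = equipartition(view.ys, r)
            nr = ypart.bins
            if nr < 2 or nr in seen_rows:
                continue
            seen_rows.add(nr)
            budget = cfg.col_budget(n, nr)
            if budget < 2:
                continue
            I = optimize_x_axis(view, ypart, budget, cfg)
            for i, val in enumerate(I):
                l = i + 2
                key = (nr, l) if swap else (l, nr)
                matrix.record(*key, val / np.log2(min(l, nr)))
    result = mic_from_matrix(matrix)
    return MicResult(
        mic=result.mic,
        best_shape=result.best_shape,
        matrix=matrix,
        algorithm="approxmaxmi",
    )
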