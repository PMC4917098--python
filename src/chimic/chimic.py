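"""ChiMIC: sequential endpoint insertion terminated by a chi-square test.

Instead of exhausting the B(n) grid-size budget like ApproxMaxMI, ChiMIC
grows the x-axis partition one endpoint at a time.  Each candidate endpoint
EP_m splits one existing column into two; the r x 2 contingency table of the
two flanking columns it creates is submitted to a chi-square test of
independence (Yates-corrected when r = 2).  A significant table (p below the
threshold, default 0.01) means the endpoint separates genuinely different
conditional y-distributions and the search continues; otherwise the endpoint
is discarded and the partition search for this row count terminates.  On
independent data almost every endpoint fails the test, so the grid stays
coarse and the MIC stays near zero; on structured data the test keeps
passing until the structure is resolved.

The threshold 0.01 comes from the smallest table the expected-count-of-five
rule admits: a 2x2 table with counts {0, 5; 5, 0} has a corrected p-value of
0.0114, so 0.01 rejects even that extreme pattern at minimal size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .axis_optimizer import (
    CharacteristicMatrix,
    OptimizerConfig,
    _cumulative_rows,
    build_clumps,
)
from .core_grid import AxisPartition, ContingencyTable, PairedSample, equipartition

log = logging.getLogger("chimic")

__all__ = [
    "ChiSquareResult",
    "TerminationConfig",
    "flanking_table",
    "chi_square_test",
    "chimic_x_axis",
    "chimic_mic",
]


@dataclass(frozen=True)
class ChiSquareResult:
    """Chi-square statistic, degrees of freedom r-1, and upper-tail p-value."""

    statistic: float
    df: int
    p_value: float
    corrected: bool


@dataclass(frozen=True)
class TerminationConfig:
    """ChiMIC stopping rule.

    alpha : significance threshold; an endpoint whose flanking-table p-value
        is >= alpha is rejected and the axis search stops.
    apply_b_cap : keep the B(n) cap on the *row* sweep (the insertion depth
        along the optimized axis is governed solely by the test); False
        removes the grid-size restriction entirely.
    test_first_endpoint : submit EP_1 (whose flanking columns are the whole
        sample split in two) to the test as well.  Disabling it accepts the
        first endpoint unconditionally.
    """

    alpha: float = 0.01
    apply_b_cap: bool = True
    test_first_endpoint: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def chi_square_test(table: ContingencyTable, correct: bool = True) -> ChiSquareResult:
    """Chi-square test of independence on an r x 2 flanking-column table.

    The statistic is ``sum_ij (|f_ij - n_i T_j / N| - h)^2 / (n_i T_j / N)``
    with the Yates continuity term h = 0.5 when ``correct`` and the table is
    effectively 2x2, else h = 0.  Rows with zero margin contribute expected
    count 0 and are excluded; a degenerate table (one effective row, or a
    zero column margin) yields statistic 0 and p = 1.
    """
    counts = table.counts.astype(float)
    if counts.shape[1] != 2:
        raise ValueError("flanking-column tables must have exactly 2 columns")
    counts = counts[counts.sum(axis=1) > 0]
    r_eff = counts.shape[0]
    if r_eff < 2 or (counts.sum(axis=0) == 0).any():
        return ChiSquareResult(0.0, max(r_eff - 1, 1), 1.0, False)
    N = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / N
    yates = bool(correct and r_eff == 2)
    h = 0.5 if yates else 0.0
    dev = np.maximum(np.abs(counts - expected) - h, 0.0)
    stat = float((dev**2 / expected).sum())
    df = r_eff - 1
    return ChiSquareResult(stat, df, float(chi2.sf(stat, df)), yates)


def flanking_table(
    sample: PairedSample,
    ypart: AxisPartition,
    xpart: AxisPartition,
    new_cut: int,
) -> ContingencyTable:
    """The r x 2 table of the two x-columns flanking ``new_cut``.

    ``new_cut`` must be one of ``xpart``'s cuts; the two columns are the
    bins immediately left and right of it, restricted to their points.
    """
    if new_cut not in xpart.cuts:
        raise ValueError(f"position {new_cut} is not a cut of the partition")
    cum = _cumulative_rows(sample, ypart)
    edges = xpart.edges
    j = int(np.searchsorted(edges, new_cut))
    lo, hi = edges[j - 1], edges[j + 1]
    left = cum[new_cut] - cum[lo]
    right = cum[hi] - cum[new_cut]
    return ContingencyTable(np.stack([left, right], axis=1).astype(np.int64))


def _bin_term(cum: np.ndarray, a: int, b: int, n: int) -> float:
    cnt = cum[b] - cum[a]
    nz = cnt[cnt > 0]
    return float((nz * np.log2(nz / (b - a))).sum() / n)


def chimic_x_axis(
    sample: PairedSample,
    ypart: AxisPartition,
    cfg: TerminationConfig | None = None,
    opt: OptimizerConfig | None = None,
) -> tuple[AxisPartition, list[float]]:
    """Greedy chi-square-terminated x-axis partition given fixed y rows.

    Endpoints are inserted one at a time: with previously accepted cuts
    frozen, the clump-boundary candidate maximizing the grid mutual
    information is proposed, its flanking r x 2 table is tested, and the
    search stops at the first rejection (p >= alpha) or when candidates are
    exhausted.  Returns the accepted partition and the mutual information
    (bits) after each accepted insertion, i.e. at 2, 3, ... bins.
    """
    cfg = cfg or TerminationConfig()
    opt = opt or OptimizerConfig()
    n = sample.n
    # same candidate machinery as the DP baseline: clump boundaries, coarsened
    # to c * (column budget) superclumps when the B cap is in force
    if cfg.apply_b_cap:
        max_clumps = opt.c * max(2, opt.col_budget(n, ypart.bins))
    else:
        max_clumps = None
    candidates = build_clumps(sample, ypart, max_clumps=max_clumps)
    cum = _cumulative_rows(sample, ypart)
    nz = cum[n][cum[n] > 0]
    H_rows = float(-(nz / n * np.log2(nz / n)).sum())

    edges = [0, n]
    G = _bin_term(cum, 0, n, n)
    trace: list[float] = []
    cand = candidates.tolist()
    first = True
    while cand:
        acc = np.asarray(edges)
        best_p, best_G, best_j = None, -np.inf, -1
        for p in cand:
            j = int(np.searchsorted(acc, p))
            a, b = acc[j - 1], acc[j]
            g = G - _bin_term(cum, a, b, n) + _bin_term(cum, a, p, n) + _bin_term(cum, p, b, n)
            if g > best_G:
                best_p, best_G, best_j = p, g, j
        a, b = acc[best_j - 1], acc[best_j]
        if not first or cfg.test_first_endpoint:
            left = cum[best_p] - cum[a]
            right = cum[b] - cum[best_p]
            table = ContingencyTable(np.stack([left, right], axis=1).astype(np.int64))
            test = chi_square_test(table)
            if test.p_value >= cfg.alpha:
                log.info(
                    "terminated at %d bins (%d rows): flanking p=%.4g >= alpha=%g",
                    len(edges) - 1, ypart.bins, test.p_value, cfg.alpha,
                )
                break
        first = False
        edges.insert(best_j, best_p)
        cand.remove(best_p)
        G = best_G
        trace.append(H_rows + G)
    return AxisPartition(np.asarray(edges[1:-1], dtype=np.int64), n), trace


def chimic_mic(
    sample: PairedSample,
    cfg: TerminationConfig | None = None,
    opt: OptimizerConfig | None = None,
):
    """MIC by the ChiMIC sweep: chi-square-terminated search per row count.

    Sweeps the row count over both axis orientations (bounded by B(n) when
    ``cfg.apply_b_cap``), runs :func:`chimic_x_axis` for each, and fills the
    characteristic matrix with the normalized scores of every intermediate
    grid actually visited.  MIC is the maximum entry; if no endpoint is
    accepted anywhere -- typical for small independent samples -- the MIC is
    0 with no attaining shape.
    """
    from .mine_stats import MicResult

    cfg = cfg or TerminationConfig()
    opt = opt or OptimizerConfig()
    n = sample.n
    if n < 4:
        raise ValueError("need n >= 4 to form a 2x2 grid")
    if cfg.apply_b_cap:
        max_rows = opt.max_cells(n) // 2
    else:
        max_rows = n // 2
    matrix = CharacteristicMatrix(opt.b_cap(n))
    for swap in (False, True):
        view = sample.swapped() if swap else sample
        seen_rows: set[int] = set()
        for r in range(2, max_rows + 1):
            ypart = equipartition(view.ys, r)
            nr = ypart.bins
            if nr < 2 or nr in seen_rows:
                continue
            seen_rows.add(nr)
            _, trace = chimic_x_axis(view, ypart, cfg, opt)
            for i, val in enumerate(trace):
                l = i + 2
                if cfg.apply_b_cap and l * nr > opt.max_cells(n):
                    break
                key = (nr, l) if swap else (l, nr)
                matrix.record(*key, val / np.log2(min(l, nr)))
    if len(matrix) == 0:
        return MicResult(mic=0.0, best_shape=None, matrix=matrix, algorithm="chimic")
    mic, shape = matrix.max_entry()
    return MicResult(mic=mic, best_shape=shape, matrix=matrix, algorithm="chimic")
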