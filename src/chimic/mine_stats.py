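"""Statistics over a characteristic matrix: MIC extraction and MCN complexity.

MIC is the maximum normalized score over all computed grid shapes.  The
minimum cell number, MCN(D, eps) = min{ log2(l*r) : M[l][r] >= (1-eps) MIC },
measures how coarse a grid suffices to (nearly) attain MIC and thereby the
complexity of the association: 2 for a monotone relationship (a 2x2 grid
suffices), larger for relationships needing finer grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .axis_optimizer import CharacteristicMatrix

__all__ = ["MicResult", "McnQuery", "mic_from_matrix", "mcn"]

#: absolute slack when testing a matrix entry against the (1-eps)*MIC
#: threshold, so that shapes attaining the maximum up to rounding qualify
_QUALIFY_TOL = 1e-9


@dataclass(frozen=True)
class MicResult:
    """MIC value, the grid shape attaining it, and the full matrix.

    ``best_shape`` is (columns, rows); on ties the smallest cell count and
    then the smallest column count win.  ``best_shape`` is None only for a
    degenerate result with no computed entry (then ``mic`` is 0).
    """

    mic: float
    best_shape: tuple[int, int] | None
    matrix: "CharacteristicMatrix"
    algorithm: str = ""
    partitions: dict | None = None


@dataclass(frozen=True)
class McnQuery:
    """How to evaluate MCN.

    epsilon : robustness margin in [0, 1]; ignored in "one-minus-mic" mode,
        where eps = 1 - MIC(D) is taken per data set.
    mode : "fixed-epsilon" or "one-minus-mic".
    B : optional cell-count bound for the search (grids with l*r beyond it
        are skipped); by default every computed entry qualifies, since the
        generating sweep already enforced its own B(n) cap.
    strict : whether the bound is l*r < B (True) or l*r <= B.
    """

    epsilon: float = 0.0
    mode: str = "fixed-epsilon"
    B: float | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.mode not in ("fixed-epsilon", "one-minus-mic"):
            raise ValueError("mode must be 'fixed-epsilon' or 'one-minus-mic'")


def mic_from_matrix(matrix: "CharacteristicMatrix") -> MicResult:
    """Maximum computed entry with the deterministic shape tie-break."""
    mic, shape = matrix.max_entry()
    return MicResult(mic=mic, best_shape=shape, matrix=matrix)


def mcn(matrix: "CharacteristicMatrix", mic: float, query: McnQuery | None = None) -> float:
    """Minimum log2 cell count among grids scoring within (1-eps) of MIC.

    Only entries actually computed by the generating algorithm are
    searched: grids a terminated search never visited are absent, not zero.
    Returns log2(4) = 2 when no entry qualifies (the 2x2 floor).
    """
    query = query or McnQuery()
    eps = 1.0 - mic if query.mode == "one-minus-mic" else query.epsilon
    threshold = (1.0 - eps) * mic - _QUALIFY_TOL
    best = None
    for (l, r), score in matrix.items():
        cells = l * r
        if query.B is not None:
            if cells >= query.B if query.strict else cells > query.B:
                continue
        if score >= threshold:
            if best is None or cells < best:
                best = cells
    return math.log2(best) if best is not None else 2.0
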