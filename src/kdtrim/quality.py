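"""Phred-quality penalty scheme and the ``pscore`` fitness function.

A mismatch against a base called with Phred quality ``q`` is penalized
by the negative log10 of the probability that the base is actually a
match given a sequencing error::

    P(q) = P_min               q <= 0
         = P_min + q/40 * (P_max - P_min)   0 < q < 40
         = P_max               q >= 40

with ``P_min = -log10(1/3)`` (a mismatched base with no confidence is
one of three equally likely wrong calls) and
``P_max = -log10(10^(40/-10) / 3)``; for ``0 < q < 40`` the linear form
equals the closed form ``-log10(10^(q/-10)/3)`` exactly.  Insertions
and deletions are penalized by ``delta = P_max``.

``pscore(x, y) = |x| * P_max - penalty(x, y)`` rewards long, clean
alignments; the penalty is the minimum accumulated mismatch/indel
penalty of an alignment of ``x`` against ``y`` that is anchored at the
5' ends of both and end-gap free at both 3' ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alphabet import IUPAC_DEGENERACY

_LOG10_3 = math.log10(3.0)

__all__ = [
    "PenaltyParams",
    "mismatch_penalty",
    "penalty_table",
    "align_penalty",
    "pscore",
]


@dataclass(frozen=True)
class PenaltyParams:
    """Parameters of the quality-weighted penalty scheme.

    ``delta`` (the indel penalty) defaults to ``p_max`` when left
    ``None``; ``quality_cap`` is the quality at which the mismatch
    penalty saturates.
    """

    p_min: float = _LOG10_3
    p_max: float = 40.0 / 10.0 + _LOG10_3
    delta: Optional[float] = None
    quality_cap: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.p_min < self.p_max:
            raise ValueError("require 0 < p_min < p_max")
        if self.quality_cap < 1:
            raise ValueError("quality_cap must be >= 1")

    @property
    def indel_penalty(self) -> float:
        return self.p_max if self.delta is None else self.delta


DEFAULT_PENALTY_PARAMS = PenaltyParams()


def mismatch_penalty(q: int, params: PenaltyParams = DEFAULT_PENALTY_PARAMS) -> float:
    """Penalty ``P(q)`` for a mismatch against a base of Phred quality ``q``.

    Piecewise linear between ``p_min`` at ``q <= 0`` and ``p_max`` at
    ``q >= quality_cap``.
    """
    cap = params.quality_cap
    if q <= 0:
        return params.p_min
    if q >= cap:
        return params.p_max
    return params.p_min + q / cap * (params.p_max - params.p_min)


def penalty_table(params: PenaltyParams = DEFAULT_PENALTY_PARAMS) -> np.ndarray:
    """``P(q)`` for integer ``q`` in ``[0, quality_cap]`` as a lookup array."""
    return np.array(
        [mismatch_penalty(q, params) for q in range(params.quality_cap + 1)],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Penalty alignment (plain edit-path DP, no cutoff).
#
# Cells carry the pair (differences, penalty) minimized lexicographically;
# the two keys are packed into one float as differences * _DIFF_SCALE +
# penalty, which preserves the lexicographic order as long as the penalty
# stays below _DIFF_SCALE (it is bounded by |x| * p_max << _DIFF_SCALE for
# any realistic read length).
# ---------------------------------------------------------------------------

_DIFF_SCALE = float(1 << 14)

_READ_INDEX = {c: i for i, c in enumerate("ACGTN")}

# 5-bit membership mask per IUPAC code over the read alphabet ACGTN.
_DEG_BITS = {
    code: sum(1 << _READ_INDEX[b] for b in deg)
    for code, deg in IUPAC_DEGENERACY.items()
}


def _encode_read(s: str) -> np.ndarray:
    return np.array([_READ_INDEX.get(c, 4) for c in s], dtype=np.int64)


def align_penalty(
    x: str,
    y: str,
    qx: Optional[Sequence[int]] = None,
    qy: Optional[Sequence[int]] = None,
    params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
) -> tuple[int, float]:
    """Minimum (differences, penalty) of aligning ``x`` against ``y``.

    The alignment is anchored at position 0 of both strings and end-gap
    free at both far ends: whichever string runs out first ends the
    alignment, so a shared prefix relationship scores penalty 0.  The
    difference count is minimized first; among minimal-difference
    alignments the penalty is minimized.  ``y`` may contain IUPAC codes
    (the adapter side); mismatch penalties use the smaller of the two
    base qualities at the mismatching column when both are supplied,
    and ``P_min`` where the ``x`` base is an ``N``.
    """
    nx, ny = len(x), len(y)
    if qx is not None and len(qx) != nx:
        raise ValueError(f"quality/sequence length mismatch: {len(qx)} != {nx}")
    if qy is not None and len(qy) != ny:
        raise ValueError(f"quality/sequence length mismatch: {len(qy)} != {ny}")
    if nx == 0 or ny == 0:
        return 0, 0.0
    # Exact shared-prefix shortcut: (0, 0.0) is the lexicographic minimum.
    if x.startswith(y) or y.startswith(x):
        return 0, 0.0

    delta = params.indel_penalty
    cap = params.quality_cap
    ptab = penalty_table(params)

    xi = _encode_read(x)
    if qx is None:
        qxa = np.full(nx, cap, dtype=np.int64)
    else:
        qxa = np.clip(np.asarray(qx, dtype=np.int64), 0, cap)
    if qy is not None:
        qya = np.clip(np.asarray(qy, dtype=np.int64), 0, cap)

    # Substitution key per (x position, y position): 0 on match, else
    # one difference plus the quality-scaled mismatch penalty.
    sub = np.empty((nx, ny), dtype=float)
    x_is_n = xi == 4
    for j, yc in enumerate(y):
        bits = _DEG_BITS.get(yc)
        if bits is None:
            raise ValueError(f"non-IUPAC character {yc!r} in alignment target")
        match = ((bits >> xi) & 1).astype(bool)
        q_col = qxa if qy is None else np.minimum(qxa, qya[j])
        pen = ptab[q_col]
        pen = np.where(x_is_n, params.p_min, pen)
        sub[:, j] = np.where(match, 0.0, _DIFF_SCALE + pen)

    gap = _DIFF_SCALE + delta
    idx_gap = np.arange(nx + 1) * gap
    col = idx_gap.copy()  # D[:, 0]
    best_bottom = col[nx]
    tmp = np.empty(nx + 1, dtype=float)
    for j in range(1, ny + 1):
        sj = sub[:, j - 1]
        tmp[0] = col[0] + gap
        np.minimum(col[:-1] + sj, col[1:] + gap, out=tmp[1:])
        col = np.minimum.accumulate(tmp - idx_gap) + idx_gap
        if col[nx] < best_bottom:
            best_bottom = col[nx]
    key = min(best_bottom, float(col.min()))
    d = int(key // _DIFF_SCALE)
    return d, float(key - d * _DIFF_SCALE)


def pscore(
    x: str,
    y: str,
    qx: Optional[Sequence[int]] = None,
    params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
    qy: Optional[Sequence[int]] = None,
) -> float:
    """``|x| * P_max`` minus the minimum alignment penalty of ``x`` vs ``y``.

    The maximum ``|x| * P_max`` is attained iff the aligned region is an
    exact match (penalty 0); an empty ``x`` scores 0.
    """
    if qx is not None and len(qx) != len(x):
        raise ValueError(f"quality/sequence length mismatch: {len(qx)} != {len(x)}")
    _, pen = align_penalty(x, y, qx=qx, qy=qy, params=params)
    return len(x) * params.p_max - pen
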