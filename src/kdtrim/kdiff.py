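"""Bit-masked k-difference approximate matching kernel.

Finds every occurrence of an adapter pattern ``P`` (length ``m``) in a
read ``S`` (length ``n``) within ``k`` Levenshtein differences, plus —
the *extended* problem — every suffix of the read matching a prefix of
the pattern within an error-ratio bound (a partially read-through
adapter at the 3' end).

Two interchangeable implementations are provided:

``oracle_find``
    The classic semi-global dynamic programming matrix (free start on
    the read side: ``C[0, j] = 0``; anchored on the pattern side:
    ``C[i, 0] = i``), computed in full.  Kept permanently as the test
    oracle.

``find_matches`` / ``find_weighted_matches``
    The production kernel.  Instead of a column array it keeps a queue
    of the active cells of the current column: pushing the new topmost
    cell shifts every stored cell one position down its diagonal, so a
    queue slot follows a diagonal of the matrix.  Two facts make the
    update cheap: values along a diagonal never decrease (so a cell
    whose pattern position matches the current read base simply
    inherits its diagonal precursor and is never recomputed), and cells
    that exceed the ``k`` constraint are marked dead and never touched
    again.  Mismatch positions per read character are precomputed as
    bit-vectors over the pattern.  Expected cost is O(k) live cells per
    column, O(m) space.

Both implementations use the same deterministic predecessor tie-break
(diagonal, then vertical, then horizontal) to propagate the alignment
start position, so their candidate multisets are identical — a property
the test suite checks exhaustively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import IUPAC_DEGENERACY, validate_iupac
from .quality import DEFAULT_PENALTY_PARAMS, PenaltyParams, penalty_table

__all__ = [
    "AdapterPattern",
    "SearchParams",
    "MatchCandidate",
    "OracleMatrix",
    "ColumnQueue",
    "SearchStats",
    "levenshtein",
    "build_pattern",
    "oracle_find",
    "oracle_matrix",
    "find_matches",
    "find_weighted_matches",
]


# ---------------------------------------------------------------------------
# Levenshtein utilities
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Levenshtein distance between two strings (empty strings allowed)."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class AdapterPattern:
    """An adapter sequence with precomputed mismatch bit-vectors.

    ``masks[c]`` is an integer bit-vector over pattern positions
    ``0..m-1`` where bit ``i`` is set iff pattern position ``i`` does
    NOT match read character ``c`` under IUPAC semantics.  A read ``N``
    mismatches everything except a pattern ``N``.
    """

    __slots__ = ("sequence", "length", "masks")

    def __init__(self, sequence: str, masks: dict[str, int]):
        self.sequence = sequence
        self.length = len(sequence)
        self.masks = masks

    def mismatch_positions(self, read_char: str) -> frozenset[int]:
        """Position-set view of the bit-vector for ``read_char``."""
        mask = self.masks.get(read_char, self.masks["N"])
        return frozenset(i for i in range(self.length) if (mask >> i) & 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AdapterPattern({self.sequence!r})"


def build_pattern(adapter: str) -> AdapterPattern:
    """Precompute per-read-character mismatch bit-vectors for ``adapter``.

    Raises ``ValueError`` on an empty string or non-IUPAC characters.
    """
    if not adapter:
        raise ValueError("adapter pattern must be non-empty")
    seq = validate_iupac(adapter, "adapter pattern")
    masks: dict[str, int] = {}
    for c in "ACGTN":
        mask = 0
        for i, p in enumerate(seq):
            if c not in IUPAC_DEGENERACY[p]:
                mask |= 1 << i
        masks[c] = mask
    return AdapterPattern(seq, masks)


@dataclass(frozen=True)
class SearchParams:
    """Stringency of a k-difference search.

    ``error_ratio`` ``e`` sets the full-pattern threshold
    ``k = floor(n * e)`` for a read of length ``n`` (clamped below the
    pattern length) and the per-overlap threshold ``floor(L * e)`` for
    a read-suffix overlap of aligned length ``L``; overlaps shorter
    than ``min_overlap`` are not reported.  ``max_differences_override``
    fixes ``k`` directly.
    """

    error_ratio: float = 0.1
    min_overlap: int = 3
    max_differences_override: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_ratio < 1.0:
            raise ValueError("error_ratio must satisfy 0 <= e < 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def effective_k(self, read_length: int, pattern_length: int) -> int:
        if self.max_differences_override is not None:
            k = self.max_differences_override
        else:
            k = math.floor(read_length * self.error_ratio)
        return max(0, min(k, pattern_length - 1))

    def overlap_threshold(self, overlap_length: int) -> int:
        return math.floor(overlap_length * self.error_ratio)


@dataclass(frozen=True)
class MatchCandidate:
    """One k-difference occurrence or suffix-prefix overlap.

    ``[start, end)`` are 0-based read coordinates of the aligned span;
    ``matched_pattern_length`` is ``m`` for full-pattern hits and the
    matched prefix length for suffix overlaps.  ``penalty`` is 0 when no
    qualities were supplied.
    """

    start: int
    end: int
    differences: int
    penalty: float = 0.0
    matched_pattern_length: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class OracleMatrix:
    """Full DP matrix with the bookkeeping the structural theorems refer to.

    ``C`` is the (m+1) x (n+1) distance matrix, ``delta`` the m x n
    mismatch indicator, ``starts`` the per-cell alignment start
    propagated with the kernel's tie-break, and ``lac_per_column[j]``
    the last-active-cell index: the deepest row of column ``j`` whose
    value still satisfies the ``k`` constraint.
    """

    C: np.ndarray
    delta: np.ndarray
    starts: np.ndarray
    lac_per_column: list[int]
    k: int


@dataclass
class ColumnQueue:
    """Active cells of the current DP column, one slot per live diagonal.

    Slot ``p`` holds the cell of row ``p + 1``; pushing a new topmost
    cell shifts every slot one position down its diagonal.  ``dead_mask``
    bit ``p`` marks a slot whose value exceeded ``k`` (such a diagonal
    never recovers and is skipped thereafter).  Live values never exceed
    ``k`` and the queue never grows beyond ``m`` slots.
    """

    values: list[int] = field(default_factory=list)
    starts: list[int] = field(default_factory=list)
    penalties: list[float] = field(default_factory=list)
    dead_mask: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SearchStats:
    """Diagnostics of one queue search (live cells per processed column)."""

    columns: int = 0
    live_cells: int = 0

    @property
    def mean_live_cells(self) -> float:
        return self.live_cells / self.columns if self.columns else 0.0


# ---------------------------------------------------------------------------
# Oracle: full-matrix reference implementation
# ---------------------------------------------------------------------------

def _oracle_dp(read: str, pattern: AdapterPattern, k: int):
    """Full DP with start propagation; shared by oracle_find/oracle_matrix."""
    m, n = pattern.length, len(read)
    seq = pattern.sequence
    C = np.zeros((m + 1, n + 1), dtype=np.int64)
    S = np.zeros((m + 1, n + 1), dtype=np.int64)
    D = np.zeros((m, n), dtype=bool)
    C[:, 0] = np.arange(m + 1)
    S[0, :] = np.arange(n + 1)
    deg = IUPAC_DEGENERACY
    for i in range(1, m + 1):
        pset = deg[seq[i - 1]]
        for j in range(1, n + 1):
            rc = read[j - 1]
            mismatch = (rc if rc in "ACGTN" else "N") not in pset
            D[i - 1, j - 1] = mismatch
            dv = C[i - 1, j - 1]
            if not mismatch:
                C[i, j] = dv
                S[i, j] = S[i - 1, j - 1]
            else:
                best = dv + 1
                bs = S[i - 1, j - 1]
                uv = C[i - 1, j] + 1
                if uv < best:
                    best, bs = uv, S[i - 1, j]
                lv = C[i, j - 1] + 1
                if lv < best:
                    best, bs = lv, S[i, j - 1]
                C[i, j] = best
                S[i, j] = bs
    lac = []
    for j in range(n + 1):
        li = 0
        for i in range(m, -1, -1):
            if C[i, j] <= k:
                li = i
                break
        lac.append(li)
    return C, S, D, lac


def oracle_matrix(read: str, pattern: AdapterPattern, params: SearchParams) -> OracleMatrix:
    """Compute the full DP matrix and its structural bookkeeping."""
    k = params.effective_k(len(read), pattern.length)
    C, S, D, lac = _oracle_dp(read, pattern, k)
    return OracleMatrix(C=C, delta=D, starts=S, lac_per_column=lac, k=k)


def oracle_find(
    read: str, pattern: AdapterPattern, params: SearchParams
) -> list[MatchCandidate]:
    """Reference enumeration of all candidates via the full DP matrix.

    Full-pattern hits: one candidate per end position ``j`` with
    ``C[m, j] <= k``.  Suffix overlaps (from the last column): every
    pattern prefix length ``i < m`` whose aligned read-suffix length
    ``L`` satisfies ``L >= min_overlap`` and
    ``C[i, n] <= min(floor(L * e), k)``.
    """
    if not read:
        raise ValueError("read must be non-empty")
    m, n = pattern.length, len(read)
    k = params.effective_k(n, pattern.length)
    C, S, _, _ = _oracle_dp(read, pattern, k)
    out: list[MatchCandidate] = []
    for j in range(1, n + 1):
        if C[m, j] <= k:
            out.append(
                MatchCandidate(int(S[m, j]), j, int(C[m, j]), 0.0, m)
            )
    for i in range(1, m):
        d = int(C[i, n])
        if d > k:
            continue
        L = n - int(S[i, n])
        if L >= params.min_overlap and d <= params.overlap_threshold(L):
            out.append(MatchCandidate(int(S[i, n]), n, d, 0.0, i))
    return out


# ---------------------------------------------------------------------------
# Production kernel: the bit-masked queue search
# ---------------------------------------------------------------------------

def _queue_search(
    read: str,
    pattern: AdapterPattern,
    params: SearchParams,
    pen_seq: Optional[list[float]],
    delta: float,
    stats: Optional[SearchStats] = None,
) -> list[MatchCandidate]:
    """Shared engine for the plain and quality-weighted searches.

    ``pen_seq`` gives the substitution penalty at each read position
    (``None`` disables penalty tracking).  Cells carry (value, start[,
    penalty]); the start propagates with the diagonal/vertical/
    horizontal tie-break and, in the weighted case, the penalty is the
    minimum over predecessors achieving the minimal difference count,
    inheriting the diagonal at every matching position.
    """
    m, n = pattern.length, len(read)
    if n < 1:
        raise ValueError("read must be non-empty")
    k = params.effective_k(n, m)
    min_overlap = params.min_overlap
    masks = pattern.masks
    mask_n = masks["N"]
    INF = k + 1
    weighted = pen_seq is not None

    q = ColumnQueue()
    # Left-boundary diagonals: C[i, 0] = i is active while i <= k.
    seed = min(k, m)
    vals = q.values
    starts = q.starts
    pens = q.penalties
    vals.extend(range(1, seed + 1))
    starts.extend([0] * seed)
    if weighted:
        pens.extend(delta * i for i in range(1, seed + 1))

    out: list[MatchCandidate] = []
    report_full = out.append

    for j in range(1, n + 1):
        c = read[j - 1]
        M = masks.get(c, mask_n)
        # The row-m diagonal cannot extend further, but the retired cell
        # is still the horizontal predecessor of row m in this column.
        bottom_left_v = INF
        bottom_left_s = 0
        bottom_left_p = 0.0
        if len(vals) == m:
            bottom_left_v = vals.pop()
            bottom_left_s = starts.pop()
            if weighted:
                bottom_left_p = pens.pop()
        # Push the new topmost cell: its diagonal precursor is C[0, j-1].
        vals.insert(0, 0)
        starts.insert(0, j - 1)
        if weighted:
            pens.insert(0, 0.0)
        L = len(vals)
        prev_v = 0  # C[0, j]
        prev_s = j
        prev_p = 0.0
        if weighted:
            sp = pen_seq[j - 1]
            for p in range(L):
                dv = vals[p]
                if not (M >> p) & 1:
                    nv, ns, npen = dv, starts[p], pens[p]
                else:
                    nv = dv + 1
                    ns = starts[p]
                    npen = pens[p] + sp
                    uv = prev_v + 1
                    if uv < nv:
                        nv, ns, npen = uv, prev_s, prev_p + delta
                    elif uv == nv:
                        cand = prev_p + delta
                        if cand < npen:
                            npen = cand
                    if p + 1 < L:
                        lv, ls, lp = vals[p + 1], starts[p + 1], pens[p + 1]
                    else:
                        lv, ls, lp = bottom_left_v, bottom_left_s, bottom_left_p
                    if lv + 1 < nv:
                        nv, ns, npen = lv + 1, ls, lp + delta
                    elif lv + 1 == nv:
                        cand = lp + delta
                        if cand < npen:
                            npen = cand
                    if nv > k:
                        nv = INF
                vals[p] = nv
                starts[p] = ns
                pens[p] = npen
                prev_v, prev_s, prev_p = nv, ns, npen
            if L == m and vals[m - 1] <= k:
                report_full(
                    MatchCandidate(starts[m - 1], j, vals[m - 1], pens[m - 1], m)
                )
        else:
            for p in range(L):
                dv = vals[p]
                if not (M >> p) & 1:
                    nv, ns = dv, starts[p]
                else:
                    nv = dv + 1
                    ns = starts[p]
                    uv = prev_v + 1
                    if uv < nv:
                        nv, ns = uv, prev_s
                    if p + 1 < L:
                        lv, ls = vals[p + 1], starts[p + 1]
                    else:
                        lv, ls = bottom_left_v, bottom_left_s
                    if lv + 1 < nv:
                        nv, ns = lv + 1, ls
                    if nv > k:
                        nv = INF
                vals[p] = nv
                starts[p] = ns
                prev_v, prev_s = nv, ns
            if L == m and vals[m - 1] <= k:
                report_full(MatchCandidate(starts[m - 1], j, vals[m - 1], 0.0, m))
        # Retire dead diagonals from the bottom (the Ukkonen cutoff).
        while vals and vals[-1] > k:
            vals.pop()
            starts.pop()
            if weighted:
                pens.pop()
        if stats is not None:
            stats.columns += 1
            stats.live_cells += sum(1 for v in vals if v <= k)

    # Final O(m)-bounded check of the cells remaining in the queue:
    # read-suffix / pattern-prefix overlaps.
    for p in range(len(vals)):
        i = p + 1
        v = vals[p]
        if i >= m or v > k:
            continue
        L_ov = n - starts[p]
        if L_ov >= min_overlap and v <= params.overlap_threshold(L_ov):
            out.append(
                MatchCandidate(
                    starts[p], n, v, pens[p] if weighted else 0.0, i
                )
            )
    return out


def find_matches(
    read: str,
    pattern: AdapterPattern,
    params: SearchParams,
    stats: Optional[SearchStats] = None,
) -> list[MatchCandidate]:
    """Bit-masked k-difference search; same candidate multiset as
    ``oracle_find`` on every input."""
    return _queue_search(read, pattern, params, None, 0.0, stats)


def find_weighted_matches(
    read: str,
    quals: Sequence[int],
    pattern: AdapterPattern,
    params: SearchParams,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
    stats: Optional[SearchStats] = None,
) -> list[MatchCandidate]:
    """Quality-weighted search: identical candidate positions to
    ``find_matches``, each carrying the accumulated mismatch/indel
    penalty of its alignment.

    A read ``N`` is penalized at ``P_min`` (it carries no evidence
    either way); other mismatches at ``P(q)`` of the read base quality;
    indels at ``delta``.
    """
    if len(quals) != len(read):
        raise ValueError(
            f"quality/sequence length mismatch: {len(quals)} != {len(read)}"
        )
    ptab = penalty_table(penalty_params)
    cap = penalty_params.quality_cap
    p_min = penalty_params.p_min
    pen_seq = [
        p_min if c == "N" else float(ptab[min(max(q, 0), cap)])
        for c, q in zip(read, quals)
    ]
    return _queue_search(
        read, pattern, params, pen_seq, penalty_params.indel_penalty, stats
    )
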