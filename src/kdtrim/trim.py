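"""Decision layer: single-end 3' trimming, paired-end joint trimming with
reverse-complement verification, and Nextera long-mate-pair junction
splitting.

The paired-end rule exploits the geometry of read-through: when the
insert is shorter than the read length, both mates carry their adapter
from the same index ``idx`` (the insert length) and the retained
prefixes are exact reverse complements of each other.  Every candidate
``idx`` is scored as::

    score(idx) = pscore(read1[idx:], adapter1)
               + pscore(read2[idx:], adapter2)
               + pscore(read1[:idx], revcomp(read2[:idx]))

and the admissible candidate maximizing the score is applied to both
mates.  The third term is what makes paired-end trimming near-exact: a
wrong ``idx`` leaves the two retained prefixes out of register, which a
random-sequence comparison rejects immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Union

from .alphabet import reverse_complement
from .kdiff import (
    AdapterPattern,
    MatchCandidate,
    SearchParams,
    find_weighted_matches,
)
from .quality import DEFAULT_PENALTY_PARAMS, PenaltyParams, align_penalty

__all__ = [
    "ReadRecord",
    "ReadPair",
    "TrimMode",
    "TrimDecision",
    "LmpCategory",
    "revcomp",
    "trim_single",
    "pe_score",
    "trim_pair",
    "trim_lmp",
    "filter_min_length",
]

# Minimum exact 3' overlap demanded before a junction split (a split
# discards the read tail, so the evidence bar is higher than for 3'
# adapter trimming: a 12 nt exact suffix matches random sequence with
# probability 4^-12 ~ 6e-8 per read).
JUNCTION_MIN_OVERLAP = 12


@dataclass
class ReadRecord:
    """One FASTQ record: identifier, bases, decoded Phred qualities."""

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def prefix(self, length: int) -> "ReadRecord":
        """The record truncated to its first ``length`` bases."""
        return ReadRecord(self.id, self.seq[:length], self.qual[:length])


def _mate_core(read_id: str) -> str:
    token = read_id.split()[0] if read_id.split() else read_id
    if len(token) > 2 and token[-2] == "/" and token[-1] in "12":
        return token[:-2]
    return token


@dataclass
class ReadPair:
    """A synchronized mate pair; ids must agree up to the mate suffix."""

    read1: ReadRecord
    read2: ReadRecord

    def __post_init__(self) -> None:
        if _mate_core(self.read1.id) != _mate_core(self.read2.id):
            raise ValueError(
                f"mate id mismatch: {self.read1.id!r} vs {self.read2.id!r}"
            )


class TrimMode(str, Enum):
    NONE = "none"
    TAIL3 = "tail3"
    PE = "pe"
    JUNCTION = "junction"


@dataclass(frozen=True)
class TrimDecision:
    """Outcome of a trim: the retained-prefix length and its score."""

    mode: TrimMode
    trim_index: Optional[int] = None
    score: float = 0.0
    differences: int = 0

    def __post_init__(self) -> None:
        if (self.mode is TrimMode.NONE) != (self.trim_index is None):
            raise ValueError("trim_index must be absent iff mode is none")


class LmpCategory(str, Enum):
    JUNCTION_FOUND = "junction_found"
    NO_JUNCTION = "no_junction"
    EMPTY_AFTER_TRIM = "empty_after_trim"


def revcomp(seq: str) -> str:
    """Reverse complement with the full IUPAC complement table."""
    return reverse_complement(seq)


# ---------------------------------------------------------------------------
# Single-end 3' trimming
# ---------------------------------------------------------------------------

def _rank_key(cand: MatchCandidate, p_max: float):
    # pscore of the matched span; ties: longer match, then smaller start.
    score = cand.span * p_max - cand.penalty
    return (score, cand.span, -cand.start)


def _admissible(cand: MatchCandidate, error_ratio: float) -> bool:
    """Uniform error-ratio admissibility over the aligned read span.

    The kernel's full-pattern threshold k = floor(n * e) scales with the
    read length, which for a short pattern in a long read admits far
    more differences than the pattern has information for; the decision
    layer therefore re-applies the ratio over the aligned span, the
    same bound the suffix overlaps already satisfy by construction.
    """
    return cand.differences <= math.floor(cand.span * error_ratio)


def trim_single(
    read: ReadRecord,
    pattern: AdapterPattern,
    params: SearchParams,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
) -> tuple[TrimDecision, ReadRecord]:
    """Trim the best-scoring adapter occurrence from a read's 3' side.

    Candidates come from the quality-weighted k-difference search
    (including suffix overlaps); the pscore-maximal one wins and the
    read is truncated at its start.  With no admissible candidate the
    read is returned unchanged.
    """
    if not read.seq:
        raise ValueError("read must be non-empty")
    cands = [
        c
        for c in find_weighted_matches(
            read.seq, read.qual, pattern, params, penalty_params
        )
        if _admissible(c, params.error_ratio)
    ]
    if not cands:
        return TrimDecision(TrimMode.NONE), read
    p_max = penalty_params.p_max
    best = max(cands, key=lambda c: _rank_key(c, p_max))
    score = best.span * p_max - best.penalty
    decision = TrimDecision(TrimMode.TAIL3, best.start, score, best.differences)
    return decision, read.prefix(best.start)


# ---------------------------------------------------------------------------
# Paired-end joint trimming
# ---------------------------------------------------------------------------

def _mate_prefix_penalty(
    pair: ReadPair, idx: int, penalty_params: PenaltyParams
) -> tuple[int, float]:
    """Gap-free comparison of read1[:idx] with revcomp(read2[:idx]).

    The retained prefixes are reads of the same physical template, so
    their disagreement can only come from substitution errors: the
    comparison is position-wise (no indels), each mismatch penalized at
    the smaller of the two base qualities.  This is what makes a wrong
    ``idx`` unmistakable — shifted prefixes disagree at ~3/4 of their
    positions — where a gapped alignment would absorb small shifts.
    """
    r1, r2 = pair.read1, pair.read2
    x = r1.seq[:idx]
    y = reverse_complement(r2.seq[:idx])
    if x == y:
        return 0, 0.0
    qx = r1.qual[:idx]
    qy = r2.qual[:idx][::-1]
    from .quality import mismatch_penalty  # local: avoids a module cycle

    d = 0
    pen = 0.0
    p_min = penalty_params.p_min
    for cx, cy, a, b in zip(x, y, qx, qy):
        if cx != cy or cx == "N":
            d += 1
            pen += (
                p_min
                if (cx == "N" or cy == "N")
                else mismatch_penalty(min(a, b), penalty_params)
            )
    return d, pen


def _pe_terms(
    pair: ReadPair,
    pattern1: AdapterPattern,
    pattern2: AdapterPattern,
    idx: int,
    penalty_params: PenaltyParams,
) -> list[tuple[int, int, float]]:
    """The three (span, differences, penalty) components of score(idx)."""
    r1, r2 = pair.read1, pair.read2
    tail1, tail2 = r1.seq[idx:], r2.seq[idx:]
    out = []
    for tail, quals, pat in (
        (tail1, r1.qual[idx:], pattern1),
        (tail2, r2.qual[idx:], pattern2),
    ):
        d, pen = align_penalty(tail, pat.sequence, qx=quals, params=penalty_params)
        out.append((min(len(tail), pat.length), d, pen))
    d3, pen3 = _mate_prefix_penalty(pair, idx, penalty_params)
    out.append((idx, d3, pen3))
    return out


def pe_score(
    pair: ReadPair,
    pattern1: AdapterPattern,
    pattern2: AdapterPattern,
    idx: int,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
) -> float:
    """The three-term paired-end score of trimming both mates at ``idx``.

    Adapter terms align each read tail against its adapter; the third
    term aligns read1's retained prefix against the reverse complement
    of read2's, mismatches penalized at the smaller of the two base
    qualities.
    """
    len1, len2 = len(pair.read1), len(pair.read2)
    if not 0 <= idx <= min(len1, len2):
        raise ValueError(f"idx {idx} out of range [0, {min(len1, len2)}]")
    terms = _pe_terms(pair, pattern1, pattern2, idx, penalty_params)
    p_max = penalty_params.p_max
    spans = (len1 - idx, len2 - idx, idx)
    return sum(s * p_max for s in spans) - sum(pen for _, _, pen in terms)


def trim_pair(
    pair: ReadPair,
    pattern1: AdapterPattern,
    pattern2: AdapterPattern,
    params: SearchParams,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
) -> tuple[TrimDecision, ReadPair]:
    """Jointly trim a mate pair at the score-maximal admissible index.

    Candidate indices are the union of start positions of adapter
    occurrences in either mate (down to 1 nt of 3' overlap: the
    reverse-complement verification replaces the minimum-overlap guard
    used in single-end mode).  A candidate is admissible when each of
    the three score components individually satisfies the error-ratio
    constraint ``differences <= floor(span * e)``.  Both mates are
    truncated to the winning index.
    """
    pe_params = replace(params, min_overlap=1)
    r1, r2 = pair.read1, pair.read2
    c1 = find_weighted_matches(r1.seq, r1.qual, pattern1, pe_params, penalty_params)
    c2 = find_weighted_matches(r2.seq, r2.qual, pattern2, pe_params, penalty_params)
    limit = min(len(r1), len(r2))
    idxs = sorted({c.start for c in c1} | {c.start for c in c2})
    e = params.error_ratio
    p_max = penalty_params.p_max
    best_idx: Optional[int] = None
    best_score = -math.inf
    best_d = 0
    for idx in idxs:
        if idx > limit:
            continue
        terms = _pe_terms(pair, pattern1, pattern2, idx, penalty_params)
        if any(d > math.floor(span * e) for span, d, _ in terms):
            continue
        spans = (len(r1) - idx, len(r2) - idx, idx)
        score = sum(s * p_max for s in spans) - sum(pen for _, _, pen in terms)
        if score > best_score:
            best_idx, best_score = idx, score
            best_d = sum(d for _, d, _ in terms)
    if best_idx is None:
        return TrimDecision(TrimMode.NONE), pair
    trimmed = ReadPair(r1.prefix(best_idx), r2.prefix(best_idx))
    return TrimDecision(TrimMode.PE, best_idx, best_score, best_d), trimmed


# ---------------------------------------------------------------------------
# Nextera long-mate-pair junction splitting
# ---------------------------------------------------------------------------

def _trim_junction(
    read: ReadRecord,
    junction: AdapterPattern,
    params: SearchParams,
    penalty_params: PenaltyParams,
) -> tuple[ReadRecord, LmpCategory]:
    if not read.seq:
        return read, LmpCategory.EMPTY_AFTER_TRIM
    cands = [
        c
        for c in find_weighted_matches(
            read.seq, read.qual, junction, params, penalty_params
        )
        if _admissible(c, params.error_ratio)
    ]
    if not cands:
        return read, LmpCategory.NO_JUNCTION
    p_max = penalty_params.p_max
    best = max(cands, key=lambda c: _rank_key(c, p_max))
    trimmed = read.prefix(best.start)
    category = (
        LmpCategory.EMPTY_AFTER_TRIM if best.start == 0 else LmpCategory.JUNCTION_FOUND
    )
    return trimmed, category


def trim_lmp(
    pair: ReadPair,
    junction: AdapterPattern,
    pattern1: AdapterPattern,
    pattern2: AdapterPattern,
    params: SearchParams,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
    junction_min_overlap: int = JUNCTION_MIN_OVERLAP,
) -> tuple[ReadPair, tuple[LmpCategory, LmpCategory]]:
    """Two-stage Nextera LMP trimming.

    Stage 1 trims 3' adapters exactly as for paired-end reads; stage 2
    searches each mate independently for the junction adapter
    (including 3' suffix overlaps of at least ``junction_min_overlap``
    bases) and keeps the prefix before the junction start.  Each mate
    is labeled junction_found / no_junction / empty_after_trim.
    """
    _, stage1 = trim_pair(pair, pattern1, pattern2, params, penalty_params)
    j_params = replace(
        params, min_overlap=max(params.min_overlap, junction_min_overlap)
    )
    out1, cat1 = _trim_junction(stage1.read1, junction, j_params, penalty_params)
    out2, cat2 = _trim_junction(stage1.read2, junction, j_params, penalty_params)
    return ReadPair(out1, out2), (cat1, cat2)


# ---------------------------------------------------------------------------
# Length filtering
# ---------------------------------------------------------------------------

def filter_min_length(
    records: Iterable[Union[ReadRecord, ReadPair]],
    min_length: int,
    pair_policy: str = "both",
) -> tuple[list[Union[ReadRecord, ReadPair]], int]:
    """Keep records/pairs whose length satisfies ``min_length``.

    Pairs are kept when both mates (default) or any mate meets the
    bound.  Returns (kept, discarded count); kept + discarded equals
    the input count.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    if pair_policy not in ("both", "any"):
        raise ValueError("pair_policy must be 'both' or 'any'")
    kept: list[Union[ReadRecord, ReadPair]] = []
    discarded = 0
    for rec in records:
        if isinstance(rec, ReadPair):
            ok1 = len(rec.read1) >= min_length
            ok2 = len(rec.read2) >= min_length
            ok = (ok1 and ok2) if pair_policy == "both" else (ok1 or ok2)
        else:
            ok = len(rec.seq) >= min_length
        if ok:
            kept.append(rec)
        else:
            discarded += 1
    return kept, discarded
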