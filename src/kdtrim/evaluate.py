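"""Confusion-category bookkeeping and trimming quality metrics.

Each evaluated read falls into exactly one of six categories when its
post-trim length is compared with the ground truth: TP (contaminated,
trimmed at the true index), FP_ot (contaminated, over-trimmed), FN_ut
(contaminated, trimmed but short of the adapter), FN_fr (contaminated,
untrimmed — false retaining), FP_ft (clean, trimmed — false trimming)
and TN (clean, untrimmed).  From the counts::

    PPV  = TP / (TP + FP_ft + FP_ot + FN_ut)
    Sen  = TP / (TP + FN_fr + FN_ut + FP_ot)
    Spec = TN / (TN + FP_ft)
    mCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with FP = FP_ft + FP_ot and FN = FN_fr + FN_ut.  Note the PPV
denominator counts under-trimmed reads against precision even though
they were trimmed — an under-trimmed read still carries adapter
sequence, so its trim was not a correct positive call.  A metric whose
denominator is zero is reported as absent, never as 0/0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

from .kdiff import SearchParams, build_pattern
from .quality import DEFAULT_PENALTY_PARAMS, PenaltyParams
from .simulate import GroundTruthRecord
from .trim import ReadPair, ReadRecord, trim_pair, trim_single

__all__ = [
    "Category",
    "ConfusionCounts",
    "MetricSet",
    "classify_read",
    "count_categories",
    "compute_metrics",
    "RocPoint",
    "roc_sweep",
]


_CATEGORIES = ("TP", "FP_ft", "FP_ot", "FN_fr", "FN_ut", "TN")
Category = str


@dataclass(frozen=True)
class ConfusionCounts:
    """The six trimming confusion categories."""

    TP: int = 0
    FP_ft: int = 0
    FP_ot: int = 0
    FN_fr: int = 0
    FN_ut: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if any(getattr(self, c) < 0 for c in _CATEGORIES):
            raise ValueError("counts must be non-negative")

    @property
    def FP(self) -> int:
        return self.FP_ft + self.FP_ot

    @property
    def FN(self) -> int:
        return self.FN_fr + self.FN_ut

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def add(self, category: Category) -> "ConfusionCounts":
        if category not in _CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return replace(self, **{category: getattr(self, category) + 1})

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in _CATEGORIES}


@dataclass(frozen=True)
class MetricSet:
    """PPV / sensitivity / specificity / Matthews correlation; ``None``
    marks a metric whose denominator was zero."""

    ppv: Optional[float]
    sen: Optional[float]
    spec: Optional[float]
    mcc: Optional[float]


def classify_read(
    truth: GroundTruthRecord,
    observed_length: int,
    tolerance: int = 0,
    read_length: int = 0,
) -> Category:
    """Assign one read to its confusion category.

    ``observed_length`` is the read length after trimming; a read is
    untrimmed iff ``observed_length == read_length`` (the original
    length).  ``tolerance`` widens the boundary band counted as a
    correct trim.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if read_length < 1:
        raise ValueError("read_length (the original length) is required")
    if observed_length > read_length:
        raise ValueError(
            f"observed length {observed_length} exceeds read length {read_length}"
        )
    trimmed = observed_length < read_length
    if truth.contaminated:
        true_idx = truth.true_trim_index
        if abs(observed_length - true_idx) <= tolerance:
            return "TP"
        if observed_length < true_idx - tolerance:
            return "FP_ot"
        # past the true index: not trimmed at all (false retaining) vs
        # trimmed but short of the adapter (under-trimming)
        return "FN_ut" if trimmed else "FN_fr"
    return "FP_ft" if trimmed else "TN"


def count_categories(
    truth_by_id: Mapping[str, GroundTruthRecord],
    observed_lengths: Mapping[str, int],
    tolerance: int = 0,
    read_length: int = 0,
) -> ConfusionCounts:
    """Classify every read in the manifest; reads absent from
    ``observed_lengths`` count as fully trimmed (length 0)."""
    counts = ConfusionCounts()
    for rid, t in truth_by_id.items():
        obs = observed_lengths.get(rid, 0)
        counts = counts.add(classify_read(t, obs, tolerance, read_length))
    return counts


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """PPV, Sen, Spec and mCC from the six raw counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn = counts.TP, counts.TN
    fp, fn = counts.FP, counts.FN
    ppv = _ratio(tp, tp + counts.FP_ft + counts.FP_ot + counts.FN_ut)
    sen = _ratio(tp, tp + counts.FN_fr + counts.FN_ut + counts.FP_ot)
    spec = _ratio(tn, tn + counts.FP_ft)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return MetricSet(ppv=ppv, sen=sen, spec=spec, mcc=mcc)


# ---------------------------------------------------------------------------
# ROC sweep over stringency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocPoint:
    e: float
    FP: int
    TP: int
    FPR: Optional[float]
    TPR: Optional[float]


def roc_sweep(
    dataset: Sequence[Union[ReadRecord, ReadPair]],
    truth_by_id: Mapping[str, GroundTruthRecord],
    adapter1: str,
    adapter2: Optional[str],
    stringency_grid: Iterable[float],
    mode: str = "pe",
    tolerance: int = 0,
    min_overlap: int = 3,
    penalty_params: PenaltyParams = DEFAULT_PENALTY_PARAMS,
) -> list[RocPoint]:
    """Run the trimmer at each error ratio and report (FPR, TPR) points.

    ``FPR = FP / (FP + TN)`` and ``TPR = Sen``; points are returned
    sorted by ``e``.
    """
    grid = sorted(stringency_grid)
    if not grid:
        raise ValueError("stringency grid must be non-empty")
    if any(not 0.0 <= e < 1.0 for e in grid):
        raise ValueError("stringency values must lie in [0, 1)")
    p1 = build_pattern(adapter1)
    p2 = build_pattern(adapter2) if adapter2 else None
    out = []
    for e in grid:
        params = SearchParams(error_ratio=e, min_overlap=min_overlap)
        observed: dict[str, int] = {}
        read_length = None
        for item in dataset:
            if isinstance(item, ReadPair):
                if mode == "pe":
                    if p2 is None:
                        raise ValueError("pe mode requires adapter2")
                    _, trimmed = trim_pair(item, p1, p2, params, penalty_params)
                    observed[item.read1.id] = len(trimmed.read1)
                    observed[item.read2.id] = len(trimmed.read2)
                else:
                    for rec, pat in ((item.read1, p1), (item.read2, p2 or p1)):
                        _, tr = trim_single(rec, pat, params, penalty_params)
                        observed[rec.id] = len(tr)
                read_length = len(item.read1)
            else:
                _, tr = trim_single(item, p1, params, penalty_params)
                observed[item.id] = len(tr)
                read_length = len(item)
        counts = count_categories(truth_by_id, observed, tolerance, read_length)
        metrics = compute_metrics(counts)
        fpr = _ratio(counts.FP, counts.FP + counts.TN)
        out.append(RocPoint(e=e, FP=counts.FP, TP=counts.TP, FPR=fpr, TPR=metrics.sen))
    return out
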