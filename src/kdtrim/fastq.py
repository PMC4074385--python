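"""FASTQ reading/writing (plain and gzip) and paired-file synchronization.

Strictly 4-line records: multi-line (wrapped) sequences are rejected
rather than joined, since modern NGS FASTQ is 4-line and silent joining
hides corruption.  Parse errors name the offending line number; paired
readers name the offending record index.  Gzip input is auto-detected
from the magic bytes; gzip output is written with a zeroed timestamp so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .trim import ReadPair, ReadRecord

__all__ = [
    "FastqDialect",
    "FastqParseError",
    "PairSyncError",
    "read_fastq",
    "write_fastq",
    "read_paired",
    "detect_quality_offset",
]

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class FastqDialect:
    """Quality encoding offset and container choice.

    ``gzip=None`` means auto-detect on read (magic bytes) and infer
    from the ``.gz`` suffix on write.
    """

    phred_offset: int = 33
    gzip: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")


DEFAULT_DIALECT = FastqDialect()


class FastqParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class PairSyncError(ValueError):
    def __init__(self, message: str, index: int):
        super().__init__(f"record {index}: {message}")
        self.index = index


def _open_text_read(source: Union[str, Path], use_gzip: Optional[bool]):
    path = Path(source)
    if use_gzip is None:
        with open(path, "rb") as fh:
            use_gzip = fh.read(2) == _GZIP_MAGIC
    if use_gzip:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(
    source: Union[str, Path],
    dialect: FastqDialect = DEFAULT_DIALECT,
) -> Iterator[ReadRecord]:
    """Yield records from a 4-line FASTQ file, plain or gzip.

    Qualities are decoded as ``ord(char) - phred_offset``.  Raises
    :class:`FastqParseError` (naming the line number) on malformed
    input: a record not starting with ``@``, a sequence/quality length
    mismatch, or a truncated record.
    """
    offset = dialect.phred_offset
    with _open_text_read(source, dialect.gzip) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"record does not start with '@': {header[:30]!r}", lineno
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError("truncated record", lineno)
            seq = seq.rstrip("\n")
            plus = plus.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqParseError(
                    "separator line does not start with '+' "
                    "(multi-line FASTQ is not supported)",
                    lineno + 2,
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence length {len(seq)} != quality length {len(qual)}",
                    lineno + 3,
                )
            lineno += 3
            yield ReadRecord(
                id=header[1:],
                seq=seq.upper(),
                qual=[ord(c) - offset for c in qual],
            )


def write_fastq(
    records: Iterable[ReadRecord],
    sink: Union[str, Path],
    dialect: FastqDialect = DEFAULT_DIALECT,
) -> int:
    """Write 4-line records; returns the record count.

    Qualities are re-encoded with the dialect's offset (clamped at 0 so
    the written character is never below the offset).  Gzip output uses
    a fixed zero mtime, making repeated writes byte-identical.
    """
    path = Path(sink)
    use_gzip = dialect.gzip
    if use_gzip is None:
        use_gzip = path.suffix == ".gz"
    offset = dialect.phred_offset
    count = 0
    if use_gzip:
        raw = open(path, "wb")
        # empty embedded filename + zero mtime => reproducible bytes
        fh: io.TextIOBase = io.TextIOWrapper(
            gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0),
            encoding="ascii",
        )
    else:
        raw = None
        fh = open(path, "wt", encoding="ascii")
    try:
        for rec in records:
            qual = "".join(chr(max(q, 0) + offset) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            count += 1
    finally:
        fh.close()
        if raw is not None:
            raw.close()
    return count


def read_paired(
    source1: Union[str, Path],
    source2: Union[str, Path],
    dialect: FastqDialect = DEFAULT_DIALECT,
) -> Iterator[ReadPair]:
    """Zip two FASTQ files positionally into mate pairs.

    Raises :class:`PairSyncError` (naming the record index) on unequal
    record counts or a mate-id mismatch.
    """
    it1 = read_fastq(source1, dialect)
    it2 = read_fastq(source2, dialect)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = "first" if r1 is None else "second"
            raise PairSyncError(f"{short} file ran out of records", index)
        try:
            yield ReadPair(r1, r2)
        except ValueError as exc:
            raise PairSyncError(str(exc), index) from None
        index += 1


def detect_quality_offset(quality_strings: Iterable[str]) -> int:
    """Infer the Phred offset (33 or 64) from raw quality strings.

    Any character below ASCII 59 implies offset 33; all characters at
    or above 64 imply offset 64; an ambiguous sample (everything in the
    59-63 overlap zone) defaults to 33 with a warning.  An empty sample
    is an error.
    """
    lo, hi = None, None
    for qs in quality_strings:
        for ch in qs:
            o = ord(ch)
            lo = o if lo is None or o < lo else lo
            hi = o if hi is None or o > hi else hi
    if lo is None:
        raise ValueError("cannot detect quality offset from an empty sample")
    if lo < 59:
        return 33
    if lo >= 64:
        return 64
    warnings.warn(
        "quality characters all fall in the Phred+33/+64 overlap zone; "
        "assuming Phred+33",
        stacklevel=2,
    )
    return 33
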