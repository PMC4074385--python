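"""IUPAC nucleotide alphabet: degeneracy sets and complements.

Shared by the matching kernel (mismatch bit-vectors), the penalty
alignment (read-vs-adapter and read-vs-read comparisons) and the trim
engine (reverse complements).

Matching rule used throughout the package: a read character ``r``
matches a pattern character ``p`` iff ``r`` is in the degeneracy set of
``p``.  The degeneracy set of a concrete base is just itself, so an
``N`` in the read never matches a concrete pattern base (an N carries no
evidence), while a pattern ``N`` matches anything, including a read
``N``.
"""

from __future__ import annotations

# Degeneracy sets over the read-side alphabet {A,C,G,T,N}.  Pattern 'N'
# (and only 'N') also admits a read 'N'.
IUPAC_DEGENERACY: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "U": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_ALPHABET = frozenset(IUPAC_DEGENERACY)

READ_BASES = "ACGTN"


def is_iupac(seq: str) -> bool:
    """True iff every character of ``seq`` is an IUPAC nucleotide code."""
    return all(c in IUPAC_ALPHABET for c in seq.upper())


def validate_iupac(seq: str, what: str = "sequence") -> str:
    """Upper-case ``seq`` and raise ``ValueError`` on non-IUPAC characters."""
    up = seq.upper()
    for i, c in enumerate(up):
        if c not in IUPAC_ALPHABET:
            raise ValueError(
                f"invalid {what}: character {c!r} at position {i} is not an "
                "IUPAC nucleotide code"
            )
    return up


def matches(pattern_char: str, read_char: str) -> bool:
    """IUPAC-aware match test (pattern side may be degenerate)."""
    deg = IUPAC_DEGENERACY.get(pattern_char)
    if deg is None:
        raise ValueError(f"non-IUPAC pattern character {pattern_char!r}")
    return (read_char if read_char in "ACGTN" else "N") in deg


def reverse_complement(seq: str) -> str:
    """Reverse complement with the full IUPAC complement table.

    Raises ``ValueError`` on non-IUPAC characters; involution holds:
    ``reverse_complement(reverse_complement(x)) == x``.
    """
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None
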