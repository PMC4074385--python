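"""Synthetic read-through generator with known ground truth.

Emulates the canonical adapter-contamination experiment: paired 100 bp
reads drawn from a reference where a controlled fraction of sequencing
fragments is shorter than the read length, so the sequencer reads
through the insert into the adapter (and random filler beyond it).
Both mates of a read-through pair carry their adapter from the same
index — the insert length — and their retained prefixes are exact
reverse complements, which is precisely the structure the paired-end
trimmer exploits.

The generator writes a per-read ground-truth manifest (insert length
and true trim index), making exact confusion-matrix evaluation
possible; the quality model is a flat mean Phred value with optional
per-base jitter and substitution errors drawn at the per-base error
probability ``10^(-q/10)`` (indel errors optional), applied to adapter
bases as well — the hard case for the matcher.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .trim import ReadPair, ReadRecord

__all__ = [
    "SimConfig",
    "GroundTruthRecord",
    "simulate_dataset",
    "solve_contamination_fraction",
    "write_manifest",
    "read_manifest",
    "TRUSEQ_ADAPTER1",
    "TRUSEQ_ADAPTER2",
    "NEXTERA_JUNCTION",
]

# Public Illumina sequences used as defaults: TruSeq R1/R2 3' adapters
# and the 19 nt Nextera transposase junction motif.
TRUSEQ_ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"
NEXTERA_JUNCTION = "CTGTCTCTTATACACATCT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated dataset.

    Fragment lengths are Normal(fragment_mean, fragment_sd) clipped at
    0, so the contaminated fraction is exactly
    ``Phi((read_length - mean) / sd)``.  ``error_model`` is
    ``error_free`` (constant qualities, no errors) or
    ``quality_driven`` (per-base substitution probability
    ``10^(-q/10)``).  ``planted_motifs`` copies of adapter1 are written
    into the reference to emulate homology-driven false-positive risk.
    """

    genome_length: int = 100_000
    read_length: int = 100
    n_pairs: int = 1_000
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    adapter1: str = TRUSEQ_ADAPTER1
    adapter2: str = TRUSEQ_ADAPTER2
    junction: Optional[str] = None
    error_model: str = "error_free"
    mean_quality: int = 40
    quality_jitter: int = 0
    indel_rate: float = 0.0
    planted_motifs: int = 0
    seed: int = 0
    mode: str = "PE"

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.n_pairs < 1:
            raise ValueError("read_length and n_pairs must be >= 1")
        if self.fragment_sd < 0:
            raise ValueError("fragment_sd must be >= 0")
        if self.error_model not in ("error_free", "quality_driven"):
            raise ValueError("error_model must be error_free or quality_driven")
        if self.mode not in ("SE", "PE", "LMP"):
            raise ValueError("mode must be SE, PE or LMP")
        if self.mode == "LMP" and not self.junction:
            raise ValueError("LMP mode requires a junction sequence")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-read truth: contaminated iff a true trim index exists."""

    read_id: str
    insert_length: int
    true_trim_index: Optional[int]

    @property
    def contaminated(self) -> bool:
        return self.true_trim_index is not None


def solve_contamination_fraction(
    target: float, read_length: int, fragment_sd: float
) -> float:
    """Fragment mean giving ``P(length < read_length) = target``.

    Inverts the normal CDF: ``mu = read_length - Phi^-1(target) * sd``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target fraction must lie in (0, 1)")
    return read_length - float(norm.ppf(target)) * fragment_sd


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _complement_array(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        table[a] = b
    return table[arr]


def _apply_errors(
    rng: np.random.Generator, seq: np.ndarray, quals: np.ndarray, indel_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Substitution (and optional indel) errors at rate 10^(-q/10)."""
    p_err = np.power(10.0, -quals / 10.0)
    hit = rng.random(seq.size) < p_err
    if hit.any():
        seq = seq.copy()
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        lut = np.zeros(256, dtype=np.int64)
        lut[list(_BASES)] = np.arange(4)
        idx = lut[seq[hit]]
        seq[hit] = _BASES[(idx + shift) % 4]
    if indel_rate > 0.0:
        keep = rng.random(seq.size) >= indel_rate
        seq = seq[keep]
        quals = quals[keep]
    return seq, quals


def _finish_read(
    rng: np.random.Generator,
    cfg: SimConfig,
    payload: str,
    read_id: str,
) -> ReadRecord:
    """Pad/truncate to read_length, draw qualities, apply the error model."""
    L = cfg.read_length
    if len(payload) < L:
        filler = _random_genome(rng, L - len(payload))
        payload = payload + filler
    seq = np.frombuffer(payload[:L].encode("ascii"), dtype=np.uint8)
    if cfg.error_model == "error_free":
        quals = np.full(L, cfg.mean_quality, dtype=np.int64)
        return ReadRecord(read_id, payload[:L], quals.tolist())
    if cfg.quality_jitter > 0:
        jit = rng.integers(-cfg.quality_jitter, cfg.quality_jitter + 1, size=L)
        quals = np.clip(cfg.mean_quality + jit, 2, 41)
    else:
        quals = np.full(L, cfg.mean_quality, dtype=np.int64)
    seq, quals = _apply_errors(rng, seq, quals.astype(float), cfg.indel_rate)
    if seq.size < L:  # deletions shortened the read: refill from random bases
        pad = rng.choice(_BASES, size=L - seq.size)
        seq = np.concatenate([seq, pad])
        quals = np.concatenate([quals, np.full(L - quals.size, cfg.mean_quality)])
    return ReadRecord(read_id, seq.tobytes().decode("ascii"), [int(q) for q in quals])


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[Union[ReadRecord, ReadPair]], list[GroundTruthRecord]]:
    """Generate reads plus a per-read ground-truth manifest.

    PE/SE modes: fragments at uniform positions, read1 the forward
    strand and read2 the reverse complement, each padded with its
    adapter and random filler when the fragment is shorter than the
    read; the true trim index equals the insert length for contaminated
    reads.  LMP mode: the junction sequence is embedded at a uniform
    (fully contained) position inside each read, joining two unrelated
    reference sub-fragments; the true trim index is the junction start.
    Identical configs (including the seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.genome_length)
    if config.planted_motifs > 0:
        g = bytearray(genome.encode("ascii"))
        a1 = config.adapter1.encode("ascii")
        for _ in range(config.planted_motifs):
            pos = int(rng.integers(0, config.genome_length - len(a1) + 1))
            g[pos : pos + len(a1)] = a1
        genome = g.decode("ascii")
    L = config.read_length
    reads: list[Union[ReadRecord, ReadPair]] = []
    truth: list[GroundTruthRecord] = []

    if config.mode == "LMP":
        jlen = len(config.junction)
        if jlen > L:
            raise ValueError("junction longer than the read length")
        for i in range(config.n_pairs):
            pair_reads = []
            for mate in (1, 2):
                rid = f"sim_{i:06d}/{mate}"
                jpos = int(rng.integers(0, L - jlen + 1))
                head = _fragment(rng, genome, jpos)
                tail = _fragment(rng, genome, L - jpos - jlen)
                rec = _finish_read(rng, config, head + config.junction + tail, rid)
                pair_reads.append(rec)
                truth.append(GroundTruthRecord(rid, jpos, jpos))
            reads.append(ReadPair(*pair_reads))
        return reads, truth

    for i in range(config.n_pairs):
        frag_len = int(round(max(0.0, rng.normal(config.fragment_mean, config.fragment_sd))))
        frag_len = min(frag_len, config.genome_length)
        pos = int(rng.integers(0, config.genome_length - frag_len + 1))
        frag = genome[pos : pos + frag_len]
        insert = frag_len
        trim = frag_len if frag_len < L else None
        rid1 = f"sim_{i:06d}/1"
        rec1 = _finish_read(rng, config, frag[:L] if trim is None else frag + config.adapter1, rid1)
        truth.append(GroundTruthRecord(rid1, insert, trim))
        if config.mode == "SE":
            reads.append(rec1)
            continue
        rid2 = f"sim_{i:06d}/2"
        rc = _revcomp_str(frag)
        rec2 = _finish_read(rng, config, rc[:L] if trim is None else rc + config.adapter2, rid2)
        truth.append(GroundTruthRecord(rid2, insert, trim))
        reads.append(ReadPair(rec1, rec2))
    return reads, truth


def _fragment(rng: np.random.Generator, genome: str, length: int) -> str:
    if length <= 0:
        return ""
    pos = int(rng.integers(0, len(genome) - length + 1))
    return genome[pos : pos + length]


def _revcomp_str(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _complement_array(arr[::-1]).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Manifest I/O (tab-separated; one row per read)
# ---------------------------------------------------------------------------

_MANIFEST_HEADER = "read_id\tinsert_length\ttrue_trim_index\tcontaminated"


def write_manifest(truth: list[GroundTruthRecord], path: Union[str, Path]) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(_MANIFEST_HEADER + "\n")
        for t in truth:
            tt = "" if t.true_trim_index is None else str(t.true_trim_index)
            fh.write(f"{t.read_id}\t{t.insert_length}\t{tt}\t{int(t.contaminated)}\n")


def read_manifest(path: Union[str, Path]) -> dict[str, GroundTruthRecord]:
    out: dict[str, GroundTruthRecord] = {}
    with open(path, "rt", encoding="ascii") as fh:
        header = fh.readline().rstrip("\n")
        if header != _MANIFEST_HEADER:
            raise ValueError(f"unrecognized manifest header: {header!r}")
        for line in fh:
            rid, ins, tt, _flag = line.rstrip("\n").split("\t")
            out[rid] = GroundTruthRecord(
                rid, int(ins), None if tt == "" else int(tt)
            )
    return out
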