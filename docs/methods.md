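# Methods

## Problem and model

A read `S = s1…sn` may end in adapter sequence when its insert is
shorter than the read length. Trimming is modeled as semi-global
(end-space-free) alignment of the adapter pattern `P = p1…pm` against
the read: the classic DP matrix `C[0..m, 0..n]` with `C[0,j] = 0`
(the adapter may start anywhere in the read), `C[i,0] = i` (the
adapter itself is not free), and the unit-cost recurrence
`C[i,j] = min(C[i−1,j−1]+δij, C[i−1,j]+1, C[i,j−1]+1)`.

Two candidate classes are reported:

* **full-pattern hits** — end positions `j` with `C[m,j] ≤ k`, where
  `k = ⌊n·e⌋` for error ratio `e` (clamped to `k < m`, overridable);
* **suffix overlaps** — from the final column, pattern prefix lengths
  `i < m` whose aligned read-suffix length `L` satisfies
  `L ≥ min_overlap` and `C[i,n] ≤ ⌊L·e⌋` (a partially read-through
  adapter at the 3′ end).

Coordinates are 0-based half-open `[start, end)`; the trim index is the
chosen candidate's `start`.

## The cutoff queue kernel

The production kernel (`find_matches` / `find_weighted_matches`) stores
only the active cells of the current column in a queue. Pushing the
new topmost cell (row 1) shifts every stored cell one position down its
diagonal, so a queue slot follows one diagonal of the matrix. Three
facts keep the update cheap:

1. values along a diagonal are monotonically non-decreasing, so a cell
   whose pattern position matches the current read character equals its
   diagonal precursor and is never recomputed — mismatch positions per
   read character are precomputed once as bit-vectors over the pattern;
2. a cell that exceeds `k` is dead forever along its diagonal (marked
   and skipped; dead cells at the queue bottom are retired — the
   Ukkonen cutoff — and so is the row-`m` cell, whose diagonal cannot
   extend, though its value is kept one column as the horizontal
   predecessor of row `m`);
3. at `k` below the pattern length the expected number of live cells
   per column on random sequence is O(k), giving O(k·n) expected time
   in O(m) space. The suite asserts a generous version of this
   (mean live cells ≤ 5·(k+1)).

The queue is seeded with the left-boundary diagonals (`C[i,0] = i` for
`i ≤ k`), which is what lets hits with leading pattern deletions (and
reads shorter than the pattern) be found. After the last column the
cells remaining in the queue are checked once (an O(m) step) for
suffix overlaps.

A full-matrix oracle (`oracle_find`) implements the same contract by
brute force and is kept permanently; a randomized equivalence test
(patterns 4–16 nt, reads 20–100 nt, k ≤ 4, thousands of instances)
asserts the candidate multisets are identical. Both implementations
propagate the alignment start with the same deterministic predecessor
preference — diagonal, then vertical, then horizontal — so starts agree
exactly; the capping of dead values at `k+1` cannot alter any reported
cell because a predecessor that yields a value ≤ k is itself ≤ k−1 and
therefore never capped.

## Quality-weighted scoring

A mismatch against a base called at Phred quality `q` costs

    P(q) = P_min                      q ≤ 0
         = P_min + q/40·(P_max−P_min) 0 < q < 40
         = P_max                      q ≥ 40

with `P_min = −log10(1/3)` and `P_max = −log10(10^(40/−10)/3)`; on the
open interval this equals `−log10(10^(q/−10)/3)`, the negative log of
the probability that the base truly matches given a sequencing error.
Indels cost `delta = P_max`. Defaults live in `PenaltyParams`
(`quality_cap = 40`); qualities clamp to the endpoints, and a read `N`
is always a mismatch penalized at `P_min` (an N carries no evidence
either way), while IUPAC codes in the adapter match their degeneracy
sets.

In the weighted kernel the unit-cost difference count alone governs
admissibility and the start/difference bookkeeping (so candidate
positions are identical with and without qualities — a tested
invariant); the penalty is carried alongside, minimized over
predecessors that achieve the minimal difference count, inheriting the
diagonal at every matching position. `pscore(x,y) = |x|·P_max −
penalty(x,y)` uses a plain penalty DP (no cutoff) that is anchored at
the 5′ ends and end-gap free at both 3′ ends: whichever sequence runs
out ends the alignment. Free 3′ ends are essential — a read tail that
runs through the whole adapter into filler must not be charged for its
unmatched suffix, otherwise every fully-read-through candidate would be
rejected. Difference count and penalty are minimized lexicographically
by packing them into one float key (differences·2^14 + penalty, exact
for any realistic read length).

## Decision layer

**Admissibility.** The kernel's `k = ⌊n·e⌋` scales with the read
length, which for a short pattern in a long read admits more
differences than the pattern has information for. The decision layer
therefore re-applies the error ratio over the aligned span: a candidate
is admissible iff `differences ≤ ⌊span·e⌋` (suffix overlaps satisfy
this by construction).

**Single-end.** Among admissible candidates the pscore of the matched
span (`span·P_max − penalty`) is maximized; ties prefer the longer
match, then the smaller start. The default `min_overlap = 3` reflects
that a 1–2 nt exact 3′ overlap matches random sequence with probability
≥ 1/16 — such calls are noise in single-end mode.

**Paired-end.** Candidate indices are the union of admissible
occurrence starts in either mate, enumerated down to `min_overlap = 1`:
the reverse-complement verification supplies the evidence that the
overlap-length guard supplies in single-end mode, and without 1–2 nt
overlaps inserts of `readLen−1`/`readLen−2` would be unreachable. Each
index is scored with the three-term `score(idx)`; each component must
individually satisfy `differences ≤ ⌊span·e⌋` (span = the aligned
length, `min(|x|,|y|)` for the adapter terms). The third term compares
`read1[:idx]` with `revcomp(read2[:idx])` **gap-free** (substitutions
only, each penalized at the smaller of the two base qualities): the
prefixes are reads of the same physical template, so indels between
them would imply instrument indel errors, which the Illumina-like error
model excludes. A gapped comparison would absorb small shifts and
systematically false-trim inserts a few bases longer than the read.
Both mates are truncated to the winning index.

**LMP.** Stage 1 is paired-end trimming; stage 2 searches each mate
separately for the junction and keeps the prefix before the junction
start (mate-orientation fix-ups are downstream assembler concerns).
The junction stage demands a raised minimum 3′ overlap (default 12 nt):
a junction split discards the read tail, so the evidence bar is higher;
a 12 nt exact suffix matches random sequence with probability ~6·10⁻⁸
per read. Reads whose junction begins closer than that to the read end
retain a short junction stub — a documented limitation.

## Simulator

`simulate_dataset` emulates the canonical read-through experiment:
a uniform-random reference (default 100 kb), fragments at uniform
positions with Normal(μ, σ) lengths clipped at 0 (clipping keeps
`P(length < read_length) = Φ((read_length−μ)/σ)` exact, which
`solve_contamination_fraction` inverts), read 1 the forward strand and
read 2 the reverse complement, each padded with its adapter and random
filler when the fragment is shorter than the read. Defaults are the
conditions used throughout the tests: 100 bp reads, σ = 50, μ solved
for a 36% contaminated fraction, TruSeq R1/R2 adapters (33 nt). The
quality model is a flat mean Phred value (optional per-base jitter)
with substitution errors at `10^(−q/10)` — applied to adapter bases
too, the hard case for the matcher; indel errors are available for
stress-testing the indel path. LMP mode embeds the 19 nt junction at a
uniform, fully contained position per read, joining two unrelated
reference windows; the long-range pairing structure itself is not
emulated.

What the simulator does **not** model: empirically trained error
profiles (quality varies along real reads), base-composition bias,
homopolymer artifacts, chimeric fragments, or real genomic repeat
structure (a config option can plant adapter-like motifs in the
reference to study homology-driven false positives). Passing tests
therefore demonstrate the correctness of the matching and scoring
machinery under controlled contamination, not end-to-end accuracy on
any particular instrument's data.

## Evaluation

Each read is classified against the manifest at a configurable boundary
tolerance (default 0, the strictest reading): TP (trimmed at the true
index), FP_ot (over-trimmed), FN_ut (trimmed but short of the adapter),
FN_fr (contaminated but untrimmed), FP_ft (clean but trimmed), TN
(clean, untrimmed). Pairs contribute two per-read rows. Metrics:

    PPV  = TP/(TP+FP_ft+FP_ot+FN_ut)
    Sen  = TP/(TP+FN_fr+FN_ut+FP_ot)
    Spec = TN/(TN+FP_ft)
    mCC  = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Note PPV's denominator counts under-trimmed reads although they were
trimmed — an under-trimmed read still carries adapter, so its call was
not a correct positive; this differs from the textbook definition and
is intentional. Zero-denominator metrics are reported as absent.
`roc_sweep` reruns the trimmer over a stringency grid and reports
(FPR, TPR) per error ratio.

## Numerical and degenerate-input choices

* Threshold rounding is floor throughout (`⌊n·e⌋`, `⌊L·e⌋`), which
  forces exact matching for overlaps shorter than `1/e`.
* Ties everywhere are deterministic: predecessor order diag/up/down;
  candidate ranking by (score, span, −start); equal-score paired-end
  indices resolve to the smaller index.
* An insert of length 0 (primer-dimer) trims to an empty read; empty
  reads are preserved through I/O and removed only by the explicit
  length filter (`filter_min_length`, default minimum 1 in the CLI).
* Phred+33 is the I/O default; offset detection never overrides an
  explicit flag, and an all-ambiguous sample (characters 59–63) warns
  and assumes +33. Multi-line FASTQ is rejected, not joined.
* Gzip output uses a zeroed mtime and empty embedded filename so
  identical runs are byte-identical.

## Problem sizes

The test suite and the acceptance script size their simulations at
2,000 randomized kernel instances, 10,000 pairs for the paired-end
experiments (error-free and mean-Q25), and 5,000 LMP pairs — large
enough that the binomial uncertainty on every reported rate is well
below the margins asserted, while a full run stays around a minute on
one core.

## Known limitations

* 5′ adapter trimming, multi-adapter screening, barcode demultiplexing,
  read merging and quality trimming are out of scope.
* The paired-end rule assumes equal-position contamination in both
  mates (true for read-through by construction) and substitution-only
  disagreement between mate prefixes; datasets with frequent instrument
  indels would need the gapped third term back at a specificity cost.
* Junctions beginning within 12 nt of the read end are left as stubs.
* The worst-case O(k·n) refinement via extra constant-time bit
  operations is deliberately not implemented; the expected-case queue
  is simpler and empirically the extra bit operations do not pay off.
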