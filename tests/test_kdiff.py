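"""Matching kernel: Levenshtein utilities, pattern bit-vectors, oracle DP
and the bit-masked queue search."""

import random

import edlib
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kdtrim import (
    SearchParams,
    SearchStats,
    build_pattern,
    find_matches,
    find_weighted_matches,
    levenshtein,
    oracle_find,
    oracle_matrix,
)

dna_text = st.text(alphabet="ACGT", min_size=0, max_size=30)


def key(cands):
    return sorted((c.start, c.end, c.differences, c.matched_pattern_length) for c in cands)


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("", "ACG", 3),
        ("ACG", "", 3),
        ("ACGT", "ACGT", 0),
        ("GGTC", "GTTC", 1),
        ("", "", 0),
        ("A", "T", 1),
    ],
)
def test_levenshtein_examples(a, b, expected):
    assert levenshtein(a, b) == expected


@given(dna_text, dna_text, dna_text)
def test_levenshtein_metric_properties(a, b, c):
    assert levenshtein(a, b) == levenshtein(b, a)
    assert levenshtein(a, a) == 0
    assert levenshtein(a, "") == len(a)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


@given(dna_text, dna_text)
def test_levenshtein_agrees_with_edlib(a, b):
    if a and b:  # edlib rejects empty queries
        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]


# ---------------------------------------------------------------------------
# Pattern bit-vectors
# ---------------------------------------------------------------------------

def test_build_pattern_mismatch_positions():
    p = build_pattern("ACGT")
    assert p.mismatch_positions("A") == {1, 2, 3}
    assert p.mismatch_positions("C") == {0, 2, 3}
    assert p.mismatch_positions("G") == {0, 1, 3}
    assert p.mismatch_positions("T") == {0, 1, 2}
    # a read N never matches a concrete base
    assert p.mismatch_positions("N") == {0, 1, 2, 3}


def test_build_pattern_all_n_matches_everything():
    p = build_pattern("NNNN")
    for c in "ACGT":
        assert p.mismatch_positions(c) == frozenset()
    assert p.mismatch_positions("N") == frozenset()


def test_build_pattern_iupac_degeneracy():
    p = build_pattern("RY")  # R = A/G, Y = C/T
    assert p.mismatch_positions("A") == {1}
    assert p.mismatch_positions("G") == {1}
    assert p.mismatch_positions("C") == {0}
    assert p.mismatch_positions("T") == {0}


@pytest.mark.parametrize("bad", ["", "ACGX", "12"])
def test_build_pattern_rejects_invalid(bad):
    with pytest.raises(ValueError):
        build_pattern(bad)


# ---------------------------------------------------------------------------
# Oracle examples
# ---------------------------------------------------------------------------

def test_oracle_exact_hit():
    params = SearchParams(error_ratio=0.0, max_differences_override=0)
    cands = oracle_find("TTACGTTT", build_pattern("ACGT"), params)
    assert key(cands) == [(2, 6, 0, 4)]


def test_oracle_identity_read():
    params = SearchParams(error_ratio=0.0, max_differences_override=0)
    cands = oracle_find("ACGT", build_pattern("ACGT"), params)
    assert key(cands) == [(0, 4, 0, 4)]


def test_oracle_one_difference_hit():
    params = SearchParams(error_ratio=0.0, max_differences_override=1)
    cands = oracle_find("TTACTTTT", build_pattern("ACGT"), params)
    assert any(c.differences == 1 and c.matched_pattern_length == 4 for c in cands)


def test_oracle_no_shared_characters():
    params = SearchParams(error_ratio=0.0, max_differences_override=0)
    assert oracle_find("TTTT", build_pattern("CCCC"), params) == []


# ---------------------------------------------------------------------------
# Queue search vs oracle
# ---------------------------------------------------------------------------

def _random_instance(rng):
    m = rng.randint(4, 16)
    n = rng.randint(20, 100)
    pat = "".join(rng.choice("ACGT") for _ in range(m))
    read = "".join(
        rng.choice("ACGTN") if rng.random() < 0.02 else rng.choice("ACGT")
        for _ in range(n)
    )
    if rng.random() < 0.6:  # embed a mutated copy so hits are common
        mutated = list(pat)
        for _ in range(rng.randint(0, 2)):
            mutated[rng.randrange(m)] = rng.choice("ACGT")
        pos = rng.randint(0, n - m)
        read = read[:pos] + "".join(mutated) + read[pos + m:]
    if rng.random() < 0.5:
        params = SearchParams(
            error_ratio=rng.choice([0.05, 0.1, 0.2, 0.3]),
            min_overlap=rng.choice([1, 2, 3]),
            max_differences_override=rng.randint(0, 4),
        )
    else:
        params = SearchParams(
            error_ratio=rng.choice([0.05, 0.1, 0.2, 0.3]),
            min_overlap=rng.choice([1, 2, 3]),
        )
    return read, pat, params


def test_queue_matches_oracle_randomized(rng):
    for _ in range(400):
        read, pat, params = _random_instance(rng)
        p = build_pattern(pat)
        assert key(find_matches(read, p, params)) == key(oracle_find(read, p, params))


def test_queue_trivial_cases():
    params = SearchParams(max_differences_override=0, min_overlap=4)
    assert find_matches("TTTT", build_pattern("CCCC"), params) == []
    hits = find_matches("ACGT", build_pattern("ACGT"), params)
    assert key(hits) == [(0, 4, 0, 4)]


def test_pattern_longer_than_read_hits_with_deletions():
    # aligning AAAA against read AAA needs one deletion
    params = SearchParams(max_differences_override=1, min_overlap=3)
    hits = [c for c in find_matches("AAA", build_pattern("AAAA"), params)
            if c.matched_pattern_length == 4]
    assert (0, 3, 1, 4) in [(c.start, c.end, c.differences, 4) for c in hits]


def test_best_full_hit_distance_agrees_with_edlib(rng):
    """min over end positions of C[m, j] equals edlib's infix distance."""
    for _ in range(200):
        m = rng.randint(4, 16)
        n = rng.randint(20, 80)
        pat = "".join(rng.choice("ACGT") for _ in range(m))
        read = "".join(rng.choice("ACGT") for _ in range(n))
        params = SearchParams(max_differences_override=m - 1, min_overlap=m)
        full = [c for c in find_matches(read, build_pattern(pat), params)
                if c.matched_pattern_length == m]
        best = min((c.differences for c in full), default=None)
        ed = edlib.align(pat, read, mode="HW")["editDistance"]
        if best is not None:
            assert best == ed
        else:
            assert ed > m - 1


# ---------------------------------------------------------------------------
# Structural theorems on the oracle matrix
# ---------------------------------------------------------------------------

def test_diagonal_monotonicity_and_cutoff(rng):
    """Along every diagonal values never decrease, and the last active
    cell moves down by at most one per column."""
    for _ in range(100):
        read, pat, params = _random_instance(rng)
        om = oracle_matrix(read, build_pattern(pat), params)
        C = om.C
        m, n = C.shape[0] - 1, C.shape[1] - 1
        for start in range(-m, n):
            prev = None
            i, j = (1 - min(0, start + 1), max(0, start + 1))
            i = max(0, -start)
            j = max(0, start)
            while i <= m and j <= n:
                if prev is not None:
                    assert C[i, j] >= prev
                prev = C[i, j]
                i += 1
                j += 1
        lac = om.lac_per_column
        for j in range(1, len(lac)):
            assert lac[j] <= lac[j - 1] + 1


def test_boundary_initialization():
    om = oracle_matrix("ACGTACG", build_pattern("ACGT"), SearchParams())
    assert (om.C[0, :] == 0).all()
    assert list(om.C[:, 0]) == [0, 1, 2, 3, 4]


def test_queue_sparsity_on_random_dna(rng):
    """Expected O(k) live cells per column on uniform random sequence."""
    for k in (0, 1, 2, 4):
        total_mean = 0.0
        trials = 30
        for _ in range(trials):
            read = "".join(rng.choice("ACGT") for _ in range(100))
            pat = "".join(rng.choice("ACGT") for _ in range(16))
            stats = SearchStats()
            find_matches(read, build_pattern(pat),
                         SearchParams(max_differences_override=k), stats)
            total_mean += stats.mean_live_cells
        assert total_mean / trials <= 5 * (k + 1)


# ---------------------------------------------------------------------------
# Weighted search
# ---------------------------------------------------------------------------

def test_weighted_candidates_match_unweighted(rng):
    for _ in range(300):
        read, pat, params = _random_instance(rng)
        quals = [rng.randint(0, 41) for _ in range(len(read))]
        p = build_pattern(pat)
        unweighted = key(find_matches(read, p, params))
        weighted = key(find_weighted_matches(read, quals, p, params))
        assert unweighted == weighted


def test_weighted_penalty_bounds(rng):
    from kdtrim.quality import DEFAULT_PENALTY_PARAMS as P

    for _ in range(200):
        read, pat, params = _random_instance(rng)
        quals = [rng.randint(0, 41) for _ in range(len(read))]
        for c in find_weighted_matches(read, quals, build_pattern(pat), params):
            assert c.penalty >= c.differences * P.p_min - 1e-9
            assert c.penalty <= c.differences * P.p_max + 1e-9


def test_weighted_penalty_values():
    from kdtrim.quality import DEFAULT_PENALTY_PARAMS as P

    p = build_pattern("ACGT")
    params = SearchParams(max_differences_override=1, min_overlap=4)
    # perfect match: penalty 0
    perfect = [c for c in find_weighted_matches("TTACGTTT", [40] * 8, p, params)
               if c.differences == 0]
    assert perfect and all(c.penalty == 0.0 for c in perfect)
    # one substitution at q=40 costs exactly P_max
    cands = find_weighted_matches("TTACCTTT", [40] * 8, p, params)
    best = min(c.penalty for c in cands if c.differences == 1)
    assert best == pytest.approx(P.p_max)
    # one deletion (read AAA vs pattern AAAA) costs delta = P_max
    cands = find_weighted_matches("AAA", [40] * 3, build_pattern("AAAA"), params)
    full = [c for c in cands if c.matched_pattern_length == 4]
    assert min(c.penalty for c in full) == pytest.approx(P.p_max)


def test_weighted_rejects_length_mismatch():
    with pytest.raises(ValueError):
        find_weighted_matches("ACGT", [40] * 3, build_pattern("AC"), SearchParams())


# ---------------------------------------------------------------------------
# Extended (suffix overlap) search
# ---------------------------------------------------------------------------

def test_suffix_overlap_thresholds():
    adapter = "AGATCGGAAGAGCACACGT"
    p = build_pattern(adapter)
    params = SearchParams(error_ratio=0.1, min_overlap=3)
    stem = "CT" * 40  # no adapter-prefix suffix
    # exact 5 nt overlap is found at the right start
    read = stem + adapter[:5]
    hits = [c for c in find_matches(read, p, params) if c.end == len(read)]
    assert any(c.start == len(stem) and c.differences == 0 for c in hits)
    # 2 nt overlap is below min_overlap
    read = stem + adapter[:2]
    hits = [c for c in find_matches(read, p, params)
            if c.matched_pattern_length < len(adapter)]
    assert all(c.span != 2 or c.start != len(stem) for c in hits)


def test_overlap_error_budget_boundary():
    """A ceil(1/e)-long overlap admits exactly floor(len*e) differences."""
    adapter = "AGATCGGAAGAGCACACGT"
    p = build_pattern(adapter)
    params = SearchParams(error_ratio=0.1, min_overlap=3)
    stem = "CT" * 40
    one_mm = list(adapter[:10])
    one_mm[4] = "T" if one_mm[4] != "T" else "G"
    read = stem + "".join(one_mm)
    hits = [c for c in find_matches(read, p, params)
            if c.start == len(stem) and c.end == len(read)]
    assert any(c.differences == 1 for c in hits)
    two_mm = list(adapter[:10])
    for pos in (4, 7):
        two_mm[pos] = "T" if two_mm[pos] != "T" else "G"
    read = stem + "".join(two_mm)
    hits = [c for c in find_matches(read, p, params)
            if c.start == len(stem) and c.end == len(read)]
    assert not hits
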