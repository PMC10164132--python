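"""Primer scanning against an exhaustive local-alignment oracle."""

import numpy as np
import pytest

from scdemux import LongRead, PrimerSet, find_primer_hits, resolve_hits, revcomp
from scdemux.primerscan import GAP_SCORE, MATCH_SCORE, MISMATCH_SCORE, PrimerHit

BASES = "ACGT"


def smith_waterman(query: str, target: str):
    """Exhaustive O(nm) local alignment (linear gaps); returns
    (score, target_start, target_end, matches, aligned_len) of the optimum,
    preferring longer alignments then leftmost target start on score ties."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    best = (0, 0, 0, 0, 0)
    back = {}
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (
                MATCH_SCORE if query[i - 1] == target[j - 1] else MISMATCH_SCORE
            )
            up = H[i - 1, j] + GAP_SCORE
            left = H[i, j - 1] + GAP_SCORE
            H[i, j] = max(0.0, diag, up, left)
            if H[i, j] == 0:
                continue
            if H[i, j] == diag:
                back[(i, j)] = (i - 1, j - 1, query[i - 1] == target[j - 1])
            elif H[i, j] == up:
                back[(i, j)] = (i - 1, j, False)
            else:
                back[(i, j)] = (i, j - 1, False)
    candidates = []
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i, j] <= 0:
                continue
            ci, cj = i, j
            matches = 0
            length = 0
            while (ci, cj) in back and H[ci, cj] > 0:
                pi, pj, is_match = back[(ci, cj)]
                matches += is_match
                length += 1
                ci, cj = pi, pj
            candidates.append((H[i, j], length, -cj, j, matches))
    if not candidates:
        return None
    score, length, neg_start, end, matches = max(candidates)
    return score, -neg_start, end, matches, length


def random_dna(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def mutate(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def test_exact_primer_pair_found_at_exact_coordinates(primers):
    rng = np.random.default_rng(0)
    insert = random_dna(rng, 60)
    read = LongRead("r", primers.p5 + insert + revcomp(primers.p3))
    hits = find_primer_hits(read, primers)
    assert len(hits) == 2
    p5, p3 = hits
    assert (p5.primer_id, p5.strand, p5.start, p5.end) == ("P5", "+", 0, 22)
    assert p5.matches == 22 and p5.identity == 1.0
    n = len(read.sequence)
    assert (p3.primer_id, p3.strand, p3.start, p3.end) == ("P3", "-", n - 22, n)


def test_random_sequence_yields_no_hits(primers):
    rng = np.random.default_rng(99)
    # random 200-mers essentially never share a seeded >=16bp 80% match
    for _ in range(5):
        read = LongRead("r", random_dna(rng, 200))
        hits = find_primer_hits(read, primers)
        for h in hits:  # if anything is reported it must satisfy the contract
            assert h.aligned_len >= 16 and h.identity >= 0.8


@pytest.mark.parametrize("n_subs", [1, 2])
def test_substituted_primer_matches_local_alignment_oracle(primers, n_subs):
    """A primer with interior substitutions must be located exactly where an
    exhaustive local aligner puts it."""
    rng = np.random.default_rng(42 + n_subs)
    for trial in range(15):
        offset = int(rng.integers(20, 200))
        positions = rng.choice(np.arange(3, 19), size=n_subs, replace=False)
        mutated = mutate(rng, primers.p5, positions)
        background = random_dna(rng, 280)
        seq = background[:offset] + mutated + background[offset:]
        read = LongRead("r", seq)
        hits = [h for h in find_primer_hits(read, primers)
                if h.primer_id == "P5" and h.strand == "+"]
        assert hits, f"trial {trial}: primer with {n_subs} subs not found"
        hit = max(hits, key=lambda h: h.matches)
        oracle = smith_waterman(primers.p5, seq)
        assert oracle is not None
        _, o_start, o_end, o_matches, o_len = oracle
        assert (hit.start, hit.end) == (o_start, o_end)
        assert hit.matches == o_matches
        assert hit.aligned_len == o_len
        assert hit.identity == pytest.approx(o_matches / o_len)
        if o_len == 22:  # untouched terminals: the whole primer aligns
            assert hit.identity == pytest.approx((22 - n_subs) / 22)


def test_terminal_mismatches_are_clipped(primers):
    """A substitution at the primer's first base lowers the local-alignment
    score below the clipped variant, so the optimum drops that column."""
    rng = np.random.default_rng(7)
    mutated = mutate(rng, primers.p5, [0])
    seq = random_dna(rng, 50) + mutated + random_dna(rng, 50)
    read = LongRead("r", seq)
    hits = [h for h in find_primer_hits(read, primers) if h.primer_id == "P5"]
    assert hits
    hit = max(hits, key=lambda h: h.matches)
    assert (hit.start, hit.end) == (51, 72)  # first base clipped
    assert hit.matches == 21 and hit.aligned_len == 21


def test_strand_symmetry(primers):
    """Scanning the reverse complement mirrors every hit."""
    rng = np.random.default_rng(17)
    for _ in range(8):
        parts = [random_dna(rng, 40), primers.p5,
                 random_dna(rng, 80), revcomp(primers.p3), random_dna(rng, 30)]
        seq = "".join(parts)
        read = LongRead("r", seq)
        fwd = find_primer_hits(read, primers)
        rev = find_primer_hits(read.reverse_complement(), primers)
        n = len(seq)
        mirrored = sorted(
            (h.primer_id, "-" if h.strand == "+" else "+", n - h.end, n - h.start,
             h.matches, h.aligned_len)
            for h in rev
        )
        original = sorted(
            (h.primer_id, h.strand, h.start, h.end, h.matches, h.aligned_len)
            for h in fwd
        )
        assert original == mirrored


def test_determinism(primers, noisy_lib):
    read = noisy_lib.reads[0]
    a = find_primer_hits(read, primers)
    b = find_primer_hits(read, primers)
    assert a == b


# ---------------------------------------------------------------------------
# resolve_hits
# ---------------------------------------------------------------------------

def _hit(start, end, matches, primer="P5", strand="+"):
    return PrimerHit(primer, strand, start, end, matches, end - start)


def greedy_oracle(hits, max_overlap):
    """Independent restatement: accept by descending score, reject conflicts."""
    def overlap(a, b):
        return max(0, min(a.end, b.end) - max(a.start, b.start))
    order = sorted(hits, key=lambda h: (-h.matches, -h.identity, h.start, h.end,
                                        h.primer_id, h.strand))
    kept = []
    for h in order:
        if all(overlap(h, k) <= max_overlap for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end, h.primer_id, h.strand))


def test_dominant_hit_survives_identical_span():
    hits = [_hit(10, 32, 22), _hit(10, 32, 20, primer="P3")]
    kept = resolve_hits(sorted(hits, key=lambda h: h.start))
    assert kept == [_hit(10, 32, 22)]


def test_small_overlap_keeps_both():
    hits = [_hit(0, 22, 22), _hit(19, 41, 22, primer="P3")]  # overlap 3 <= 5
    assert len(resolve_hits(hits)) == 2


def test_resolution_matches_greedy_oracle_on_random_hit_sets(rng):
    for _ in range(200):
        n = int(rng.integers(1, 9))
        hits = []
        for _ in range(n):
            start = int(rng.integers(0, 60))
            length = int(rng.integers(16, 23))
            matches = int(rng.integers(13, length + 1))
            hits.append(PrimerHit(
                str(rng.choice(["P5", "P3"])), str(rng.choice(["+", "-"])),
                start, start + length, matches, length,
            ))
        hits.sort(key=lambda h: h.start)
        assert resolve_hits(hits, max_overlap=5) == greedy_oracle(hits, 5)
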