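"""Segmentation, FLNC classification, orientation and poly(A) trimming."""

import numpy as np
import pytest

from scdemux import (
    ARTIFACT,
    FLNC,
    NFL,
    LongRead,
    PrimerSet,
    classify_segment,
    demultiplex,
    demultiplex_read,
    orient_and_extract,
    revcomp,
    segment_read,
    trim_polya,
)
from scdemux.primerscan import PrimerHit, find_primer_hits, resolve_hits
from scdemux.segment import CdnaSegment, ExtractionRejection, FlncRecord


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_unit(primers, transcript, bc, umi, polya=30):
    return (primers.p5 + transcript + "A" * polya
            + revcomp(umi) + revcomp(bc) + revcomp(primers.p3))


# ---------------------------------------------------------------------------
# trim_polya
# ---------------------------------------------------------------------------

def suffix_oracle(seq, window=10, min_frac_a=0.8):
    """Brute force: largest suffix length whose every (length-capped) window
    meets the A fraction, then retract the boundary to the first A."""
    n = len(seq)
    best = 0
    for L in range(1, n + 1):
        w = min(window, L)
        ok = all(
            seq[s:s + w].count("A") / w >= min_frac_a
            for s in range(n - L, n - w + 1)
        )
        if ok:
            best = L
    p = n - best
    while p < n and seq[p] != "A":
        p += 1
    return n - p


def test_clean_tail_is_trimmed_exactly():
    trimmed, polya_len, has = trim_polya("ACGT" + "A" * 30)
    assert (trimmed, polya_len, has) == ("ACGT", 30, True)


def test_interrupted_tail_is_fully_trimmed():
    seq = "CCGTGC" + "A" * 14 + "G" + "A" * 15
    trimmed, polya_len, has = trim_polya(seq)
    assert polya_len == suffix_oracle(seq) == 30
    assert trimmed == "CCGTGC"
    assert has


def test_no_tail_reports_zero():
    trimmed, polya_len, has = trim_polya("CGTACGTACGTCG")
    assert (polya_len, has) == (0, False)
    assert trimmed == "CGTACGTACGTCG"


def test_short_tail_reported_but_not_accepted():
    trimmed, polya_len, has = trim_polya("CGCGCGCGTT" + "A" * 6)
    assert polya_len == 6
    assert not has
    assert trimmed == "CGCGCGCGTT"


def test_trimming_matches_suffix_oracle_on_random_tails(rng):
    for _ in range(300):
        body = random_dna(rng, int(rng.integers(0, 40)))
        tail = "".join(
            rng.choice(list("ACGT"), p=[0.88, 0.04, 0.04, 0.04],
                       size=int(rng.integers(0, 45)))
        )
        seq = body + tail
        _, polya_len, _ = trim_polya(seq)
        assert polya_len == suffix_oracle(seq), seq


# ---------------------------------------------------------------------------
# segment_read
# ---------------------------------------------------------------------------

def test_two_unit_concatemer_segments_into_proper_pairs(primers, rng):
    bc, umi = random_dna(rng, 16), random_dna(rng, 12)
    u1 = make_unit(primers, random_dna(rng, 200), bc, umi)
    u2 = make_unit(primers, random_dna(rng, 150), bc, umi)
    read = LongRead("r", u1 + primers.junction + u2)
    hits = resolve_hits(find_primer_hits(read, primers))
    segs = segment_read(read, hits)
    assert len(segs) == 2
    assert all(s.terminals in {("5p+", "3p-"), ("3p+", "5p-")} for s in segs)
    # junction bases belong to neither segment
    assert segs[0].end + 22 + len(primers.junction) + 22 <= segs[1].start + 1


def test_single_p5_hit_yields_one_open_segment():
    read = LongRead("r", "A" * 122)
    hits = [PrimerHit("P5", "+", 0, 22, 22, 22)]
    segs = segment_read(read, hits)
    assert len(segs) == 1
    assert segs[0].terminals == ("5p+", "NONE")
    assert (segs[0].start, segs[0].end) == (22, 122)


def test_no_hits_gives_single_unterminated_segment():
    read = LongRead("r", "C" * 80)
    segs = segment_read(read, [])
    assert len(segs) == 1
    assert segs[0].terminals == ("NONE", "NONE")


def test_short_intervals_are_suppressed():
    read = LongRead("r", "C" * 100)
    hits = [PrimerHit("P5", "+", 0, 22, 22, 22), PrimerHit("P3", "-", 30, 52, 22, 22)]
    segs = segment_read(read, hits, min_seqlen=50)
    assert len(segs) == 0  # 8-base interior and 48-base tail both below 50


def test_segment_count_matches_truth_on_error_free_simulation(clean_lib, primers):
    truth_counts = clean_lib.truth_units.groupby("read_id").size().to_dict()
    for read in clean_lib.reads:
        segs = demultiplex_read(read, primers).segments
        assert len(segs) == truth_counts[read.read_id]


# ---------------------------------------------------------------------------
# classify_segment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "terminals, has_polya, has_bcumi, expected",
    [
        (("5p+", "3p-"), True, True, FLNC),
        (("3p+", "5p-"), True, True, FLNC),
        (("5p+", "5p-"), False, False, ARTIFACT),
        (("5p+", "3p-"), False, False, NFL),     # 3' primer present, no tail
        (("5p+", "3p-"), True, False, NFL),      # truncated BC/UMI block
        (("5p+", "NONE"), True, True, NFL),      # read end: cannot certify
        (("NONE", "NONE"), False, False, ARTIFACT),
        (("NONE", "NONE"), True, False, NFL),    # poly(A) signal rescues
    ],
)
def test_classification_rules(terminals, has_polya, has_bcumi, expected):
    seg = CdnaSegment("r", 0, 0, 300, terminals[0], terminals[1])
    assert classify_segment(seg, has_polya, has_bcumi) == expected


def test_short_transcript_downgrades_flnc_to_nfl():
    seg = CdnaSegment("r", 0, 0, 300, "5p+", "3p-")
    assert classify_segment(seg, True, True, transcript_len=49) == NFL
    assert classify_segment(seg, True, True, transcript_len=50) == FLNC


# ---------------------------------------------------------------------------
# orient_and_extract
# ---------------------------------------------------------------------------

def _segment_for(read, primers):
    hits = resolve_hits(find_primer_hits(read, primers))
    segs = segment_read(read, hits)
    assert len(segs) == 1
    return segs[0]


def test_extraction_recovers_barcode_umi_transcript(primers, rng):
    bc, umi = random_dna(rng, 16), random_dna(rng, 12)
    transcript = random_dna(rng, 197) + "CGT"
    read = LongRead("r", make_unit(primers, transcript, bc, umi, polya=25))
    rec = orient_and_extract(read, _segment_for(read, primers), primers)
    assert isinstance(rec, FlncRecord)
    assert rec.raw_barcode == bc
    assert rec.raw_umi == umi
    assert rec.transcript == transcript
    assert rec.polya_len == 25


def test_extraction_is_orientation_invariant(primers, rng):
    bc, umi = random_dna(rng, 16), random_dna(rng, 12)
    transcript = random_dna(rng, 197) + "CGT"
    unit = make_unit(primers, transcript, bc, umi, polya=25)
    fwd = LongRead("r", unit)
    rev = LongRead("r", revcomp(unit))
    rec_f = orient_and_extract(fwd, _segment_for(fwd, primers), primers)
    rec_r = orient_and_extract(rev, _segment_for(rev, primers), primers)
    assert (rec_f.raw_barcode, rec_f.raw_umi, rec_f.transcript, rec_f.polya_len) == (
        rec_r.raw_barcode, rec_r.raw_umi, rec_r.transcript, rec_r.polya_len
    )


def test_truncated_bc_umi_block_is_rejected(primers, rng):
    # only 20 bases between the two primers: too short for the 28bp block
    seq = primers.p5 + random_dna(rng, 20) + revcomp(primers.p3)
    read = LongRead("r", seq)
    seg = CdnaSegment("r", 0, 22, 42, "5p+", "3p-")
    res = orient_and_extract(read, seg, primers)
    assert isinstance(res, ExtractionRejection)
    assert res.reason == "BC_UMI_TRUNCATED"


def test_missing_polya_is_rejected(primers, rng):
    bc, umi = random_dna(rng, 16), random_dna(rng, 12)
    seq = (primers.p5 + random_dna(rng, 197) + "CGT"
           + revcomp(umi) + revcomp(bc) + revcomp(primers.p3))
    read = LongRead("r", seq)
    res = orient_and_extract(read, _segment_for(read, primers), primers)
    assert isinstance(res, ExtractionRejection)
    assert res.reason == "NO_POLYA"


def test_extraction_without_3p_terminal_is_a_contract_violation(primers):
    seg = CdnaSegment("r", 0, 22, 100, "5p+", "NONE")
    with pytest.raises(ValueError, match="3'-primer"):
        orient_and_extract(LongRead("r", "C" * 100), seg, primers)


# ---------------------------------------------------------------------------
# pipeline-level invariants
# ---------------------------------------------------------------------------

def test_category_partition_is_exhaustive(noisy_lib, primers):
    result = demultiplex(noisy_lib.reads[:60], primers)
    counts = result.category_counts()
    assert sum(counts.values()) == len(result.segments)
    assert all(s.category in (FLNC, NFL, ARTIFACT) for s in result.segments)


def test_error_free_units_are_fully_recovered(clean_lib, primers):
    """At error rate zero every simulated unit must round-trip exactly."""
    result = demultiplex(clean_lib.reads, primers)
    truth = clean_lib.truth_units
    assert len(result.segments) == len(truth)
    assert result.category_counts()[FLNC] == (truth.unit_type == "FLNC").sum()
    assert result.category_counts()[ARTIFACT] == (truth.unit_type == "TSO_ARTIFACT").sum()
    truth_by_read = {}
    for row in truth.itertuples():
        truth_by_read[(row.read_id, row.start)] = row
    for rec in result.records:
        row = truth_by_read[(rec.read_id, rec.seg_start - 22)]  # 5'/3' primer is 22bp
        assert rec.raw_barcode == row.cell_bc
        assert rec.raw_umi == row.umi
        assert len(rec.transcript) == row.transcript_len
        assert rec.polya_len == row.polya_len


def test_demultiplexing_is_strand_invariant(clean_lib, primers):
    """Reverse-complementing every read leaves the FLNC multiset unchanged."""
    reads = clean_lib.reads[:40]
    fwd = demultiplex(reads, primers)
    rev = demultiplex([r.reverse_complement() for r in reads], primers)
    key = lambda r: (r.read_id, r.transcript, r.raw_barcode, r.raw_umi, r.polya_len)
    assert sorted(map(key, fwd.records)) == sorted(map(key, rev.records))
    assert fwd.category_counts() == rev.category_counts()
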