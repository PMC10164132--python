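"""Locating 5'/3' primer occurrences on long reads.

A seed-and-extend scanner: exact seed matches (seed length 5, the word size
used for primer search on consensus reads) are clustered by diagonal, each
cluster is aligned with edlib (infix mode), and the edit path is re-clipped
to the maximum-scoring local segment under a simple local-alignment scoring
(match +1, mismatch -2, gap -3).  Hits are reported in the read's own
coordinate frame; reverse-strand hits come from scanning with the
reverse-complemented primer.

To make the scan exactly symmetric under reverse complement, the read and
its reverse complement are both scanned and the mirrored hit sets are
merged; duplicated spans keep the better-scoring record.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import edlib
import numpy as np

from .core import LongRead, PrimerSet, revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_SCORE = -3

_SEED_BAND = 8  # diagonal tolerance / window margin, generous vs indel rates

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class PrimerHit:
    """One located primer occurrence, 0-based half-open read coordinates."""

    primer_id: str  # "P5" or "P3"
    strand: str     # "+" or "-"
    start: int
    end: int
    matches: int
    aligned_len: int
    score: int = 0  # local alignment score of the clipped segment

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_len

    def overlap(self, other: "PrimerHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _kmer_ids(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(ids, valid) for every k-mer start; invalid where a non-ACGT base occurs."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        ids = ids * 4 + codes[j:j + n]
        valid &= codes[j:j + n] < 4
    return ids, valid


@lru_cache(maxsize=65536)
def _clip_local(cigar: str) -> Optional[tuple[int, int, int, int, int]]:
    """Clip an edlib edit path to its best local segment.

    Returns (target_offset_start, target_offset_end, matches, aligned_len,
    score) relative to the aligned target span, or None for an all-negative
    path.  Ties prefer higher score, then longer segment, then leftmost start.
    """
    ops: list[str] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.extend(ch * int(num))
            num = ""
    m = len(ops)
    if all(o == "=" for o in ops):  # common error-free case
        return 0, m, m, m, m * MATCH_SCORE
    scores = [MATCH_SCORE if o == "=" else MISMATCH_SCORE if o == "X" else GAP_SCORE
              for o in ops]
    prefix = [0] * (m + 1)
    for k, s in enumerate(scores):
        prefix[k + 1] = prefix[k] + s
    best: Optional[tuple[int, int, int]] = None  # (score, length, -start)
    for i in range(m):
        for j in range(i + 1, m + 1):
            cand = (prefix[j] - prefix[i], j - i, -i)
            if best is None or cand > best:
                best = cand
    if best is None or best[0] <= 0:
        return None
    score, length, neg_i = best
    i = -neg_i
    j = i + length
    # target advances on match, mismatch and deletion-from-query ("D" in
    # edlib: the target has a base the query lacks)
    t0 = sum(1 for o in ops[:i] if o in "=XD")
    t1 = t0 + sum(1 for o in ops[i:j] if o in "=XD")
    matches = sum(1 for o in ops[i:j] if o == "=")
    return t0, t1, matches, length, score


def _seed_lut(
    queries: tuple[tuple[str, str, str], ...], seed_len: int
) -> tuple[dict[int, list[tuple[int, int]]], np.ndarray]:
    """Seed lookup table: kmer id -> [(query index, query offset)]."""
    lut: dict[int, list[tuple[int, int]]] = {}
    for qi, (_, _, qseq) in enumerate(queries):
        qids, qvalid = _kmer_ids(qseq, seed_len)
        for qpos, (kid, ok) in enumerate(zip(qids, qvalid)):
            if ok:
                lut.setdefault(int(kid), []).append((qi, qpos))
    keys = np.fromiter(lut.keys(), dtype=np.int64, count=len(lut))
    return lut, np.sort(keys)


_LUT_CACHE: dict[tuple, tuple[dict[int, list[tuple[int, int]]], np.ndarray]] = {}


def _best_ungapped(query: str, window: str) -> Optional[tuple[int, int, int, int, int]]:
    """Best ungapped local alignment of query against window.

    Returns (start, end, matches, aligned_len, score) in window coordinates,
    or None when nothing scores positively.  Edit-distance-optimal paths
    reported by edlib occasionally trade two mismatches for an indel pair,
    which scores worse locally; this exhaustive per-diagonal scan recovers
    the proper ungapped optimum in those cases."""
    nq, nw = len(query), len(window)
    best: Optional[tuple[int, int, int, int]] = None  # (score, length, -start, matches)
    for off in range(-(nq - 1), nw):
        lo = max(0, -off)
        hi = min(nq, nw - off)
        if hi - lo <= 0:
            continue
        run_score = 0
        run_start = lo
        run_matches = 0
        for j in range(lo, hi):
            sc = MATCH_SCORE if query[j] == window[off + j] else MISMATCH_SCORE
            if run_score <= 0:
                run_score, run_start, run_matches = sc, j, int(sc > 0)
            else:
                run_score += sc
                run_matches += int(sc > 0)
            if run_score > 0:
                cand = (run_score, j + 1 - run_start, -(off + run_start), run_matches)
                if best is None or cand > best:
                    best = cand
    if best is None:
        return None
    score, length, neg_start, matches = best
    start = -neg_start
    return start, start + length, matches, length, score


def _scan_one_frame(
    seq: str,
    queries: tuple[tuple[str, str, str], ...],
    seed_len: int,
    min_primerlen: int,
    min_identity: float,
) -> list[PrimerHit]:
    """Scan one orientation of a read with prepared (primer_id, strand, qseq)."""
    n = len(seq)
    ids, valid = _kmer_ids(seq, seed_len)
    if len(ids) == 0:
        return []
    cache_key = (queries, seed_len)
    if cache_key not in _LUT_CACHE:
        _LUT_CACHE[cache_key] = _seed_lut(queries, seed_len)
    lut, keys = _LUT_CACHE[cache_key]
    hit_pos = np.nonzero(valid & np.isin(ids, keys))[0]

    seeds: dict[int, list[tuple[int, int]]] = {qi: [] for qi in range(len(queries))}
    for p in hit_pos:
        for qi, qpos in lut[int(ids[p])]:
            seeds[qi].append((int(p) - qpos, int(p)))  # (diagonal, read pos)

    hits: dict[tuple[str, str, int, int], PrimerHit] = {}
    for qi, (primer_id, strand, qseq) in enumerate(queries):
        qlen = len(qseq)
        slist = sorted(seeds[qi])
        clusters: list[list[tuple[int, int]]] = []
        for diag, pos in slist:
            if clusters and diag - clusters[-1][-1][0] <= _SEED_BAND:
                clusters[-1].append((diag, pos))
            else:
                clusters.append([(diag, pos)])
        for cl in clusters:
            if len(cl) < 2:
                continue  # single random seeds are noise; real primers seed densely
            dmin = min(d for d, _ in cl)
            dmax = max(d for d, _ in cl)
            ws = max(0, dmin - _SEED_BAND)
            we = min(n, dmax + qlen + _SEED_BAND)
            window = seq[ws:we]
            res = edlib.align(qseq, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc_start = res["locations"][0][0]
            cigar = res["cigar"]
            clip = _clip_local(cigar)
            if clip is None:
                continue
            t0, t1, matches, aligned_len, score = clip
            t0 += loc_start
            t1 += loc_start
            if "I" in cigar or "D" in cigar:
                ug = _best_ungapped(qseq, window)
                if ug is not None and ug[4] >= score:
                    t0, t1, matches, aligned_len, score = ug
            if aligned_len < min_primerlen or matches / aligned_len < min_identity:
                continue
            start = ws + t0
            end = ws + t1
            hit = PrimerHit(primer_id, strand, start, end, matches, aligned_len, score)
            key = (primer_id, strand, start, end)
            prev = hits.get(key)
            if prev is None or (hit.score, hit.matches) > (prev.score, prev.matches):
                hits[key] = hit
    return list(hits.values())


def find_primer_hits(
    read: LongRead,
    primers: PrimerSet,
    min_primerlen: int = 16,
    min_identity: float = 0.8,
    seed_len: int = 5,
) -> list[PrimerHit]:
    """All 5'/3'-primer occurrences on either strand of ``read``.

    Every reported hit has ``aligned_len >= min_primerlen`` and
    ``identity >= min_identity``; hits are sorted by ascending start.
    Reverse-strand hits are in the read's coordinate frame.
    """
    seq = read.sequence
    queries = (
        ("P5", "+", primers.p5),
        ("P5", "-", revcomp(primers.p5)),
        ("P3", "+", primers.p3),
        ("P3", "-", revcomp(primers.p3)),
    )
    fwd = _scan_one_frame(seq, queries, seed_len, min_primerlen, min_identity)
    rev = _scan_one_frame(revcomp(seq), queries, seed_len, min_primerlen, min_identity)
    n = len(seq)
    merged: dict[tuple[str, str, int, int], PrimerHit] = {}
    mirrored = [
        PrimerHit(
            h.primer_id,
            "-" if h.strand == "+" else "+",
            n - h.end,
            n - h.start,
            h.matches,
            h.aligned_len,
            h.score,
        )
        for h in rev
    ]
    for h in fwd + mirrored:
        key = (h.primer_id, h.strand, h.start, h.end)
        prev = merged.get(key)
        if prev is None or (h.score, h.matches) > (prev.score, prev.matches):
            merged[key] = h
    return sorted(merged.values(), key=lambda h: (h.start, h.end, h.primer_id, h.strand))


def resolve_hits(hits: list[PrimerHit], max_overlap: int = 5) -> list[PrimerHit]:
    """Greedy conflict resolution among overlapping hits.

    Hits overlapping by more than ``max_overlap`` bases conflict; the
    higher-scoring one survives (more matches, then higher identity, then
    leftmost start).  Output is sorted by start and mutually non-conflicting.
    """
    order = sorted(
        hits,
        key=lambda h: (-h.matches, -h.identity, h.start, h.end, h.primer_id, h.strand),
    )
    accepted: list[PrimerHit] = []
    for h in order:
        if all(h.overlap(a) <= max_overlap for a in accepted):
            accepted.append(h)
    return sorted(accepted, key=lambda h: (h.start, h.end, h.primer_id, h.strand))
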