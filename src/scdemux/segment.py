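"""Splitting concatenated reads into cDNA segments and extracting FLNC records.

A concatemer carries several cDNA units joined at ligation junctions; each
unit is flanked by the 5' primer on one side and the 3' primer on the other,
in either orientation.  Resolved primer hits delimit the segments.  A
segment whose terminals are a proper opposite-strand 5'/3' pair
(5p+ ... 3p-  or  3p+ ... 5p-) and which contains the 28 bp barcode+UMI
block and a poly(A) tail, with a post-trim transcript of at least
``min_seqlen`` bases, is a full-length non-chimeric (FLNC) cDNA.  Segments
with neither a 3'-primer terminal nor a poly(A) signal are artifacts
(template-switching by-products); everything else is non-full-length (NFL).

Terminal labels: "5p+", "5p-", "3p+", "3p-" give primer identity and strand
in the read's coordinate frame; "NONE" marks a read end without a primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import LongRead, PrimerSet, revcomp
from .primerscan import PrimerHit

FLNC = "FLNC"
NFL = "NFL"
ARTIFACT = "ARTIFACT"

_FLNC_TERMINAL_PAIRS = {("5p+", "3p-"), ("3p+", "5p-")}


@dataclass
class CdnaSegment:
    read_id: str
    index_in_read: int
    start: int
    end: int
    left_terminal: str
    right_terminal: str
    category: Optional[str] = None
    polya_only: bool = False  # poly(A) signal present without any 3'-primer terminal

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def terminals(self) -> tuple[str, str]:
        return (self.left_terminal, self.right_terminal)


@dataclass
class FlncRecord:
    """One oriented full-length cDNA with its barcode/UMI block removed."""

    read_id: str
    segment_index: int
    transcript: str                      # sense orientation, poly(A) trimmed
    raw_barcode: str                     # 16-mer as read
    raw_umi: str                         # 12-mer as read
    bc_qualities: np.ndarray
    umi_qualities: np.ndarray
    transcript_qualities: np.ndarray
    polya_len: int
    read_qv: Optional[float] = None
    seg_start: int = 0
    seg_end: int = 0


@dataclass(frozen=True)
class ExtractionRejection:
    reason: str   # BC_UMI_TRUNCATED | NO_POLYA | TOO_SHORT | BC_OUTSIDE
    polya_len: int = 0


def _terminal_label(hit: PrimerHit) -> str:
    return ("5p" if hit.primer_id == "P5" else "3p") + hit.strand


def segment_read(
    read: LongRead, hits: list[PrimerHit], min_seqlen: int = 50
) -> list[CdnaSegment]:
    """Segments of a read delimited by resolved, ordered primer hits.

    Every maximal inter-primer interval with interior length >= min_seqlen
    becomes a segment; shorter intervals (residual junction bases between
    back-to-back primers) are assigned to neither segment.  Read ends
    without a primer are labelled NONE.
    """
    n = len(read.sequence)
    bounds: list[tuple[int, int, str, str]] = []
    if not hits:
        bounds.append((0, n, "NONE", "NONE"))
    else:
        bounds.append((0, hits[0].start, "NONE", _terminal_label(hits[0])))
        for left, right in zip(hits, hits[1:]):
            bounds.append((left.end, right.start, _terminal_label(left), _terminal_label(right)))
        bounds.append((hits[-1].end, n, _terminal_label(hits[-1]), "NONE"))
    segments = []
    for start, end, lterm, rterm in bounds:
        if end - start >= min_seqlen:
            segments.append(
                CdnaSegment(read.read_id, len(segments), start, end, lterm, rterm)
            )
    return segments


def classify_segment(
    seg: CdnaSegment,
    has_polya: bool,
    has_bcumi: bool,
    transcript_len: Optional[int] = None,
    min_seqlen: int = 50,
) -> str:
    """FLNC / NFL / ARTIFACT classification of one segment.

    FLNC requires a proper opposite-strand primer pair at both terminals, a
    poly(A) tail, the 28 bp barcode+UMI block, and (when known) a trimmed
    transcript of at least ``min_seqlen`` bases.  A segment with neither a
    3'-primer terminal nor a poly(A) signal is an ARTIFACT; everything else
    is NFL.  A segment flanked by a read end (NONE) is never FLNC — its
    full-length status cannot be certified.
    """
    proper_pair = seg.terminals in _FLNC_TERMINAL_PAIRS
    long_enough = transcript_len is None or transcript_len >= min_seqlen
    if proper_pair and has_polya and has_bcumi and long_enough:
        return FLNC
    has_3p = "3p" in seg.left_terminal or "3p" in seg.right_terminal
    if not has_3p and not has_polya:
        return ARTIFACT
    return NFL


def trim_polya(
    seq: str,
    window: int = 10,
    min_frac_a: float = 0.8,
    min_polya_len: int = 10,
    max_len: Optional[int] = None,
) -> tuple[str, int, bool]:
    """Sliding-window poly(A) trimming at the 3' end of a sense transcript.

    The trimmed tail is the longest suffix (capped at ``max_len``) in which
    every length-``window`` window has an A fraction >= ``min_frac_a``
    (suffixes shorter than the window are judged as a single window of their
    own length), retracted so the tail starts on an A.  Returns
    ``(trimmed_seq, polya_len, has_polya)`` with ``has_polya`` true iff
    ``polya_len >= min_polya_len``; shorter tails are still reported.
    """
    n = len(seq)
    cap = n if max_len is None else min(n, max_len)
    is_a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("A")
    csum = np.concatenate([[0], np.cumsum(is_a)])

    def window_ok(s: int, w: int) -> bool:
        return (csum[s + w] - csum[s]) / w >= min_frac_a

    best = 0
    # suffixes shorter than the window, each judged on its own
    for length in range(1, min(window - 1, cap) + 1):
        if window_ok(n - length, length):
            best = length
    # chained full windows: monotone, extend while each new window passes
    if cap >= window and window_ok(n - window, window):
        length = window
        while length < cap and window_ok(n - length - 1, window):
            length += 1
        best = max(best, length)
    # retract to the first A of the tail
    p = n - best
    while p < n and seq[p] != "A":
        p += 1
    polya_len = n - p
    return seq[:p], polya_len, polya_len >= min_polya_len


def orient_and_extract(
    read: LongRead,
    seg: CdnaSegment,
    primers: PrimerSet,
    min_seqlen: int = 50,
    polya_window: int = 10,
    min_frac_a: float = 0.8,
    min_polya_len: int = 10,
    polya_search_limit: int = 50,
) -> Union[FlncRecord, ExtractionRejection]:
    """Orient a segment to its 3' primer and extract barcode, UMI and transcript.

    The segment is re-expressed on the strand where its 3' primer reads
    forward (the primer then directly precedes the segment); the first 16
    bases are the raw cell barcode, the following 12 the raw UMI, and the
    rest, reverse-complemented back to transcript sense, is poly(A)-trimmed.
    Rejections: BC_UMI_TRUNCATED (fewer than 28 bases), NO_POLYA, TOO_SHORT,
    BC_OUTSIDE (the only 3'-primer terminal faces away from the segment).
    """
    has_3p = "3p" in seg.left_terminal or "3p" in seg.right_terminal
    if not has_3p:
        raise ValueError(
            f"orient_and_extract on segment {seg.read_id}[{seg.index_in_read}] "
            "without a 3'-primer terminal"
        )
    quals = read.effective_qualities()
    seq = read.sequence[seg.start:seg.end]
    q = quals[seg.start:seg.end]
    if seg.left_terminal == "3p+":
        frame_seq, frame_q = seq, q
    elif seg.right_terminal == "3p-":
        frame_seq, frame_q = revcomp(seq), q[::-1]
    else:
        return ExtractionRejection("BC_OUTSIDE")

    bc_block = primers.bc_len + primers.umi_len
    if len(frame_seq) < bc_block:
        return ExtractionRejection("BC_UMI_TRUNCATED")
    raw_bc = frame_seq[: primers.bc_len]
    raw_umi = frame_seq[primers.bc_len:bc_block]
    bc_q = frame_q[: primers.bc_len].copy()
    umi_q = frame_q[primers.bc_len:bc_block].copy()

    rest = frame_seq[bc_block:]
    rest_q = frame_q[bc_block:]
    sense = revcomp(rest)
    sense_q = rest_q[::-1]
    transcript, polya_len, has_polya = trim_polya(
        sense,
        window=polya_window,
        min_frac_a=min_frac_a,
        min_polya_len=min_polya_len,
        max_len=polya_search_limit,
    )
    if not has_polya:
        return ExtractionRejection("NO_POLYA", polya_len=polya_len)
    if len(transcript) < min_seqlen:
        return ExtractionRejection("TOO_SHORT", polya_len=polya_len)
    return FlncRecord(
        read_id=read.read_id,
        segment_index=seg.index_in_read,
        transcript=transcript,
        raw_barcode=raw_bc,
        raw_umi=raw_umi,
        bc_qualities=bc_q,
        umi_qualities=umi_q,
        transcript_qualities=sense_q[: len(transcript)].copy(),
        polya_len=polya_len,
        read_qv=read.effective_read_qv(),
        seg_start=seg.start,
        seg_end=seg.end,
    )


def segment_has_polya_signal(
    read: LongRead,
    seg: CdnaSegment,
    polya_window: int = 10,
    min_frac_a: float = 0.8,
    min_polya_len: int = 10,
    polya_search_limit: int = 50,
) -> bool:
    """Poly(A)/poly(T) signal at either segment end, orientation unknown.

    Used to separate artifacts from NFL segments that lack a usable
    3'-primer terminal.
    """
    seq = read.sequence[seg.start:seg.end]
    for s in (seq, revcomp(seq)):
        _, _, ok = trim_polya(
            s,
            window=polya_window,
            min_frac_a=min_frac_a,
            min_polya_len=min_polya_len,
            max_len=polya_search_limit,
        )
        if ok:
            return True
    return False
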