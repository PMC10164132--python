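"""End-to-end demultiplexing: reads -> segments -> FLNC records -> tables.

Ties together primer scanning, segmentation, classification and
barcode/UMI extraction, and provides the TSV/FASTQ writers for the FLNC
output plus the run summary used for per-run accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import LongRead, PipelineConfig, PrimerSet, quals_to_string, write_fastq
from .primerscan import find_primer_hits, resolve_hits
from .segment import (
    ARTIFACT,
    FLNC,
    NFL,
    CdnaSegment,
    ExtractionRejection,
    FlncRecord,
    classify_segment,
    orient_and_extract,
    segment_has_polya_signal,
    segment_read,
)

FLNC_TSV_COLUMNS = [
    "read_id", "segment_index", "seg_start", "seg_end", "category",
    "left_terminal", "right_terminal", "raw_barcode", "raw_umi",
    "bc_qual", "umi_qual", "polya_len", "read_qv",
]


@dataclass
class DemuxResult:
    segments: list[CdnaSegment] = field(default_factory=list)
    records: list[FlncRecord] = field(default_factory=list)
    rejections: list[tuple[CdnaSegment, ExtractionRejection]] = field(default_factory=list)
    n_reads: int = 0

    def category_counts(self) -> dict[str, int]:
        counts = {FLNC: 0, NFL: 0, ARTIFACT: 0}
        for seg in self.segments:
            counts[seg.category] += 1
        return counts

    def summary(self) -> dict:
        counts = self.category_counts()
        total = len(self.segments)
        seg_lengths = [s.length for s in self.segments]
        tr_lengths = [len(r.transcript) for r in self.records]
        return {
            "n_reads": self.n_reads,
            "linked_cdna_count": total,
            "counts": counts,
            "percentages": {
                k: (100.0 * v / total if total else 0.0) for k, v in counts.items()
            },
            "mean_segment_length": float(np.mean(seg_lengths)) if seg_lengths else 0.0,
            "mean_transcript_length": float(np.mean(tr_lengths)) if tr_lengths else 0.0,
            "mean_polya_length": (
                float(np.mean([r.polya_len for r in self.records])) if self.records else 0.0
            ),
        }


def demultiplex_read(
    read: LongRead,
    primers: PrimerSet,
    config: Optional[PipelineConfig] = None,
) -> DemuxResult:
    """Segment one read and extract its FLNC records."""
    cfg = config or PipelineConfig()
    hits = find_primer_hits(
        read, primers,
        min_primerlen=cfg.min_primerlen,
        min_identity=cfg.min_identity,
        seed_len=cfg.seed_len,
    )
    resolved = resolve_hits(hits, max_overlap=cfg.max_overlap)
    segments = segment_read(read, resolved, min_seqlen=cfg.min_seqlen)
    result = DemuxResult(segments=segments, n_reads=1)
    polya_kw = dict(
        polya_window=cfg.polya_window,
        min_frac_a=cfg.min_frac_a,
        min_polya_len=cfg.min_polya_len,
        polya_search_limit=cfg.polya_search_limit,
    )
    for seg in segments:
        extractable = seg.left_terminal == "3p+" or seg.right_terminal == "3p-"
        has_3p = "3p" in seg.left_terminal or "3p" in seg.right_terminal
        if extractable:
            res = orient_and_extract(read, seg, primers, min_seqlen=cfg.min_seqlen, **polya_kw)
            if isinstance(res, FlncRecord):
                seg.category = classify_segment(
                    seg, has_polya=True, has_bcumi=True,
                    transcript_len=len(res.transcript), min_seqlen=cfg.min_seqlen,
                )
                if seg.category == FLNC:
                    result.records.append(res)
                else:
                    result.rejections.append((seg, ExtractionRejection("IMPROPER_TERMINALS")))
            else:
                if res.reason == "NO_POLYA":
                    has_polya = False
                elif res.reason == "BC_UMI_TRUNCATED":
                    # too short to hold the 28 bp block; poly(A) state unknown,
                    # but the 3' primer already rules out ARTIFACT
                    has_polya = segment_has_polya_signal(read, seg, **polya_kw)
                else:
                    has_polya = True
                seg.category = classify_segment(
                    seg, has_polya=has_polya, has_bcumi=False, min_seqlen=cfg.min_seqlen
                )
                result.rejections.append((seg, res))
        else:
            has_polya = segment_has_polya_signal(read, seg, **polya_kw)
            seg.polya_only = has_polya and not has_3p
            seg.category = classify_segment(
                seg, has_polya=has_polya, has_bcumi=False, min_seqlen=cfg.min_seqlen
            )
            if has_3p:
                result.rejections.append((seg, ExtractionRejection("BC_OUTSIDE")))
    return result


def demultiplex(
    reads: Iterable[LongRead],
    primers: Optional[PrimerSet] = None,
    config: Optional[PipelineConfig] = None,
) -> DemuxResult:
    """Demultiplex a stream of reads into a combined result."""
    primers = primers or PrimerSet()
    cfg = config or PipelineConfig()
    combined = DemuxResult()
    for read in reads:
        one = demultiplex_read(read, primers, cfg)
        combined.segments.extend(one.segments)
        combined.records.extend(one.records)
        combined.rejections.extend(one.rejections)
        combined.n_reads += 1
    return combined


# ---------------------------------------------------------------------------
# FLNC output
# ---------------------------------------------------------------------------

def records_to_frame(result: DemuxResult) -> pd.DataFrame:
    """FLNC records as a TSV-ready DataFrame (one row per record)."""
    seg_by_key = {(s.read_id, s.index_in_read): s for s in result.segments}
    rows = []
    for r in result.records:
        seg = seg_by_key[(r.read_id, r.segment_index)]
        rows.append((
            r.read_id, r.segment_index, r.seg_start, r.seg_end, seg.category,
            seg.left_terminal, seg.right_terminal, r.raw_barcode, r.raw_umi,
            quals_to_string(r.bc_qualities), quals_to_string(r.umi_qualities),
            r.polya_len, r.read_qv,
        ))
    return pd.DataFrame(rows, columns=FLNC_TSV_COLUMNS)


def assignments_frame(pairs) -> pd.DataFrame:
    """(FlncRecord, BarcodeAssignment) pairs -> one evaluation/matrix row each."""
    rows = []
    for rec, asn in pairs:
        rows.append((
            rec.read_id, rec.segment_index, rec.seg_start, rec.seg_end,
            rec.raw_barcode, asn.corrected_barcode, asn.status, asn.posterior,
            rec.raw_umi, quals_to_string(rec.umi_qualities), rec.read_qv,
        ))
    return pd.DataFrame(rows, columns=[
        "read_id", "segment_index", "seg_start", "seg_end",
        "raw_barcode", "corrected_barcode", "status", "posterior",
        "umi", "umi_qual", "read_qv",
    ])


def assemble_matrix_input(
    assignments: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Join assigned records with their feature assignments on
    (read_id, segment_index); unassigned records are dropped."""
    assigned = assignments[assignments["status"] != "UNASSIGNED"]
    joined = assigned.merge(features, on=["read_id", "segment_index"], how="inner")
    joined = joined.rename(columns={"corrected_barcode": "cell"})
    return joined[[
        "read_id", "segment_index", "cell", "umi", "umi_qual",
        "gene_id", "isoform_id", "class_code",
    ]]


def write_flnc(result: DemuxResult, out_prefix) -> None:
    """Write FLNC transcripts (FASTQ), the record sidecar TSV and a summary."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    flnc_reads = [
        LongRead(
            f"{r.read_id}/{r.segment_index}",
            r.transcript,
            r.transcript_qualities,
            r.read_qv,
        )
        for r in result.records
    ]
    write_fastq(flnc_reads, f"{out_prefix}.flnc.fastq")
    records_to_frame(result).to_csv(f"{out_prefix}.flnc.tsv", sep="\t", index=False)
    with open(f"{out_prefix}.summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=1, sort_keys=True)
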