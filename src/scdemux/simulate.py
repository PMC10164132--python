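"""Synthetic concatenated single-cell isoform reads with full ground truth.

Each simulated read is a concatemer of 3-4 cDNA units joined by the
ligation-junction sequence, each unit independently reverse-complemented
with probability 0.5 (ligation is orientation-blind).  A full-length unit
is

    p5 + transcript + polyA + revcomp(UMI) + revcomp(barcode) + revcomp(p3)

and a template-switching artifact unit carries 5'-primer-type terminals and
no poly(A), barcode or UMI:

    p5 + cDNA + revcomp(p5)

Sequencing errors are applied i.i.d. per base at configured substitution /
insertion / deletion rates; per-base qualities reflect the substitution
rate with small jitter, and the read-level QV is one minus the realised
error fraction.  The synthetic whitelist keeps barcodes mutually at Hamming
distance >= 3 so single-substitution correction is unambiguous; the
spike-in barcode deliberately violates this (the whitelist excludes it but
contains a member at edit distance 1), reproducing the adversarial probe
used to measure assignment specificity.

Transcripts come from a generated toy transcriptome, so feature-assignment
truth (gene, isoform, class code "=") exists without any alignment step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import LongRead, PrimerSet, revcomp, write_fastq, write_whitelist
from .primerscan import find_primer_hits

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_UNIT_COLUMNS = [
    "read_id", "unit_index", "unit_type", "start", "end", "orientation",
    "cell_bc", "umi", "gene_id", "isoform_id", "transcript_len", "polya_len",
    "is_spike",
]


@dataclass
class SimConfig:
    n_reads: int = 20000
    n_cells: int = 200
    whitelist_size: int = 1000
    spike_in_barcode: Optional[str] = "AAGTCCTTCCAGTCTT"
    spike_in_fraction: float = 0.01
    units_min: int = 3
    units_max: int = 4
    transcript_len_mean: float = 500.0
    transcript_len_sd: float = 150.0
    transcript_len_min: int = 100
    polya_len_mean: float = 30.0
    polya_len_sd: float = 5.0
    polya_len_min: int = 12
    artifact_fraction: float = 0.08   # HIT-mode default; ~0.5 emulates no artifact removal
    sub_rate: float = 0.005
    ins_rate: float = 0.001
    del_rate: float = 0.001
    n_genes: int = 60
    max_isoforms_per_gene: int = 3
    n_spike_isoforms: int = 7
    seed: int = 0
    primers: PrimerSet = field(default_factory=PrimerSet)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "artifact_fraction",
                     "spike_in_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} not in [0, 1]")
        if self.units_min < 1 or self.units_max < self.units_min:
            raise ValueError("invalid units_per_read range")


@dataclass
class SimulatedLibrary:
    reads: list[LongRead]
    truth_units: pd.DataFrame          # TRUTH_UNIT_COLUMNS
    whitelist: list[str]
    truth_features: pd.DataFrame       # read_id, segment_index, gene_id, isoform_id, class_code
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, outdir / "reads.fastq")
        self.truth_units.to_csv(outdir / "truth_units.tsv", sep="\t", index=False)
        write_whitelist(self.whitelist, outdir / "whitelist.txt")
        self.truth_features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _random_transcript(rng: np.random.Generator, n: int, primers: PrimerSet) -> str:
    """Random transcript free of internal primer-like stretches.

    cDNA synthesis and amplification presuppose that the primer sequences do
    not occur inside the insert; a random 500-mer occasionally contains a
    16 bp stretch locally alignable to a primer at >=75% identity, so such
    draws are rejected and redrawn.  The three 3'-terminal bases are drawn
    from {C,G,T}: a transcript ending in A fuses seamlessly with its poly(A)
    tail, making the tail boundary unidentifiable for any trimmer."""
    non_a = np.frombuffer(b"CGT", dtype=np.uint8)
    for _ in range(100):
        seq = (
            _random_seq(rng, max(n - 3, 0))
            + non_a[rng.integers(0, 3, size=min(n, 3))].tobytes().decode("ascii")
        )
        hits = find_primer_hits(
            LongRead("t", seq), primers, min_primerlen=16, min_identity=0.75
        )
        if not hits:
            return seq
    raise RuntimeError("could not draw a primer-free transcript")


def _barcode_context_clean(barcode: str, primers: PrimerSet) -> bool:
    """True unless the barcode's in-read context mimics a primer.

    In a read the barcode sits as revcomp(barcode) immediately before
    revcomp(p3); a barcode whose fused context aligns locally to a primer at
    >=75% identity over >=16 bp (other than the genuine 3'-primer match)
    would let a spurious hit truncate the barcode block, so such draws are
    rejected."""
    ctx = revcomp(barcode) + revcomp(primers.p3)
    hits = find_primer_hits(
        LongRead("ctx", ctx), primers, min_primerlen=16, min_identity=0.75
    )
    return all(h.start >= len(barcode) for h in hits)


def _make_whitelist(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[str], Optional[str]]:
    """Whitelist of mutually >=3-Hamming barcodes; if spiking, one member is
    placed at Hamming distance 1 from the (excluded) spike-in barcode."""
    bc_len = cfg.primers.bc_len
    rows: list[np.ndarray] = []          # barcodes kept at mutual distance
    out: list[str] = []
    neighbour: Optional[str] = None
    if cfg.spike_in_barcode is not None:
        spike = cfg.spike_in_barcode.upper()
        if len(spike) != bc_len:
            raise ValueError("spike_in_barcode length != bc_len")
        rows.append(np.frombuffer(spike.encode(), dtype=np.uint8))
        for _ in range(200):
            pos = int(rng.integers(0, bc_len))
            choices = [b for b in b"ACGT" if b != spike.encode()[pos]]
            nb = bytearray(spike.encode())
            nb[pos] = choices[int(rng.integers(0, 3))]
            if _barcode_context_clean(nb.decode("ascii"), cfg.primers):
                neighbour = nb.decode("ascii")
                break
        else:
            raise ValueError("cannot place a clean Hamming-1 neighbour of the spike-in")
        rows.append(np.frombuffer(neighbour.encode(), dtype=np.uint8))
        out.append(neighbour)
    max_tries = 200 * cfg.whitelist_size + 1000
    tries = 0
    stack = np.vstack(rows) if rows else np.empty((0, bc_len), dtype=np.uint8)
    while len(out) < cfg.whitelist_size:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {cfg.whitelist_size} barcodes at mutual Hamming "
                f"distance >= 3 (length {bc_len})"
            )
        cand = _BASES[rng.integers(0, 4, size=bc_len)]
        if stack.shape[0] and int((stack != cand).sum(axis=1).min()) < 3:
            continue
        cand_s = cand.tobytes().decode("ascii")
        if not _barcode_context_clean(cand_s, cfg.primers):
            continue
        stack = np.vstack([stack, cand])
        out.append(cand_s)
    return out, neighbour


def _apply_errors(
    seq: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, np.ndarray, float, np.ndarray]:
    """Apply i.i.d. per-base errors; returns (mutated seq, Phred qualities,
    read_qv, coordinate map old->new of length len(seq)+1)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(codes)
    base_q = int(round(-10.0 * math.log10(max(cfg.sub_rate, 1e-4))))
    r = rng.random(n)
    del_mask = r < cfg.del_rate
    ins_mask = (~del_mask) & (r < cfg.del_rate + cfg.ins_rate)
    sub_mask = (~del_mask) & (~ins_mask) & (
        r < cfg.del_rate + cfg.ins_rate + cfg.sub_rate
    )
    # substitutions: shift to one of the three other bases
    if sub_mask.any():
        idx = np.nonzero(sub_mask)[0]
        code_idx = np.searchsorted(_BASES, codes[idx])  # ACGT are sorted ASCII
        new_idx = (code_idx + rng.integers(1, 4, size=len(idx))) % 4
        codes[idx] = _BASES[new_idx]
    # deletions drop the base; insertions duplicate the slot, second copy random
    counts = np.ones(n, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2
    cmap = np.concatenate([[0], np.cumsum(counts)])
    out = np.repeat(codes, counts)
    if ins_mask.any():
        ins_out_pos = cmap[1:][ins_mask] - 1
        out[ins_out_pos] = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
    quals = np.clip(
        base_q + rng.integers(-2, 3, size=len(out)), 2, 60
    ).astype(np.int16)
    n_err = int(del_mask.sum() + ins_mask.sum() + sub_mask.sum())
    read_qv = max(0.0, 1.0 - n_err / max(n, 1))
    return out.tobytes().decode("ascii"), quals, read_qv, cmap


def simulate_library(cfg: SimConfig) -> SimulatedLibrary:
    """Generate a seeded synthetic library; byte-identical for equal seeds."""
    rng = np.random.default_rng(cfg.seed)
    primers = cfg.primers
    whitelist, neighbour = _make_whitelist(cfg, rng)
    cell_pool = [b for b in whitelist if b != neighbour]
    cells = list(rng.choice(cell_pool, size=min(cfg.n_cells, len(cell_pool)), replace=False))

    def tlen() -> int:
        return max(cfg.transcript_len_min,
                   int(round(rng.normal(cfg.transcript_len_mean, cfg.transcript_len_sd))))

    # toy transcriptome + spike-in isoform set
    isoforms: list[tuple[str, str, str]] = []
    for g in range(cfg.n_genes):
        gene = f"G{g:04d}"
        for i in range(int(rng.integers(1, cfg.max_isoforms_per_gene + 1))):
            isoforms.append((gene, f"{gene}.I{i + 1}", _random_transcript(rng, tlen(), primers)))
    spike_isoforms = [
        ("SIRV", f"SIRV.I{i + 1}", _random_transcript(rng, tlen(), primers))
        for i in range(cfg.n_spike_isoforms)
    ]

    reads: list[LongRead] = []
    truth_rows: list[tuple] = []
    feature_rows: list[tuple] = []
    junction = primers.junction
    for ridx in range(cfg.n_reads):
        read_id = f"sim_{ridx:06d}"
        n_units = int(rng.integers(cfg.units_min, cfg.units_max + 1))
        parts: list[str] = []
        unit_meta: list[tuple] = []   # spans filled after assembly
        pos = 0
        spans: list[tuple[int, int]] = []
        for uidx in range(n_units):
            if uidx > 0:
                parts.append(junction)
                pos += len(junction)
            if rng.random() < cfg.artifact_fraction:
                # template-switching artifacts are barcode-free cDNA; reuse
                # the (primer-free) isoform pool as their sequence source
                insert = isoforms[int(rng.integers(0, len(isoforms)))][2]
                unit = primers.p5 + insert + revcomp(primers.p5)
                meta = ("TSO_ARTIFACT", "", "", "", "", len(insert), 0, False)
            else:
                is_spike = (
                    cfg.spike_in_barcode is not None
                    and rng.random() < cfg.spike_in_fraction
                )
                if is_spike:
                    bc = cfg.spike_in_barcode
                    gene, iso, tseq = spike_isoforms[int(rng.integers(0, len(spike_isoforms)))]
                else:
                    bc = cells[int(rng.integers(0, len(cells)))]
                    gene, iso, tseq = isoforms[int(rng.integers(0, len(isoforms)))]
                umi = _random_seq(rng, primers.umi_len)
                polya = max(cfg.polya_len_min,
                            int(round(rng.normal(cfg.polya_len_mean, cfg.polya_len_sd))))
                unit = (
                    primers.p5 + tseq + "A" * polya
                    + revcomp(umi) + revcomp(bc) + revcomp(primers.p3)
                )
                meta = ("FLNC", bc, umi, gene, iso, len(tseq), polya, is_spike)
            if rng.random() < 0.5:
                unit = revcomp(unit)
                orientation = "-"
            else:
                orientation = "+"
            parts.append(unit)
            spans.append((pos, pos + len(unit)))
            pos += len(unit)
            unit_meta.append(meta + (orientation,))

        clean = "".join(parts)
        seq, quals, read_qv, cmap = _apply_errors(clean, cfg, rng)
        reads.append(LongRead(read_id, seq, quals, read_qv))
        for uidx, ((s, e), meta) in enumerate(zip(spans, unit_meta)):
            utype, bc, umi, gene, iso, tl, pl, is_spike, orientation = meta
            truth_rows.append((
                read_id, uidx, utype, int(cmap[s]), int(cmap[e]), orientation,
                bc, umi, gene, iso, tl, pl, is_spike,
            ))
            if utype == "FLNC":
                feature_rows.append((read_id, uidx, gene, iso, "="))

    truth_units = pd.DataFrame(truth_rows, columns=TRUTH_UNIT_COLUMNS)
    truth_features = pd.DataFrame(
        feature_rows,
        columns=["read_id", "segment_index", "gene_id", "isoform_id", "class_code"],
    )
    return SimulatedLibrary(reads, truth_units, whitelist, truth_features, cfg)
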