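"""Domain types, coordinate conventions and file IO.

All coordinates in this package are 0-based, half-open.  Strand "+" means
the orientation in which a read was given; "-" is its reverse complement.
Per-base qualities are Phred scores (integers); FASTQ encoding is Phred+33.
Reads that carry no qualities are treated as uniform Phred ``DEFAULT_PHRED``
wherever a quality is needed (e.g. the barcode-correction posterior).
"""

from __future__ import annotations

import dataclasses
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

import numpy as np
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# Fallback Phred score for reads without per-base qualities.
DEFAULT_PHRED = 30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def phred_to_error(q) -> np.ndarray:
    """Phred score(s) -> probability of a base-call error, 10^(-q/10)."""
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    """One high-accuracy (consensus) long read.

    ``read_qv`` is the read-level predicted accuracy in [0, 1] (the
    consensus-read QV).  When absent it can be derived from the per-base
    qualities via :meth:`effective_read_qv`.
    """

    read_id: str
    sequence: str
    qualities: Optional[np.ndarray] = None  # per-base Phred, len == len(sequence)
    read_qv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=np.int16)
            if len(self.qualities) != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id!r}: quality length "
                    f"{len(self.qualities)} != sequence length {len(self.sequence)}"
                )
        if self.read_qv is not None and not (0.0 <= self.read_qv <= 1.0):
            raise ValueError(f"read {self.read_id!r}: read_qv {self.read_qv} not in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)

    def effective_qualities(self) -> np.ndarray:
        if self.qualities is not None:
            return self.qualities
        return np.full(len(self.sequence), DEFAULT_PHRED, dtype=np.int16)

    def effective_read_qv(self) -> float:
        """Read accuracy: stored value, else 1 - mean per-base error probability."""
        if self.read_qv is not None:
            return self.read_qv
        if len(self.sequence) == 0:
            return 1.0
        return float(1.0 - phred_to_error(self.effective_qualities()).mean())

    def reverse_complement(self) -> "LongRead":
        quals = None if self.qualities is None else self.qualities[::-1].copy()
        return LongRead(self.read_id, revcomp(self.sequence), quals, self.read_qv)


@dataclass
class PrimerSet:
    """5'/3' cDNA primers, the ligation junction, and barcode/UMI geometry.

    The 16 bp cell barcode plus the 12 bp UMI form the 28 bp block that
    follows the 3' primer on the barcode strand.  Deoxyuracil (U) printed in
    primer designs is mapped to T on construction, since sequenced molecules
    contain thymine.
    """

    p5: str = "AAGCAGTGGTATCAACGCAGAG"
    p3: str = "CTACACGACGCTCTTCCGATCT"
    junction: str = "ACTAGT"
    bc_len: int = 16
    umi_len: int = 12

    def __post_init__(self) -> None:
        self.p5 = self.p5.upper().replace("U", "T")
        self.p3 = self.p3.upper().replace("U", "T")
        self.junction = self.junction.upper().replace("U", "T")
        if self.p5 == self.p3:
            raise ValueError("5' and 3' primers must differ")
        if self.bc_len + self.umi_len != 28:
            raise ValueError("bc_len + umi_len must equal 28")


@dataclass
class Whitelist:
    """The set of legal cell barcodes with observed exact-match frequencies."""

    barcodes: frozenset[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
        for b in self.counts:
            if b not in self.barcodes:
                raise ValueError(f"counted barcode {b!r} not on the whitelist")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes)))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default.

    Defaults follow the published tool parameters where stated
    (min_primerlen 16, min_seqlen 50, barcode posterior threshold 0.975,
    UMI base quality >= 10, isoform filters minUMIcount 3 / min 5 cells,
    read-QV cutoff 0.95); the remainder are this package's own declared
    choices, recorded in run output.
    """

    # primer scan
    min_primerlen: int = 16
    min_identity: float = 0.8
    seed_len: int = 5
    max_overlap: int = 5
    # segmentation
    min_seqlen: int = 50
    polya_window: int = 10
    min_frac_a: float = 0.8
    min_polya_len: int = 10
    polya_search_limit: int = 50
    # barcode correction
    bc_posterior_threshold: float = 0.975
    read_qv_cutoff: float = 0.95
    # UMI filtering
    min_umi_qual: int = 10
    # isoform matrix
    min_umi_count: int = 3
    min_cells: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[LongRead]:
    """Stream reads from a FASTQ or FASTA file (gzip transparently).

    FASTA records yield reads without qualities.  Malformed records raise a
    ``ValueError`` naming the record index.  N bases are preserved.
    """
    path = Path(path)
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            yield from _read_fasta(fh, path)
        elif head == "@":
            yield from _read_fastq_records(fh, path)
        elif head == "":
            return
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {head!r})")


def _read_fastq_records(fh: TextIO, path: Path) -> Iterator[LongRead]:
    idx = 0
    try:
        for title, seq, qual in FastqGeneralIterator(fh):
            seq = seq.upper()
            _check_bases(seq, path, idx)
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            try:
                yield LongRead(title.split()[0], seq, quals)
            except ValueError as exc:
                raise ValueError(f"{path}: record {idx}: {exc}") from exc
            idx += 1
    except ValueError as exc:
        # Biopython raises plain ValueErrors on malformed records.
        raise ValueError(f"{path}: malformed FASTQ at record {idx}: {exc}") from exc


def _read_fasta(fh: TextIO, path: Path) -> Iterator[LongRead]:
    name: Optional[str] = None
    chunks: list[str] = []
    idx = 0

    def flush() -> Iterator[LongRead]:
        nonlocal idx
        if name is not None:
            seq = "".join(chunks).upper()
            if not seq:
                raise ValueError(f"{path}: record {idx} ({name!r}) has an empty sequence")
            _check_bases(seq, path, idx)
            yield LongRead(name, seq)
            idx += 1

    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            yield from flush()
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise ValueError(f"{path}: sequence data before first FASTA header")
            chunks.append(line)
    yield from flush()


def _check_bases(seq: str, path: Path, idx: int) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{path}: record {idx}: invalid characters {sorted(bad)}")


def write_fastq(reads: Iterable[LongRead], path) -> None:
    """Write reads as FASTQ (Phred+33); quality-less reads get DEFAULT_PHRED."""
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = (read.effective_qualities().clip(0, 93) + 33).astype(np.uint8)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual.tobytes().decode('ascii')}\n")


def load_whitelist(path) -> Whitelist:
    """Load a one-barcode-per-line whitelist; duplicates collapse.

    Mixed lengths or non-ACGT characters are errors.  Counts start at zero.
    """
    barcodes: set[str] = set()
    length: Optional[int] = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            bc = line.strip().upper()
            if not bc:
                continue
            if set(bc) - set("ACGT"):
                raise ValueError(f"{path}:{lineno}: non-ACGT barcode {bc!r}")
            if length is None:
                length = len(bc)
            elif len(bc) != length:
                raise ValueError(
                    f"{path}:{lineno}: barcode length {len(bc)} != {length}"
                )
            barcodes.add(bc)
    if not barcodes:
        raise ValueError(f"{path}: empty whitelist")
    return Whitelist(frozenset(barcodes), {})


def write_whitelist(barcodes: Iterable[str], path) -> None:
    with _open_text(path, "wt") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")


def quals_to_string(quals: np.ndarray) -> str:
    """Encode Phred scores as a Phred+33 string (for TSV sidecars)."""
    return (np.asarray(quals, dtype=np.int16).clip(0, 93) + 33).astype(np.uint8).tobytes().decode("ascii")


def quals_from_string(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
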