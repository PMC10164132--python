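"""Whitelist-based cell-barcode confirmation and correction.

An observed barcode found verbatim on the whitelist is confirmed (EXACT).
Otherwise every whitelist barcode at Hamming distance 1 (substitutions
only) is a candidate origin; the posterior that the observation arose from
candidate ``c`` by a sequencing error at the differing base ``i`` is

    posterior(c) = prior(c) * eps(q_i) / sum over candidates,
    eps(q) = 10^(-q/10),
    prior(c) = (counts[c] + 1) / sum over candidates (counts[c'] + 1),

where ``counts`` are whitelist exact-match frequencies in the data set and
the +1 pseudocount lets never-observed true barcodes be rescued.  The
observation is replaced by the argmax candidate only when its posterior
exceeds the threshold (default 0.975); otherwise it stays UNASSIGNED.
Indel-corrupted barcodes have no Hamming-1 candidate and fall to
UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .core import Whitelist, phred_to_error
from .segment import FlncRecord

UNASSIGNED = "UNASSIGNED"

_BASES = "ACGT"


@dataclass(frozen=True)
class BarcodeAssignment:
    raw_barcode: str
    corrected_barcode: str          # whitelist member or UNASSIGNED
    status: str                     # EXACT | CORRECTED | UNASSIGNED
    posterior: Optional[float] = None

    @property
    def assigned(self) -> bool:
        return self.status != UNASSIGNED


def count_whitelist_freq(records: Iterable[FlncRecord], wl: Whitelist) -> Whitelist:
    """Observed frequency of every whitelist barcode (exact matches only)."""
    counts = {b: 0 for b in wl.barcodes}
    for rec in records:
        if rec.raw_barcode in counts:
            counts[rec.raw_barcode] += 1
    return Whitelist(wl.barcodes, counts)


def hamming1_candidates(raw: str, wl: Whitelist) -> list[tuple[str, int]]:
    """Whitelist barcodes at Hamming distance exactly 1, with the differing
    position; generated by single-substitution enumeration (48 lookups for a
    16-mer), equivalent to a whole-whitelist scan."""
    out = []
    for i, orig in enumerate(raw):
        for b in _BASES:
            if b == orig:
                continue
            cand = raw[:i] + b + raw[i + 1:]
            if cand in wl.barcodes:
                out.append((cand, i))
    return out


def correct_barcode(
    raw: str,
    quals: np.ndarray,
    wl: Whitelist,
    threshold: float = 0.975,
) -> BarcodeAssignment:
    """Confirm or correct one observed barcode against the whitelist."""
    if len(raw) != wl.barcode_length:
        raise ValueError(
            f"barcode length {len(raw)} != whitelist length {wl.barcode_length}"
        )
    if raw in wl.barcodes:
        return BarcodeAssignment(raw, raw, "EXACT")
    cands = hamming1_candidates(raw, wl)
    if not cands:
        return BarcodeAssignment(raw, UNASSIGNED, UNASSIGNED)
    quals = np.asarray(quals, dtype=float)
    pseudo = np.array([wl.counts.get(c, 0) + 1 for c, _ in cands], dtype=float)
    priors = pseudo / pseudo.sum()
    errs = np.array([phred_to_error(quals[i]) for _, i in cands])
    scores = priors * errs
    posteriors = scores / scores.sum()
    best = int(np.argmax(posteriors))
    best_post = float(posteriors[best])
    # a tie at the max can never exceed a threshold >= 0.5 in a >=2-way split
    n_at_max = int(np.sum(np.isclose(posteriors, best_post, rtol=0, atol=1e-15)))
    if best_post > threshold and n_at_max == 1:
        return BarcodeAssignment(raw, cands[best][0], "CORRECTED", best_post)
    return BarcodeAssignment(raw, UNASSIGNED, UNASSIGNED, best_post)


def correct_records(
    records: list[FlncRecord],
    wl: Whitelist,
    threshold: float = 0.975,
    read_qv_cutoff: Optional[float] = None,
) -> list[tuple[FlncRecord, BarcodeAssignment]]:
    """Count whitelist frequencies, then correct every record's barcode.

    Frequencies are computed on the same record set being corrected (after
    the optional read-QV cut, when one is given).
    """
    if read_qv_cutoff is not None:
        records = [
            r for r in records
            if r.read_qv is None or r.read_qv >= read_qv_cutoff
        ]
    counted = count_whitelist_freq(records, wl)
    # cache: many records share a raw barcode but qualities differ only for
    # non-exact ones, so cache exact confirmations only
    exact_cache: dict[str, BarcodeAssignment] = {}
    out = []
    for rec in records:
        asn = exact_cache.get(rec.raw_barcode)
        if asn is None:
            asn = correct_barcode(rec.raw_barcode, rec.bc_qualities, counted, threshold)
            if asn.status == "EXACT":
                exact_cache[rec.raw_barcode] = asn
        out.append((rec, asn))
    return out
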