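"""UMI quality filtering and within-(cell, feature) deduplication.

A UMI passes basic quality filtering unless it is a homopolymer, contains
an N, or has any base with quality < 10.  Within the group of UMIs sharing
a cell barcode and a feature (gene or isoform), UMIs within Hamming
distance 1 of a higher-count (or equal-count, lexicographically smaller)
UMI are corrected to it: processing runs in descending count (ties broken
by ascending sequence), each UMI merges into the first already-accepted
Hamming-1 neighbour in that order, and read counts add on merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class UmiGroup:
    """UMIs observed for one (cell barcode, feature) pair, with read counts."""

    cell: str
    feature: str
    umi_counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.umi_counts.values())


@dataclass(frozen=True)
class UmiFilterResult:
    passed: bool
    reason: Optional[str] = None  # HOMOPOLYMER | CONTAINS_N | LOW_QUAL


def filter_umi(umi: str, quals: np.ndarray, min_qual: int = 10) -> UmiFilterResult:
    """Basic UMI quality filter: homopolymers, Ns, low-quality bases."""
    if len(set(umi)) == 1:
        return UmiFilterResult(False, "HOMOPOLYMER")
    if "N" in umi:
        return UmiFilterResult(False, "CONTAINS_N")
    if np.any(np.asarray(quals) < min_qual):
        return UmiFilterResult(False, "LOW_QUAL")
    return UmiFilterResult(True)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diffs = 0
    for x, y in zip(a, b):
        if x != y:
            diffs += 1
            if diffs > 1:
                return False
    return diffs == 1


def dedup_umis(group: UmiGroup) -> tuple[UmiGroup, dict[str, str]]:
    """Merge 1-Hamming UMI variants into their higher-count neighbour.

    Returns the corrected group and the old->new mapping (identity entries
    included).  Total count is conserved; surviving UMIs are mutually at
    Hamming distance >= 2, so the operation is idempotent.
    """
    order = sorted(group.umi_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    accepted: list[str] = []
    merged_counts: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for umi, count in order:
        target = None
        for acc in accepted:
            if _hamming1(umi, acc):
                target = acc
                break
        if target is None:
            accepted.append(umi)
            merged_counts[umi] = merged_counts.get(umi, 0) + count
            mapping[umi] = umi
        else:
            merged_counts[target] += count
            mapping[umi] = target
    return UmiGroup(group.cell, group.feature, merged_counts), mapping
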