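"""Scoring demultiplexed output against simulator ground truth.

Demultiplexed records are matched to truth units by maximal coordinate
overlap within the read (truth spans are in post-error read coordinates),
so one missed primer cannot shift the pairing of every later unit.

Confusion-matrix definitions (normative for this package, printed in the
report header): positives are spike-in truth units among the scored
records.  TP = spike units assigned the spike barcode; FN = spike units
assigned any other barcode or left unassigned; FP = non-spike units
assigned the spike barcode; TN = the remaining non-spike units.  Accuracy =
(TP+TN)/all, specificity = TN/(TN+FP), sensitivity = TP/(TP+FN).

Per-barcode assignment accuracy is the fraction of assigned FLNC units
whose corrected barcode equals the truth barcode, computed by default over
units whose true barcode is assignable (on the whitelist); spike-in units,
whose barcode is deliberately absent from the whitelist, are scored by the
confusion matrix instead (``include_spike=True`` folds them in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .barcodes import UNASSIGNED

CONFUSION_DEFINITIONS = (
    "positives = spike-in truth units; TP: spike units assigned the spike "
    "barcode; FN: spike units assigned otherwise or unassigned; FP: non-spike "
    "units assigned the spike barcode; TN: remaining non-spike units"
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)


def match_to_truth(assignments: pd.DataFrame, truth_units: pd.DataFrame) -> pd.DataFrame:
    """Attach the maximally-overlapping truth unit to every record row.

    ``assignments`` needs read_id, seg_start, seg_end (plus whatever
    assignment columns the caller wants to keep).  Raises if any record
    overlaps no truth unit of its read.
    """
    truth_by_read: dict[str, list[tuple[int, int, int]]] = {}
    for idx, row in enumerate(
        truth_units[["read_id", "start", "end"]].itertuples(index=False)
    ):
        truth_by_read.setdefault(row.read_id, []).append((row.start, row.end, idx))
    matched_idx = []
    for row in assignments[["read_id", "seg_start", "seg_end"]].itertuples(index=False):
        units = truth_by_read.get(row.read_id, [])
        best, best_ov = None, 0
        for s, e, idx in units:
            ov = min(e, row.seg_end) - max(s, row.seg_start)
            if ov > best_ov:
                best, best_ov = idx, ov
        if best is None:
            raise ValueError(
                f"record {row.read_id}[{row.seg_start}:{row.seg_end}] has no "
                "overlapping truth unit"
            )
        matched_idx.append(best)
    truth_cols = truth_units.iloc[matched_idx].reset_index(drop=True)
    truth_cols = truth_cols.rename(
        columns={c: f"truth_{c}" for c in truth_cols.columns}
    )
    return pd.concat([assignments.reset_index(drop=True), truth_cols], axis=1)


def score_spikein(
    assignments: pd.DataFrame,
    truth_units: pd.DataFrame,
    spike_barcode: str,
    count_unassigned_spike_as_fn: bool = True,
) -> ConfusionCounts:
    """Confusion matrix for spike-in barcode assignment (see module header)."""
    matched = match_to_truth(assignments, truth_units)
    is_spike = matched["truth_is_spike"].astype(bool)
    assigned_spike = matched["corrected_barcode"] == spike_barcode
    unassigned = matched["corrected_barcode"] == UNASSIGNED
    if not count_unassigned_spike_as_fn:
        keep = ~(is_spike & unassigned)
        is_spike, assigned_spike = is_spike[keep], assigned_spike[keep]
    tp = int((is_spike & assigned_spike).sum())
    fn = int((is_spike & ~assigned_spike).sum())
    fp = int((~is_spike & assigned_spike).sum())
    tn = int((~is_spike & ~assigned_spike).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def per_barcode_accuracy(
    assignments: pd.DataFrame,
    truth_units: pd.DataFrame,
    include_spike: bool = False,
) -> float:
    """Fraction of assigned units whose corrected barcode equals truth."""
    matched = match_to_truth(assignments, truth_units)
    assigned = matched["corrected_barcode"] != UNASSIGNED
    if not include_spike:
        assigned &= ~matched["truth_is_spike"].astype(bool)
    scored = matched[assigned]
    if len(scored) == 0:
        raise ValueError("no assigned units to score")
    return float((scored["corrected_barcode"] == scored["truth_cell_bc"]).mean())


def run_report(
    summary: dict,
    assignments: Optional[pd.DataFrame] = None,
    gene_matrix=None,
    isoform_matrix=None,
    read_qv_cutoff: float = 0.95,
) -> dict:
    """Deterministic per-run accounting: segment partition, yields, assignment."""
    report = {
        "confusion_definitions": CONFUSION_DEFINITIONS,
        "segmentation": summary,
    }
    if assignments is not None and len(assignments):
        assigned = assignments["corrected_barcode"] != UNASSIGNED
        at_qv = assignments["read_qv"] >= read_qv_cutoff
        report["assignment"] = {
            "n_records": int(len(assignments)),
            "n_assigned": int(assigned.sum()),
            "assigned_fraction": float(assigned.mean()),
            "read_qv_cutoff": read_qv_cutoff,
            "n_at_qv_cutoff": int(at_qv.sum()),
            "assigned_fraction_at_qv_cutoff": (
                float(assignments.loc[at_qv, "corrected_barcode"].ne(UNASSIGNED).mean())
                if int(at_qv.sum()) else 0.0
            ),
        }
    for name, mat in (("gene_matrix", gene_matrix), ("isoform_matrix", isoform_matrix)):
        if mat is not None:
            report[name] = {
                "n_features": len(mat.features),
                "n_cells": len(mat.cells),
                "total_umis": int(mat.matrix.sum()),
            }
    return report
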