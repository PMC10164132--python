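"""Single-cell gene and isoform UMI-count matrices.

Per-record feature assignments (gene, isoform, gffcompare-style class code)
are joined with corrected cell barcodes and UMIs.  Records whose class code
is outside the exonic set {=, c, k, m, n, j, e, o} are excluded, matching
the convention of short-read cell-calling pipelines.  Per (cell, feature),
UMIs are quality-filtered and 1-Hamming deduplicated; a matrix entry is the
number of distinct corrected UMIs.  The isoform matrix additionally drops
(cell, isoform) entries with fewer than ``min_umi_count`` UMIs and isoforms
detected in fewer than ``min_cells`` cells.

Matrices are written in Matrix Market triplet form (1-based indices) with
features.tsv / barcodes.tsv sidecars, the de-facto single-cell exchange
layout; rows and columns are ordered lexicographically for determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .umi import UmiGroup, dedup_umis, filter_umi
from .core import quals_from_string

EXONIC_CLASS_CODES = frozenset("=ckmnjeo")

#: columns of a feature-assignment table (TSV)
FEATURE_COLUMNS = ["read_id", "segment_index", "gene_id", "isoform_id", "class_code"]


@dataclass
class CountMatrix:
    """Sparse features x cells matrix of distinct-UMI counts."""

    features: list[str]
    cells: list[str]
    matrix: scipy.sparse.csr_matrix  # shape (len(features), len(cells))

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def triplets(self) -> set[tuple[str, str, int]]:
        coo = self.matrix.tocoo()
        return {
            (self.features[i], self.cells[j], int(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "matrix.mtx", self.matrix.tocoo(), field="integer")
        (outdir / "features.tsv").write_text("".join(f + "\n" for f in self.features))
        (outdir / "barcodes.tsv").write_text("".join(c + "\n" for c in self.cells))
        per_cell = np.asarray(self.matrix.sum(axis=0)).ravel()
        genes_per_cell = np.asarray((self.matrix > 0).sum(axis=0)).ravel()
        summary = {
            "n_features": len(self.features),
            "n_cells": len(self.cells),
            "per_cell": {
                c: {"features": int(g), "umis": int(u)}
                for c, g, u in zip(self.cells, genes_per_cell, per_cell)
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    @classmethod
    def read(cls, outdir) -> "CountMatrix":
        outdir = Path(outdir)
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(outdir / "matrix.mtx"))
        features = (outdir / "features.tsv").read_text().splitlines()
        cells = (outdir / "barcodes.tsv").read_text().splitlines()
        return cls(features, cells, mat)


def read_feature_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "gene_id": str, "isoform_id": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature-assignment columns {sorted(missing)}")
    return df


def write_feature_assignments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _check_unique(records: pd.DataFrame) -> None:
    dup = records.duplicated(subset=["read_id", "segment_index"])
    if dup.any():
        first = records.loc[dup, ["read_id", "segment_index"]].iloc[0]
        raise ValueError(
            f"duplicate record for read {first['read_id']!r} "
            f"segment {first['segment_index']}"
        )


def _exonic_rows(records: pd.DataFrame) -> pd.DataFrame:
    exonic = records["class_code"].isin(EXONIC_CLASS_CODES)
    missing_gene = exonic & (records["gene_id"].isna() | (records["gene_id"] == ""))
    if missing_gene.any():
        rid = records.loc[missing_gene, "read_id"].iloc[0]
        raise ValueError(
            f"exonic class code without a gene_id (read {rid!r}): corrupt assignment table"
        )
    return records[exonic]


def _filtered_umi_counts(rows: pd.DataFrame, feature_col: str, min_umi_qual: int):
    """(cell, feature) -> {umi: read count}, after per-observation UMI filtering."""
    keep = [
        filter_umi(u, quals_from_string(q), min_qual=min_umi_qual).passed
        for u, q in zip(rows["umi"], rows["umi_qual"])
    ]
    rows = rows[np.asarray(keep, dtype=bool)]
    grouped: dict[tuple[str, str], dict[str, int]] = {}
    for cell, feat, umi in zip(rows["cell"], rows[feature_col], rows["umi"]):
        grouped.setdefault((cell, feat), {}).setdefault(umi, 0)
        grouped[(cell, feat)][umi] += 1
    return grouped


def _to_matrix(entries: dict[tuple[str, str], int]) -> CountMatrix:
    features = sorted({f for _, f in entries})
    cells = sorted({c for c, _ in entries})
    fidx = {f: i for i, f in enumerate(features)}
    cidx = {c: j for j, c in enumerate(cells)}
    rows, cols, data = [], [], []
    for (cell, feat), count in entries.items():
        rows.append(fidx[feat])
        cols.append(cidx[cell])
        data.append(count)
    mat = scipy.sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(features), len(cells)), dtype=np.int64
    )
    return CountMatrix(features, cells, mat.tocsr())


def build_gene_matrix(records: pd.DataFrame, min_umi_qual: int = 10) -> CountMatrix:
    """Gene x cell distinct-UMI matrix from joined records.

    ``records`` columns: read_id, segment_index, cell, umi, umi_qual,
    gene_id, isoform_id, class_code — one row per assigned FLNC record
    (barcode status must not be UNASSIGNED).
    """
    _check_unique(records)
    rows = _exonic_rows(records)
    grouped = _filtered_umi_counts(rows, "gene_id", min_umi_qual)
    entries = {}
    for (cell, gene), umi_counts in grouped.items():
        deduped, _ = dedup_umis(UmiGroup(cell, gene, umi_counts))
        entries[(cell, gene)] = len(deduped.umi_counts)
    return _to_matrix(entries)


def build_isoform_matrix(
    records: pd.DataFrame,
    min_umi_count: int = 3,
    min_cells: int = 5,
    min_umi_qual: int = 10,
) -> CountMatrix:
    """Isoform x cell matrix with abundance filters.

    Per (cell, isoform) entries with a distinct corrected UMI count below
    ``min_umi_count`` are dropped; isoforms then detected in fewer than
    ``min_cells`` cells are removed entirely.
    """
    _check_unique(records)
    rows = _exonic_rows(records)
    rows = rows[rows["isoform_id"].notna() & (rows["isoform_id"] != "")]
    grouped = _filtered_umi_counts(rows, "isoform_id", min_umi_qual)
    entries = {}
    for (cell, iso), umi_counts in grouped.items():
        deduped, _ = dedup_umis(UmiGroup(cell, iso, umi_counts))
        n = len(deduped.umi_counts)
        if n >= min_umi_count:
            entries[(cell, iso)] = n
    cells_per_iso: dict[str, int] = {}
    for (_, iso) in entries:
        cells_per_iso[iso] = cells_per_iso.get(iso, 0) + 1
    entries = {
        key: v for key, v in entries.items() if cells_per_iso[key[1]] >= min_cells
    }
    return _to_matrix(entries)
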