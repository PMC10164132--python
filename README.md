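# scdemux

Demultiplexing toolkit for **concatenated single-cell long-read isoform
libraries**. High-throughput single-cell isoform sequencing protocols ligate
several barcoded full-length cDNAs into one long insert, so a single
high-accuracy consensus read carries 3–4 independent cDNA molecules in random
orientations. Before any expression analysis those concatemers must be cut
back into single-cell, single-molecule records. `scdemux` does that, end to
end, and ships a synthetic concatemer simulator with full ground truth so the
whole pipeline can be validated without sequencing data.

The pipeline:

1. **Primer scanning** — locate every 5′/3′ cDNA primer occurrence on both
   strands (seed-and-extend, seed length 5, local re-scoring; hits need
   ≥ 16 aligned bases at ≥ 80% identity) and resolve overlapping hits.
2. **Segmentation & classification** — consecutive primer hits delimit cDNA
   segments. A segment whose terminals are a proper opposite-strand pair
   (`5p+ … 3p-` or `3p+ … 5p-`) with a poly(A) tail, the 28 bp
   barcode+UMI block and a ≥ 50 bp transcript is **FLNC** (full-length
   non-chimeric); a segment with neither a 3′ primer nor a poly(A) signal is
   an **artifact** (template-switching by-product); the rest are **NFL**.
3. **Orientation & extraction** — each FLNC segment is re-expressed 5′→3′;
   the 16 bp cell barcode and 12 bp UMI follow the 3′ primer; the poly(A)
   tail is trimmed by a sliding-window scan (window 10, ≥ 80% A).
4. **Barcode correction** — an observed barcode `b` not on the whitelist is
   replaced by the whitelist barcode `c` at Hamming distance 1 maximising

   `P(c | b) ∝ prior(c) · ε(q_i)`, with `ε(q) = 10^(−q/10)`,
   `prior(c) = (n_c + 1) / Σ_{c'}(n_{c'} + 1)`

   where `q_i` is the base quality at the differing position and `n_c` the
   whitelist frequency of `c` in the data set; the replacement happens only
   when the posterior exceeds 0.975.
5. **UMI correction** — UMIs that are homopolymers, contain N, or have a
   base below Q10 are dropped; within a (cell, gene) group, UMIs at Hamming
   distance 1 from a higher-count UMI are merged into it.
6. **Count matrices** — gene × cell and isoform × cell distinct-UMI matrices
   (Matrix Market + sidecars). Gene counting keeps records whose
   gffcompare-style class code is in `= c k m n j e o`; the isoform matrix
   drops entries with < 3 UMIs and isoforms seen in < 5 cells.
7. **Evaluation** — confusion matrix (accuracy / specificity / sensitivity)
   for an adversarial barcode spike-in, per-barcode assignment accuracy, and
   run accounting, all against simulator ground truth.

## Worked example

```python
from scdemux import (SimConfig, Whitelist, simulate_library, demultiplex,
                     correct_records, assignments_frame, per_barcode_accuracy,
                     score_spikein)

cfg = SimConfig(n_reads=500, seed=7)          # 3-4 units/read, 0.5% subs, 0.1% indels
lib = simulate_library(cfg)
result = demultiplex(lib.reads)
print(result.summary()["counts"])

wl = Whitelist(frozenset(lib.whitelist))
pairs = correct_records(result.records, wl, threshold=0.975, read_qv_cutoff=0.95)
df = assignments_frame(pairs)
print(round(100 * per_barcode_accuracy(df, lib.truth_units), 4))
print(round(100 * score_spikein(df, lib.truth_units, cfg.spike_in_barcode).specificity, 4))
```

prints

```
{'FLNC': 1571, 'NFL': 11, 'ARTIFACT': 156}
100.0
100.0
```

The 500 concatemers decompose into 1,738 cDNA segments: 90.4% FLNC, 9.0%
artifacts (matching the configured 8% artifact rate plus boundary losses) and
a handful of NFL segments whose structure was damaged by simulated errors.
Of the 1,571 FLNC records, 1,498 receive a confident barcode; every one of
them matches the true cell of origin (accuracy 100%), and no record is ever
assigned the off-whitelist spike-in barcode (specificity 100%). The same
objects feed `build_gene_matrix` / `build_isoform_matrix` to produce sparse
count matrices.

A command-line interface wraps the same functions:

```sh
scdemux simulate --out-dir sim --seed 7 --n-reads 500
scdemux demux sim/reads.fastq --out-prefix run
scdemux correct --flnc run.flnc.tsv --whitelist sim/whitelist.txt --out barcodes.tsv
scdemux matrix --assignments barcodes.tsv --features sim/truth_features.tsv --out-dir mtx
scdemux evaluate --assignments barcodes.tsv --truth sim/truth_units.tsv \
    --spike-barcode AAGTCCTTCCAGTCTT --out report.json
```

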