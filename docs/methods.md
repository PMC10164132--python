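# Methods

## Library model

A concatemer read is modelled as 3–4 cDNA units joined by a 6 bp ligation
junction (`ACTAGT`), each unit independently reverse-complemented with
probability 0.5 (blunt ligation is orientation-blind). A full-length unit is

```
p5 + transcript + polyA + revcomp(UMI) + revcomp(barcode) + revcomp(p3)
```

with `p5 = AAGCAGTGGTATCAACGCAGAG` and `p3 = CTACACGACGCTCTTCCGATCT` (primer
designs printed with deoxyuracil are mapped U→T on load, since sequenced
molecules contain thymine). A template-switching (TSO) artifact unit carries
5′-primer-type terminals and no poly(A), barcode or UMI:
`p5 + cDNA + revcomp(p5)`. On the read's forward strand a unit therefore
shows terminals `5p+ … 3p-`, and its reverse complement `3p+ … 5p-` — the
four terminal combinations a segmenter must recognise.

All coordinates are 0-based half-open; strand `+` is the read-as-given
orientation.

## Primer scanning

The 5′/3′ primers are located by seed-and-extend: exact 5-mer seed matches
(both primers, both strands) are clustered by alignment diagonal (tolerance
±8; a cluster needs ≥ 2 seeds — a full 22-mer primer with two substitutions
still guarantees ≥ 8 seeds, while isolated random 5-mers are noise). Each
cluster window is aligned with edlib (infix mode) and the edit path is
re-clipped to its maximum-scoring local segment under match +1 / mismatch −2
/ gap −3. Edit-distance-optimal paths occasionally trade two mismatches for
an indel pair, which scores worse locally; when a path contains indels an
exhaustive ungapped per-diagonal scan of the window recovers the proper
local optimum. Reported hits need ≥ 16 aligned columns (`min_primerlen`) at
≥ 0.8 identity (`min_identity`; the identity floor is this package's own
declared threshold — chosen so primers survive realistic consensus-read
error rates while random 16-mers do not — and is exposed in the config).

Strand symmetry is structural: the read and its reverse complement are both
scanned and the mirrored hit sets merged (duplicate spans keep the higher
local score), so `find_primer_hits(revcomp(read))` is exactly the mirror of
`find_primer_hits(read)`.

Overlap resolution is greedy and deterministic: hits overlapping by more
than `max_overlap` (5) bases conflict; more matches win, then higher
identity, then the leftmost start.

## Segmentation, classification, extraction

Consecutive resolved hits delimit segments; every inter-primer interval with
interior ≥ `min_seqlen` (50) bases becomes a segment, and shorter residues
(junction bases between back-to-back primers) are assigned to neither
neighbour. Classification:

- **FLNC** — proper opposite-strand terminal pair, poly(A) tail present,
  28 bp barcode+UMI block present, trimmed transcript ≥ 50 bp. A segment
  flanked by a read end (`NONE`) is never FLNC: its full-length status
  cannot be certified even if the visible terminal is a proper primer.
- **ARTIFACT** — neither a 3′-primer terminal nor a poly(A) signal.
- **NFL** — everything else. A truncated barcode block or a poly(A)-only
  segment (flagged `polya_only`) lands here, not in ARTIFACT, because one of
  the two signals is present.

Extraction re-expresses the segment on the strand where its 3′ primer reads
forward: the first 16 bases are the raw cell barcode, the next 12 the raw
UMI (base qualities carried along; reads without qualities are assigned a
uniform Phred 30), and the remainder is reverse-complemented to transcript
sense before poly(A) trimming. In the degenerate case of a segment flanked
by two inward 3′ primers the left one wins, deterministically.

### Poly(A) trimming

From the 3′ end, the trimmed tail is the longest suffix in which every
window of 10 bases is ≥ 80% A (suffixes shorter than the window are judged
as one window of their own length), retracted so the tail starts on an A.
Defaults — window 10, A-fraction 0.8, minimum accepted tail 10 — are this
package's declared values for an otherwise under-specified "sliding window"
step, recorded in run output. The search is capped at the 50 bases upstream
of the UMI block (`polya_search_limit`) so genuinely A-rich transcript
interiors are not consumed. Tails shorter than `min_polya_len` are reported
but do not count as a poly(A) signal.

## Barcode correction

Exact whitelist matches are confirmed unchanged. Otherwise candidates are
whitelist barcodes at Hamming distance exactly 1 (substitutions only —
indel-corrupted barcodes deliberately fall to UNASSIGNED). For candidate `c`
differing at position `i`:

```
score(c)     = prior(c) · ε(q_i),      ε(q) = 10^(−q/10)
prior(c)     = (counts[c] + 1) / Σ_{c'} (counts[c'] + 1)
posterior(c) = score(c) / Σ score
```

`counts` are whitelist exact-match frequencies computed on the same record
set being corrected (after the optional read-QV cut, when one is applied —
the ordering is recorded here as the package's choice). The +1 pseudocount
lets a never-observed true barcode be rescued. The argmax candidate is
assigned only when its posterior exceeds 0.975; ties at the maximum cannot
clear that threshold and resolve to UNASSIGNED. Records may additionally be
restricted to read-level QV ≥ 0.95 (`read_qv_cutoff`), the regime in which
consensus reads are reliably assignable.

## UMI filtering and deduplication

A UMI observation fails if it is a homopolymer, contains N, or has any base
below Q10. Within a (cell, feature) group UMIs are processed in descending
read count (ties: lexicographically ascending); each UMI at Hamming
distance 1 from an already-accepted UMI merges into the first such neighbour
in processing order, counts adding. Survivors are mutually at distance ≥ 2,
so the operation conserves total counts and is idempotent. Matrix entries
count distinct corrected UMIs, which makes the count-add vs.
collapse-to-presence readings equivalent at the matrix level.

## Count matrices

Gene counting keeps records whose class code is in the exonic set
`{=, c, k, m, n, j, e, o}` (the convention of droplet cell-calling
pipelines); an exonic record without a gene id is a hard error (corrupt
assignment table), as is a duplicated (read, segment) row. The isoform
matrix applies the same exonic filter, then drops (cell, isoform) entries
with fewer than 3 distinct UMIs and isoforms detected in fewer than 5 cells.
Features and cells are ordered lexicographically; output is Matrix Market
triplets (1-based) with `features.tsv` / `barcodes.tsv` sidecars and a
per-cell summary JSON.

Feature assignment itself (alignment, isoform collapsing, class-code
computation) is out of scope: the pipeline consumes a per-record
feature-assignment table (read id, segment index, gene, isoform, class
code). The simulator emits this table as ground truth with class code `=`.

## Simulator

The generator's defaults are the study conditions: 20,000 reads, 3–4 units
per read, 1,000-barcode whitelist, 200 cells, substitution rate 0.005 and
indel rates 0.001 per base (the high-accuracy consensus regime), artifact
fraction 0.08 (the low TSO-artifact regime of a capture-based protocol;
~0.5 emulates a protocol without artifact removal), transcript lengths
normal(500, 150) clipped at 100 (desk-scale transcripts that keep runtime
modest while preserving structure), poly(A) lengths normal(30, 5) clipped at
12, spike-in fraction 0.01.

Per-base qualities are `−10·log10(max(sub_rate, 1e−4))` with ±2 jitter, so
the correction posterior sees realistic quality semantics; the read-level QV
is one minus the realised error fraction. One seeded generator drives the
entire run, making output byte-identical for equal seeds. Truth tables carry
each unit's span in post-error read coordinates, and evaluation pairs
records with truth units by maximal coordinate overlap, so a single missed
primer cannot shift the pairing of later units.

What the generator deliberately emulates — and what it does not:

- **Whitelist spacing.** Synthetic whitelist barcodes are mutually ≥ 3
  substitutions apart, so single-substitution correction is
  information-theoretically unambiguous and pipeline error is isolated from
  whitelist ambiguity. The spike-in barcode (`AAGTCCTTCCAGTCTT`, excluded
  from the whitelist but at edit distance 1 from one member) deliberately
  violates this to probe the correction's failure mode.
- **Primer-free inserts.** Transcripts are rejection-sampled to contain no
  internal primer-like stretch (≥ 16 bp at ≥ 75% local identity), and
  whitelist barcodes whose in-read context (revcomp(bc)+revcomp(p3)) mimics
  a primer are redrawn. Real libraries satisfy this by construction of the
  chemistry; without it a few percent of random units would be split by
  legitimate-looking spurious hits, which is a property of the sequences,
  not of the segmenter. TSO-artifact inserts are drawn from the same
  screened isoform pool (artifacts are barcode-free cDNA).
- **Identifiable tail boundaries.** Transcript 3′ ends draw their last
  three bases from {C, G, T}: a transcript ending in A fuses seamlessly
  with its poly(A) tail, making the boundary unidentifiable for any
  trimmer. On real data the reported poly(A) length is accordingly only
  exact up to this ambiguity.
- **Not modelled:** instrument noise structure (pass-number-dependent error,
  homopolymer bias), chimera formation beyond configured TSO artifacts,
  unequal cell sizes, ambient RNA. Passing tests therefore demonstrate
  correctness of the segmentation/correction/counting logic under the
  declared error model, not robustness to every real-data pathology.

## Evaluation definitions

Confusion matrix (printed in the report header): positives are spike-in
truth units among scored records; TP = spike units assigned the spike
barcode; FN = spike units assigned otherwise or unassigned (a flag can
exclude unassigned spike units instead); FP = non-spike units assigned the
spike barcode; TN = the rest. Accuracy = (TP+TN)/all, specificity =
TN/(TN+FP), sensitivity = TP/(TP+FN).

**Per-barcode assignment accuracy** is the fraction of assigned FLNC units
whose corrected barcode equals the truth barcode, computed over units whose
true barcode is assignable (on the whitelist). Spike-in units are excluded
by default and scored by the confusion matrix instead: their barcode is
deliberately absent from the whitelist, and under the posterior rule a
clean spike-in observation has a single Hamming-1 candidate with posterior
1.0, so it is confidently — and unavoidably — corrected to the planted
neighbour. Folding that designed failure mode into the accuracy of
assignable units would measure the spike-in design, not the correction;
`include_spike=True` folds it in for anyone who wants the strict reading.

## Numerical and determinism notes

- Greedy tie-breaks everywhere are total orders (scores, then lexicographic
  keys), so identical inputs give identical outputs.
- Posterior normalisation is over ≤ 48 candidates; sums are exact to 1e−12.
- The acceptance run (`scripts/acceptance.py`) uses 20,000 reads (≈ 70,000
  units) — the scale at which binomial noise on a 99.99% bound is ≤ a few
  units — and finishes in a few minutes on one CPU.

## Known limitations

- Concatemers with a fully deleted internal primer merge two units into one
  segment; no transcript-level rescue is attempted.
- 2-substitution barcode errors are unrecoverable by design (Hamming-1
  correction); they surface as UNASSIGNED, not as mis-assignments, given a
  distance-3 whitelist.
- The poly(A)-window parameters are declared, not fitted; extremely A-rich
  3′ UTRs will be over-trimmed on real data.
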