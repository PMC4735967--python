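# seqsanitize

Unified quality control, format conversion and read cleaning for Sanger
and next-generation sequencing data.

Clinical and targeted-sequencing studies routinely combine traditional
Sanger capillary sequencing with one or more NGS platforms (Illumina,
454, Ion Torrent): NGS screens many samples cheaply, Sanger confirms
candidate variants. Each platform emits its own raw format —
chromatograms in AB1 (ABIF) or SCF, flowgrams in SFF, text reads in
FASTA+QUAL or FASTQ with either Phred+33 or legacy Phred+64 quality
encoding — and each has its own failure modes. Before any variant can be
trusted, every read set needs the same treatment: conversion to one
common representation, removal of synthetic sequence (barcodes, PCR
primers, sequencing adapters), removal of artifact reads (PCR
duplicates, low-complexity junk, low-quality tails), and an auditable
per-sample QC report. `seqsanitize` does all of this for a whole cohort
in one run, from a single tab-separated sample sheet, and emits
Sanger-encoded (Phred+33) FASTQ that downstream mutation-screening or
assembly pipelines can consume directly.

## What it computes

**Quality model.** Per-base qualities are Phred scores,
q = −10·log₁₀(p_error), carried as integers in [0, 93] and encoded in
FASTQ as `chr(q + 33)`. Legacy Phred+64 input is detected from the
minimum quality character code m over the first 10⁴ reads (m < 64 forces
Phred+33, since codes 59–63 are illegal in Phred+64 data) and converted
losslessly.

**Ambiguous base-call refinement (Sanger).** Capillary base callers emit
`N` where the trace signal is unclear, even when the chromatogram shows
exactly two competing dye peaks. At each `N`, the four channel signals
at that base's peak position are compared; every channel with signal
≥ r·S₁ (S₁ the strongest channel, ratio threshold r = 0.5 by default)
is *competing*, and the call becomes the IUPAC code of the competing
set: {A,G} → `R`, {C,T} → `Y`, three-base sets → `B/D/H/V`, all four or
no signal → `N`.

**Adapter/primer trimming.** Mismatch-tolerant ungapped matching:
candidate offsets are seeded by exact k-mer hits (k = 10), extended to a
full alignment, and 3′-terminal partial occurrences of the adapter
prefix (read-through) down to 5 bp are also scored. An alignment of
length a against an adapter of length A is accepted with at most
⌈max_mismatch · a / A⌉ mismatches (max_mismatch = 2). A primer anchored
within the first 3 bases clips the 5′ end; any adapter match clips from
the match to the 3′ end.

**Duplicate and low-complexity filtering (NGS).** Duplicates are removed
in one streaming pass keeping the first occurrence — exact sequence
match, 5′-prefix match and reverse-complement match are selectable
modes; paired reads are keyed on the concatenation of both mates.
Low complexity is scored on overlapping 3-mers: the DUST statistic
100 · Σ cₜ(cₜ−1)/2 ÷ [(L−2)(L−3)/2] (homopolymer = 100, fails above 7)
or normalized Shannon entropy (homopolymer = 0, fails below 30).

**End trimming and read filtering.** Terminal `N` runs are removed and
each end is trimmed while the mean quality of the terminal window
(5 bases) is below Q20, reflecting the growth of sequencing error with
position in the read. Reads then must satisfy mean quality, length and
complexity thresholds; every removal is attributed to the first failed
criterion, so kept + removed-per-criterion = input, always.

**Paired-end consistency.** If one read of a pair is lost at any stage,
its mate is excluded too: the R1 and R2 outputs always contain the same
reads in the same order.

## Worked example

The package's `fixtures` module generates valid files in every supported
format with planted ground truth, so a complete demonstration needs no
external data. Given a pooled, barcoded 454-style run shared by two
patients plus three AB1 traces for a third:

```
Patient_ID  Platform  Read1         Traces                         MID       Demultiplexed  Diagnosis
patientA    454       pooled.fastq                                 ACGTAACC  no             case
patientB    454       pooled.fastq                                 TGCATTGG  no             control
patientC    sanger              trace00000.ab1;trace00001.ab1;...                           control
```

```sh
seqsanitize run --target target.tsv --adapters adapters.tsv --out qc_out
```

prints

```
INFO seqsanitize.pipeline: demultiplexed pooled.fastq: {'patientA': 90, 'patientB': 90, 'unassigned': 20}
INFO seqsanitize.pipeline: sample patientA (454): 90 -> 90 reads
INFO seqsanitize.pipeline: sample patientB (454): 90 -> 90 reads
INFO seqsanitize.pipeline: sample patientC (sanger): 3 -> 3 reads
summary: qc_out/summary.html
```

and `qc_out/summary.tsv` holds one row per patient:

```
patient_id  reads_before  reads_after  gc_before  gc_after  status
patientA    90            90           50.33      50.17     ok
patientB    90            90           50.66      50.43     ok
patientC    3             3            50.67      50.67     ok
```

Reading the numbers: the 200-read pool split into 90 + 90 + 20 reads
(20 carried neither barcode — they land in the `unassigned` bin rather
than being guessed into a patient); all demultiplexed reads survived
cleaning, and the slight GC shift (50.33 → 50.17) is the planted
TruSeq-style adapter being trimmed off. Each patient also gets
`<id>.fastq` (Phred+33), a before/after QC report
(`<id>_qc.html` + TSV sidecars with per-position quality quartiles,
length histogram, duplication levels and overrepresented sequences),
and `effective_options.txt` records the full configuration so the run
can be reproduced from its own output directory.

The stages are also available individually (`seqsanitize convert`,
`demux`, `trim`, `filter`, `stats`) and as library functions
(`seqsanitize.read_chromatogram`, `refine_ambiguous_calls`,
`locate_adapter`, `filter_duplicates`, `complexity_score`,
`synchronize_pairs`, …).

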