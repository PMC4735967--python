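# Methods

This note documents the models, rules and numerical choices behind
`seqsanitize`, the assumptions they rest on, and what the synthetic test
data does and does not establish about behaviour on real instruments.

## Input model and conversion

A read is an identifier, an upper-case IUPAC base string, one Phred
quality integer per base (clamped into [0, 93], the Sanger-encodable
range) and a pair role. All platform formats are mapped onto this one
container at the conversion boundary; everything downstream is
platform-agnostic except where the stage flow says otherwise.

* **ABIF (AB1).** The directory is parsed per the public ABIF layout
  (big-endian, 28-byte entries, payloads ≤ 4 bytes stored inline in the
  offset field). The *base-caller's* entries are used — `PBAS.1`,
  `PCON.1`, `PLOC.1`, traces `DATA.9–12` in `FWO_.1` channel order —
  not the user-edited tag-number-2 copies, because the pipeline's job is
  to audit the instrument's calls, not an analyst's later edits. A file
  lacking `PBAS.1`/`PCON.1` is an error: inventing qualities would be
  worse than failing loudly. Files lacking trace or peak entries still
  convert; they simply skip call refinement.
* **SCF.** Version ≥ 3.00 only (the long-standing Staden layout;
  sample data double-delta decoded with two cumulative sums modulo the
  sample word size). Per-base quality is taken from the probability
  array of the called channel, and for ambiguous calls from the best
  supported channel. Older SCF v2 interleaving is rejected with a clear
  error rather than half-supported.
* **SFF v1.** Big-endian, flowgram format code 1; the index block is
  skipped. Clip coordinates are preserved verbatim on the record
  (1-based, 0 = absent) and applied at conversion time as the stricter
  combination: left = max of quality/adapter left clips, right = min of
  the non-zero right clips. Vendor clips encode instrument knowledge
  the pipeline cannot reconstruct, so they are honored before any of
  the package's own trimming.
* **FASTQ.** The encoding is inferred from the minimum quality
  character code m over the first 10,000 reads: m < 64 forces Phred+33
  (codes 59–63 cannot occur in well-formed Phred+64 data). When every
  code is ≥ 64 the file is treated as legacy Phred+64 and the decision
  is logged — uniformly high-quality Phred+33 data is possible but much
  rarer than legacy files, and the probe covers 10⁴ reads. This is the
  one heuristic in the reader layer; everything else is deterministic
  structure. One consequence worth knowing: a synthetic file whose
  every base is exactly Q31+ at offset 33 will be mis-read as Phred+64,
  so test fixtures use quality models whose codes dip below 64.
* **Output** is always Phred+33 FASTQ; qualities above 93 are clamped
  to 93 with a logged warning (lossy but auditable, and preserves the
  read).

One trace file is one read; multi-read chromatogram containers are not
a thing in AB1/SCF practice and are not supported.

## Ambiguous-call refinement

The trace re-examination stage answers one question per `N`: which
channels are actually competing at that peak? With signals S₁ ≥ S₂ ≥ S₃
≥ S₄ at the called base's peak index, the competing set is every channel
with signal ≥ r·S₁. The IUPAC code of that set replaces the call; its
quality value is untouched, and read length never changes.

* `ratio_threshold` r defaults to 0.5: a secondary peak at half the
  primary height is the classic visual criterion for a real secondary
  signal, and values much lower start promoting baseline noise into
  ambiguity codes. At r = 1.0 (with distinct signals) every `N` becomes
  the argmax base.
* Scope defaults to `n_only`. Re-calling confident bases
  (`all_positions`) is opt-in, because overriding a base caller's
  high-confidence calls with a single-sample ratio rule is aggressive.
* The signal is read at the single peak sample, not a window average —
  the simplest defensible rule, and the synthetic traces the tests use
  are clean Gaussians where windowing changes nothing. On noisy real
  chromatograms a windowed variant may be preferable; that is a known
  limitation, and this rule is a transparent stand-in for proprietary
  trace re-callers rather than a reimplementation of any of them.
* All-zero signal leaves `N` in place; missing trace data raises a
  contract error so the caller skips refinement instead of silently
  passing calls through a no-op.

## Demultiplexing

Barcodes (MIDs) are anchored at the 5′ end of the (forward) read.
Assignment computes the Hamming distance between each MID and the read
prefix of equal length, with `N` counting as a mismatch. With
mixed-length MID sets the longest length is tried first (454 MID sets
vary in length, and a longer exact match is strictly more specific);
within a length the unique minimum-distance candidate within
`max_mismatch` wins. Any tie leaves the read unassigned — in a clinical
context putting a read in the wrong patient's file is strictly worse
than discarding it. The default `max_mismatch` is 0.

MID tables are validated at load: duplicate MIDs are fatal; equal-length
MIDs closer than 2·max_mismatch + 1 in Hamming distance are flagged as
inseparable at that tolerance (assignment then relies on the tie rule).

For paired-end input the barcode is read from the forward mate only and
the reverse mate follows its partner's bin; dual indexing is out of
scope. In the cohort runner, demultiplexing is a serial pre-pass over
groups of manifest rows that share a pooled input file; after the split,
samples are fully independent, which is what makes worker-count
invariance trivial to guarantee.

## Adapter and primer trimming

Matching is ungapped by design: an exact, enumerable rule that a
brute-force all-offsets oracle can verify bit-for-bit. Indel-tolerant
trimming would be more sensitive on 454/Ion homopolymer errors and is
deliberately future work.

* Full-length candidate offsets come from exact k-mer seeding (k = 10,
  every adapter k-mer indexed). By pigeonhole, an occurrence with m
  substitutions is guaranteed a seed when the feature is at least
  (m+1)·k long — with the default budget of 2 that means features of
  ≥ 30 bp (typical sequencing adapters and long PCR primers qualify).
  Features shorter than k fall back to scanning every offset.
* 3′-terminal partial occurrences of the adapter *prefix* (read-through
  into the adapter) are enumerated exhaustively down to `min_overlap`
  = 5 bases.
* The mismatch budget scales with aligned length: ⌈max_mismatch · a /
  A⌉ for an a-long alignment of an A-long adapter, so short overlaps
  are not charged the full-length allowance. Fewest mismatches wins,
  ties go leftmost. `N` in the read is always a mismatch.
* A *primer* match anchored within the first 3 bases clips the 5′ end
  to the match end; any *adapter* match clips from its start to the 3′
  end. Forward/single reads are searched with each feature's forward
  sequence plus the reverse complement of its reverse sequence; reverse
  mates see the mirror image (their 5′ end starts with the reverse
  primer). The cascade repeats until nothing matches, at most 3 rounds,
  which removes stacked features (barcode remnants, double
  read-through).

A 5-base overlap at a 1-mismatch budget will occasionally fire on insert
sequence that merely resembles the adapter start — an irreducible
property of overlap-based trimming shared by every tool in this family,
at a rate of about 1–2 % per read end for random sequence. The planted-
truth tests therefore reject candidate inserts that themselves match a
feature under the active parameters: such constructs have no
well-defined truth for *any* trimmer, so including them would test the
generator, not the matcher.

End trimming afterwards: terminal `N` runs are removed (interior `N`s
kept — they carry positional information), then each end is eroded while
the mean quality of the terminal window (min(window, remaining length),
window = 5) is below `q_trim` = 20. Window 1 reduces to the per-base
rule; the procedure is a deterministic fixed point and never touches
interior low-quality bases.

## Duplicate and low-complexity filtering

Both screens are NGS-only stages: PCR duplicates are a library-
preparation artifact, and three Sanger traces from one patient are
routinely the *same* amplicon on purpose. Duplicate scope is per sample,
after demultiplexing, because duplicates are library-specific.

Duplicate detection streams once, keeping the first occurrence —
deterministic under streaming, and read order in instrument output is
informative (first = earliest cluster). Retention-by-best-quality would
require buffering the whole stream and is documented as a possible
option rather than implemented. Modes (combinable): identical base
string; 5′ prefix of an already-kept longer read; reverse complement of
a kept read. The prefix screen stores all prefixes of kept reads in a
hash set — memory O(total kept bases), which is fine at the
amplicon/targeted scale this tool addresses and is the price of exact
streaming semantics. Pairs are keyed on the concatenation of both
mates.

Low-complexity ("contamination") screening is 3-mer based, on a 0–100
scale:

* DUST: 100 · Σₜ cₜ(cₜ−1)/2 ÷ [(L−2)(L−3)/2] over the L−2 overlapping
  3-mers; a homopolymer scores exactly 100, a sequence with all-distinct
  3-mers exactly 0. Fails above 7.
* Entropy: Shannon entropy of the 3-mer distribution, normalized by
  log(min(L−2, 64)), scaled to 0–100; fails below 30.

Reference-based contaminant screening (against vectors or foreign
genomes) is explicitly out of scope; "contamination" here means the
low-complexity junk that sequence-intrinsic screens can catch.

## Read filtering and accounting

The final filter keeps a read iff mean quality ≥ `min_mean_q` (20),
`min_len` ≤ length ≤ `max_len`, and the complexity screen passes.
Criteria are checked in that fixed order and the first failure is
recorded, giving exact conservation: kept + Σ removed-per-criterion =
input, which the QC layer asserts per sample. Length defaults differ by
platform — 50 for short reads, 100 for Sanger, where a shorter trace
indicates a failed reaction. An empty read reports `min_len`.

## Paired-end consistency

Mate ids are normalized by stripping `/1`/`/2` and space-delimited
Casava suffixes (the two dominant dialects). After per-side cleaning,
exactly the pairs whose both mates survived are emitted, in original
order, so the R1 and R2 id sequences are identical — the invariant that
mapping and assembly tools downstream depend on. Duplicate ids within
one side are an error, not silently resolved.

## QC statistics and reports

All statistics accumulate in one streaming pass: per-position quality
histograms (position × quality counts; quartiles by nearest rank on the
histogram, which is exact and needs no buffering), read-length
histogram, duplication levels (copy-number → distinct sequences, capped
at 500,000 tracked distinct sequences), overrepresented sequences
(> 0.1 % of reads, top 20 listed) and GC content. GC is the per-read
percentage averaged over reads, counting S (G-or-C) as GC and W (A-or-T)
as AT, with all other ambiguity codes and `N` excluded from the
denominator — maximal use of the information in the call without biasing
toward either composition. An empty stream reports GC 0 with an explicit
flag.

Reports are standalone HTML with a "before" and an "after" section plus
tab-separated sidecars carrying the identical numbers; the renderer
formats `QCStats` fields and derives nothing itself, so report and
statistics cannot disagree. The cohort summary has one row per manifest
sample (failed samples included, marked), with manifest extras carried
verbatim.

## Orchestration

The target file is the single source of cohort structure: mandatory
unique `Patient_ID`, platform (inferred from file content when absent),
paths, optional MID and demultiplexed flag, and arbitrary extra columns
preserved into the summary. The options file is a flat `key = value`
schema with dotted namespaces; unknown keys are fatal (they are almost
always typos), omitted keys take defaults, and the effective
configuration is echoed next to the outputs so any run can be reproduced
from its own output directory — the echo file round-trips through the
parser to an identical run.

Stage order per platform: Sanger reads go basecall-refine → convert →
primer/adapter trim → N/quality trim → filter; NGS reads go convert →
demultiplex → trim → duplicate filter → complexity filter → N/quality
trim → filter → pair-synchronize. Samples run independently (thread
pool, `workers` configurable); results are collected in manifest order
and per-sample outputs never interact, so outputs are byte-identical
across worker counts. A failing sample is marked failed in the summary
and the rest of the cohort completes; the CLI exits non-zero if any
sample failed.

## Synthetic data: what it shows and what it does not

The fixtures module emulates the properties each stage actually
consumes: seeded random inserts; linearly 3′-decaying quality (the
dominant real error pattern) with Gaussian jitter, clipped to [0, 60];
barcodes/primers/adapters planted at recorded positions with recorded
per-copy substitution counts; chromatogram traces as clean Gaussian
peaks (height 1000, configurable secondary heights for planting
ambiguities); SFF flows synthesized on the standard TACG cycle at 100
units per incorporated base. Format writers are implemented from the
public specifications and share no code with the readers, so round-trip
equality checks two independent implementations against each other —
additionally, the SFF fixtures are cross-read with Biopython's parser
in the test suite as a third-party referee.

Not modelled, and therefore not established by the passing tests: dye
blobs, baseline noise and peak-spacing drift in chromatograms;
homopolymer flow-value noise in SFF (flows are exact multiples of 100);
sequencing-error substitutions outside planted features; quality-model
miscalibration. The pipeline's behaviour on such data follows from the
rules above, but the tests quantify correctness only on the planted
properties. Problem sizes in the test suite and the acceptance script —
1,000 records per format round-trip, 10,000 reads demultiplexed, 1,000
trimming constructs, 5,000 filter reads, a 10-sample mixed cohort — are
the package's chosen verification scale: large enough that rare-event
paths (ties, boundary lengths, collisions) are exercised, small enough
to run routinely.

## Known limitations

* Ungapped adapter matching; no indel tolerance.
* No dual-index demultiplexing; barcode on the forward mate only.
* The ambiguity-refinement rule is a transparent stand-in, not a
  statistically calibrated heterozygote caller; no quality
  re-estimation is done at refined positions.
* Reference-based contamination screening and RNA-seq-specific handling
  are out of scope.
* AB1 files lacking `PCON.1` are rejected rather than given invented
  qualities.
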