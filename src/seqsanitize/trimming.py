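"""Adapter/primer removal and end trimming.

Three independent trimming operations, applied in cascade by the
pipeline:

1. **Adapter / primer trimming** — mismatch-tolerant, ungapped matching
   of known feature sequences.  Candidate positions come from exact
   k-mer seeds between adapter and read; each seed is extended to a full
   ungapped alignment, and partial occurrences of the adapter's prefix
   hanging off the 3' end of the read (read-through into the adapter)
   are also considered down to ``min_overlap`` bases.  A primer found at
   the very start of a read clips the 5' end; an adapter match removes
   everything from the match to the 3' end.
2. **Terminal N trimming** — leading/trailing runs of ``N`` are removed;
   interior Ns stay.
3. **Quality end trimming** — bases are dropped from each end while the
   mean quality of the terminal window falls below the threshold,
   reflecting the position-dependent error growth of sequencing reads.

Matching is ungapped by design: it keeps behaviour exactly checkable
against a brute-force all-offsets oracle.  Indel-tolerant trimming is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional

from .errors import ContractError
from .records import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class AdapterSpec:
    """One adapter or primer from the adapter-primer table.

    Either orientation's sequence may be empty, but not both.
    """

    feature_type: str  # "adapter" | "primer"
    feature_id: str
    forward_seq: str = ""
    reverse_seq: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in ("adapter", "primer"):
            raise ContractError(
                f"feature {self.feature_id!r}: type must be adapter or primer, "
                f"got {self.feature_type!r}"
            )
        if not self.forward_seq and not self.reverse_seq:
            raise ContractError(
                f"feature {self.feature_id!r}: both sequences empty"
            )
        for seq in (self.forward_seq, self.reverse_seq):
            bad = set(seq) - set("ACGT")
            if bad:
                raise ContractError(
                    f"feature {self.feature_id!r}: non-ACGT characters {sorted(bad)}"
                )


@dataclass
class TrimParams:
    """Tunable trimming parameters.

    kmer:
        Seed length for adapter matching (default 10).  Seeding finds any
        occurrence with m mismatches provided the adapter is at least
        ``(m + 1) * kmer`` long (pigeonhole); shorter features fall back
        to scanning every offset.
    max_mismatch:
        Mismatches allowed across a full-length adapter alignment
        (default 2); scaled proportionally for partial 3' overlaps.
    min_overlap:
        Minimum length of a 3'-terminal partial adapter occurrence
        (default 5).
    q_trim:
        Phred threshold for quality end trimming (default 20).
    window:
        Terminal window size for quality trimming (default 5).
    """

    kmer: int = 10
    max_mismatch: int = 2
    min_overlap: int = 5
    q_trim: int = 20
    window: int = 5
    max_rounds: int = 3

    def __post_init__(self) -> None:
        if self.kmer < 4:
            raise ContractError("kmer must be >= 4")
        if self.min_overlap < 1:
            raise ContractError("min_overlap must be >= 1")
        if not (0 <= self.q_trim <= 93):
            raise ContractError("q_trim must be in [0, 93]")


@dataclass(frozen=True)
class AdapterMatch:
    """An ungapped occurrence: 0-based half-open read coordinates."""

    start: int
    end: int
    mismatches: int


def _count_mismatches(read: str, offset: int, feature: str, length: int,
                      budget: int) -> int:
    """Mismatches of ``feature[:length]`` against ``read[offset:offset+length]``.

    Ns in the read always count as mismatches.  Stops early once over
    ``budget`` (returns ``budget + 1``).
    """
    mm = 0
    for i in range(length):
        if read[offset + i] != feature[i]:
            mm += 1
            if mm > budget:
                return mm
    return mm


def locate_adapter(read_bases: str, adapter: str,
                   params: Optional[TrimParams] = None) -> Optional[AdapterMatch]:
    """Best ungapped occurrence of ``adapter`` in ``read_bases``, or None.

    Full-length alignments are seeded by exact k-mer hits (every adapter
    k-mer is indexed); 3'-terminal partial occurrences of the adapter's
    prefix of length >= ``min_overlap`` are enumerated exhaustively.  The
    mismatch budget for an alignment of length ``a`` is
    ``ceil(max_mismatch * a / len(adapter))``.  The accepted match with
    the fewest mismatches wins; ties go to the leftmost.
    """
    params = params or TrimParams()
    if not adapter:
        raise ContractError("locate_adapter called with empty adapter")
    read = read_bases.upper()
    adapter = adapter.upper()
    L, A = len(read), len(adapter)
    k = params.kmer

    offsets: set[int] = set()
    if A <= L:
        if A < k:
            offsets.update(range(L - A + 1))  # too short to seed: scan all
        else:
            seed_pos: dict[str, list[int]] = {}
            for i in range(A - k + 1):
                seed_pos.setdefault(adapter[i:i + k], []).append(i)
            for j in range(L - k + 1):
                for i in seed_pos.get(read[j:j + k], ()):
                    off = j - i
                    if 0 <= off <= L - A:
                        offsets.add(off)

    candidates: list[tuple[int, int, int]] = []  # (mismatches, start, length)
    for off in offsets:
        budget = params.max_mismatch
        mm = _count_mismatches(read, off, adapter, A, budget)
        if mm <= budget:
            candidates.append((mm, off, A))

    # partial 3'-terminal overlap with the adapter's prefix
    lo = max(0, L - A + 1)
    for off in range(lo, L - params.min_overlap + 1):
        length = L - off
        budget = ceil(params.max_mismatch * length / A)
        mm = _count_mismatches(read, off, adapter, length, budget)
        if mm <= budget:
            candidates.append((mm, off, length))

    if not candidates:
        return None
    mm, start, length = min(candidates, key=lambda c: (c[0], c[1]))
    return AdapterMatch(start=start, end=start + length, mismatches=mm)


#: Maximum 0-based start position at which a primer counts as 5'-anchored.
PRIMER_ANCHOR = 3


def _oriented_features(specs: Iterable[AdapterSpec],
                       orientation: str) -> list[tuple[str, str]]:
    """(feature_type, sequence) pairs to search for a given read orientation.

    Forward/single reads are searched with each feature's forward
    sequence and the reverse complement of its reverse sequence; reverse
    mates see the mirror image.
    """
    out = []
    for spec in specs:
        if orientation == "reverse":
            seqs = [spec.reverse_seq,
                    reverse_complement(spec.forward_seq) if spec.forward_seq else ""]
        else:
            seqs = [spec.forward_seq,
                    reverse_complement(spec.reverse_seq) if spec.reverse_seq else ""]
        for s in seqs:
            if s:
                out.append((spec.feature_type, s.upper()))
    return out


def trim_adapters_primers(
    record: SequenceRecord,
    specs: Iterable[AdapterSpec],
    params: Optional[TrimParams] = None,
    orientation: Optional[str] = None,
) -> SequenceRecord:
    """Remove primer and adapter occurrences from a read.

    A primer match whose start lies within the first ``PRIMER_ANCHOR``
    bases clips the 5' end up to the match end; any adapter match clips
    from its start to the 3' end.  Qualities are trimmed in lockstep.
    The search repeats until nothing more matches (at most
    ``params.max_rounds`` rounds), so stacked or read-through features
    are removed too.
    """
    params = params or TrimParams()
    orientation = orientation or record.pair_role
    features = _oriented_features(specs, orientation)
    if not features:
        return record

    current = record
    for _ in range(params.max_rounds):
        changed = False
        # 5' primer clip first: an anchored primer hides the true insert start
        best_primer = None
        for ftype, seq in features:
            if ftype != "primer":
                continue
            m = locate_adapter(current.bases, seq, params)
            if m is not None and m.start <= PRIMER_ANCHOR:
                if best_primer is None or (m.end, -m.mismatches) > (
                        best_primer.end, -best_primer.mismatches):
                    best_primer = m
        if best_primer is not None and best_primer.end > 0:
            current = current.slice(best_primer.end, len(current))
            changed = True
        # 3' adapter clip: everything from the leftmost best match onward
        best_adapter = None
        for ftype, seq in features:
            if ftype != "adapter":
                continue
            m = locate_adapter(current.bases, seq, params)
            if m is not None:
                if best_adapter is None or (m.mismatches, m.start) < (
                        best_adapter.mismatches, best_adapter.start):
                    best_adapter = m
        if best_adapter is not None:
            current = current.slice(0, best_adapter.start)
            changed = True
        if not changed or len(current) == 0:
            break
    return current


def trim_terminal_ns(record: SequenceRecord) -> SequenceRecord:
    """Strip leading and trailing runs of ``N`` (interior Ns are kept)."""
    bases = record.bases
    start = 0
    while start < len(bases) and bases[start] == "N":
        start += 1
    stop = len(bases)
    while stop > start and bases[stop - 1] == "N":
        stop -= 1
    if start == 0 and stop == len(bases):
        return record
    return record.slice(start, stop)


def trim_quality_ends(record: SequenceRecord, q_trim: int = 20,
                      window: int = 5) -> SequenceRecord:
    """Drop low-quality stretches from both read ends.

    From the 3' end, the terminal base is removed while the mean quality
    of the last ``min(window, length)`` bases is below ``q_trim``; the 5'
    end is then treated symmetrically.  The result is a deterministic
    fixed point; interior low-quality bases are never touched.
    """
    quals = record.quals
    start, stop = 0, len(quals)
    while stop > start:
        w = min(window, stop - start)
        if sum(quals[stop - w:stop]) / w < q_trim:
            stop -= 1
        else:
            break
    while stop > start:
        w = min(window, stop - start)
        if sum(quals[start:start + w]) / w < q_trim:
            start += 1
        else:
            break
    if start == 0 and stop == len(quals):
        return record
    return record.slice(start, stop)


def trim_cascade(record: SequenceRecord, specs: Iterable[AdapterSpec],
                 params: Optional[TrimParams] = None,
                 orientation: Optional[str] = None) -> SequenceRecord:
    """Full trimming chain: features, then terminal Ns, then quality ends."""
    params = params or TrimParams()
    rec = trim_adapters_primers(record, specs, params, orientation)
    rec = trim_terminal_ns(rec)
    rec = trim_quality_ends(rec, params.q_trim, params.window)
    return rec
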