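"""Synthetic sequencing data with planted, machine-readable ground truth.

This module manufactures reads and writes them as valid AB1 (ABIF),
SCF v3, SFF v1, FASTA+QUAL and FASTQ files so every pipeline stage can be
exercised against known truth without any external dataset.  The binary
writers are implemented here from the public format specifications and
share no parsing code with :mod:`seqsanitize.seqio` — a round-trip
therefore checks two independent implementations against each other.

The quality model emulates the dominant feature of real base-calling
error: mean quality decays towards the 3' end of the read.  Chromatogram
traces are synthesized as clean Gaussian peaks (one per called base, with
configurable secondary-channel heights for ambiguity planting); dye
blobs, baseline noise and homopolymer flow distortion are deliberately
not modelled.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import ChromatogramRecord, FlowRecord, SequenceRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PlantedFeature:
    """One adapter/primer/barcode occurrence planted into a read."""

    feature_type: str  # "barcode" | "primer" | "adapter"
    feature_id: str
    start: int  # 0-based position in the final read
    end: int
    mismatches: int


@dataclass
class ReadTruth:
    """Everything known about one synthetic read."""

    read_id: str
    insert: str
    insert_quals: list[int] = field(default_factory=list)
    sample_id: Optional[str] = None
    features: list[PlantedFeature] = field(default_factory=list)
    duplicate_group: Optional[int] = None


@dataclass
class TruthTable:
    """Planted ground truth for a batch of synthetic reads."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def add(self, truth: ReadTruth) -> None:
        if truth.read_id in self.reads:
            raise ValueError(f"duplicate truth entry {truth.read_id!r}")
        self.reads[truth.read_id] = truth

    def by_sample(self) -> dict[Optional[str], list[str]]:
        out: dict[Optional[str], list[str]] = {}
        for rid, t in self.reads.items():
            out.setdefault(t.sample_id, []).append(rid)
        return out

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass
class QualityModel:
    """Linear 5'->3' quality decay with Gaussian jitter.

    ``start_mean``/``end_mean`` are the mean Phred values at the first and
    last base; per-base jitter has standard deviation ``sd``.  Values are
    clipped into [0, 60], the realistic base-caller range.
    """

    start_mean: float = 36.0
    end_mean: float = 22.0
    sd: float = 3.0

    def sample(self, length: int, rng: np.random.Generator) -> list[int]:
        means = np.linspace(self.start_mean, self.end_mean, max(length, 1))
        q = rng.normal(means, self.sd)
        return np.clip(np.rint(q), 0, 60).astype(int).tolist()


@dataclass
class LengthModel:
    """Normal read-length model, truncated below at ``minimum``."""

    mean: float = 150.0
    sd: float = 0.0
    minimum: int = 20

    def sample(self, rng: np.random.Generator) -> int:
        if self.sd == 0:
            return max(int(self.mean), self.minimum)
        return max(int(round(rng.normal(self.mean, self.sd))), self.minimum)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_reads(
    n: int,
    length_model: Optional[LengthModel] = None,
    quality_model: Optional[QualityModel] = None,
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate ``n`` random reads plus their truth table.

    Reproducible for a given seed; the insert sequence and qualities of
    every read are recorded in the truth table so that any later
    modification (feature planting, trimming) can be verified against
    them.
    """
    length_model = length_model or LengthModel()
    quality_model = quality_model or QualityModel()
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    truth = TruthTable()
    for i in range(n):
        length = length_model.sample(rng)
        bases = random_sequence(length, rng)
        quals = quality_model.sample(length, rng)
        rid = f"{id_prefix}{i:05d}"
        reads.append(SequenceRecord(read_id=rid, bases=bases, quals=quals))
        truth.add(ReadTruth(read_id=rid, insert=bases,
                            insert_quals=list(quals)))
    return reads, truth


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> tuple[str, int]:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0 or not seq:
        return seq, 0
    n_subs = min(n_subs, len(seq))
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars), n_subs


def plant_features(
    reads: Sequence[SequenceRecord],
    truth: TruthTable,
    barcodes: Optional[dict[str, str]] = None,
    barcode_fraction: float = 0.8,
    primer: Optional[tuple[str, str]] = None,
    adapter: Optional[tuple[str, str]] = None,
    mismatch_rate: float = 0.0,
    max_feature_mismatch: int = 2,
    feature_quality: int = 30,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Plant barcodes / primers / adapters into reads and record the truth.

    ``barcodes`` maps sample id -> MID; a ``barcode_fraction`` share of
    reads (round-robin across samples) gets a barcode prepended, the rest
    stay barcode-free (``sample_id`` None).  ``primer`` / ``adapter`` are
    ``(feature_id, sequence)`` pairs planted at the 5' end (after any
    barcode) and appended at the 3' end respectively.  With
    ``mismatch_rate > 0`` each planted primer/adapter copy receives a
    uniform 0..``max_feature_mismatch`` substitutions (barcodes are always
    planted exactly).  Planted positions and per-copy mismatch counts go
    into the truth table.
    """
    rng = np.random.default_rng(seed)
    sample_ids = sorted(barcodes) if barcodes else []
    out: list[SequenceRecord] = []
    n_barcoded = int(round(barcode_fraction * len(reads))) if barcodes else 0

    for i, rec in enumerate(reads):
        t = truth.reads[rec.read_id]
        parts_b: list[str] = []
        parts_q: list[int] = []
        features: list[PlantedFeature] = []

        def append(seq: str, ftype: str, fid: str, mm: int) -> None:
            start = len(parts_b)
            parts_b.extend(seq)
            parts_q.extend([feature_quality] * len(seq))
            features.append(PlantedFeature(ftype, fid, start, len(parts_b), mm))

        if barcodes and i < n_barcoded:
            sid = sample_ids[i % len(sample_ids)]
            append(barcodes[sid], "barcode", sid, 0)
            t.sample_id = sid
        if primer is not None:
            n_mm = int(rng.integers(0, max_feature_mismatch + 1)) \
                if mismatch_rate > 0 else 0
            seq, mm = _mutate(primer[1], n_mm, rng)
            append(seq, "primer", primer[0], mm)
        insert_start = len(parts_b)
        parts_b.extend(rec.bases)
        parts_q.extend(rec.quals)
        if adapter is not None:
            n_mm = int(rng.integers(0, max_feature_mismatch + 1)) \
                if mismatch_rate > 0 else 0
            seq, mm = _mutate(adapter[1], n_mm, rng)
            append(seq, "adapter", adapter[0], mm)

        t.features = features
        t.insert = rec.bases
        t.insert_quals = list(rec.quals)
        out.append(SequenceRecord(
            read_id=rec.read_id,
            bases="".join(parts_b),
            quals=parts_q,
            pair_role=rec.pair_role,
        ))
        del insert_start
    return out, truth


# ---------------------------------------------------------------------------
# Chromatogram synthesis + AB1 / SCF writers
# ---------------------------------------------------------------------------

#: Trace samples per called base in synthetic chromatograms.
PEAK_SPACING = 8
_PRIMARY_HEIGHT = 1000


def synthesize_traces(
    bases: str,
    channel_order: str = "ACGT",
    channel_heights: Optional[dict[int, dict[str, int]]] = None,
) -> tuple[list[list[int]], list[int]]:
    """Clean Gaussian-peak traces for a base string.

    Each called base gets a Gaussian peak of height 1000 in its own
    channel at evenly spaced positions; ``channel_heights`` overrides the
    per-channel peak heights at selected base positions (used to plant
    ambiguous two- or three-channel signals).  ``N`` calls get no peak
    unless overridden.  Returns ``(traces, peak_index)`` with traces in
    ``channel_order``.
    """
    n = len(bases)
    length = n * PEAK_SPACING + PEAK_SPACING
    traces = [[0] * length for _ in range(4)]
    peak_index = [i * PEAK_SPACING + PEAK_SPACING // 2 for i in range(n)]
    chan_of = {b: i for i, b in enumerate(channel_order)}
    sigma = PEAK_SPACING / 4.0
    for i, base in enumerate(bases):
        heights: dict[str, int] = {}
        if channel_heights and i in channel_heights:
            heights = channel_heights[i]
        elif base in chan_of:
            heights = {base: _PRIMARY_HEIGHT}
        center = peak_index[i]
        for b, h in heights.items():
            chan = chan_of[b]
            for dx in range(-PEAK_SPACING // 2, PEAK_SPACING // 2 + 1):
                x = center + dx
                if 0 <= x < length:
                    traces[chan][x] += int(round(h * math.exp(-(dx * dx) / (2 * sigma * sigma))))
    return traces, peak_index


def write_synthetic_trace(
    record: SequenceRecord,
    format: str,
    path,
    channel_order: str = "ACGT",
    channel_heights: Optional[dict[int, dict[str, int]]] = None,
) -> Path:
    """Write a record as a valid AB1 or SCF v3 trace file.

    Traces are synthesized with :func:`synthesize_traces` unless the
    record already carries them (a :class:`ChromatogramRecord` with
    trace data is written verbatim).
    """
    path = Path(path)
    if isinstance(record, ChromatogramRecord) and record.traces is not None:
        traces, peak_index = record.traces, record.peak_index
        channel_order = record.channel_order
    else:
        traces, peak_index = synthesize_traces(
            record.bases, channel_order, channel_heights)
    if format == "ab1":
        _write_abif(path, record.bases, record.quals, traces,
                    peak_index, channel_order)
    elif format == "scf":
        if channel_order != "ACGT":
            order = {b: i for i, b in enumerate(channel_order)}
            traces = [traces[order[b]] for b in "ACGT"]
        _write_scf(path, record.bases, record.quals, traces, peak_index)
    else:
        raise ValueError(f"unknown trace format {format!r}")
    return path


def _write_abif(path: Path, bases: str, quals: Sequence[int],
                traces: Sequence[Sequence[int]], peak_index: Sequence[int],
                channel_order: str) -> None:
    # ABIF: 128-byte header whose "tdir" entry points at a directory of
    # 28-byte entries; payloads of <= 4 bytes live inline in the offset field.
    tags: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: bytes, number: int, etype: int, esize: int,
            nelem: int, payload: bytes) -> None:
        tags.append((name, number, etype, esize, nelem, payload))

    n = len(bases)
    add(b"PBAS", 1, 2, 1, n, bases.encode("ascii"))
    add(b"PCON", 1, 1, 1, n, bytes(min(max(q, 0), 255) for q in quals))
    add(b"PLOC", 1, 4, 2, n, struct.pack(f">{n}h", *peak_index))
    add(b"FWO_", 1, 2, 1, 4, channel_order.encode("ascii"))
    for i, trace in enumerate(traces):
        add(b"DATA", 9 + i, 4, 2,
            len(trace), struct.pack(f">{len(trace)}h", *trace))

    dir_offset = 128
    data_offset = dir_offset + 28 * len(tags)
    entries = b""
    blob = b""
    for name, number, etype, esize, nelem, payload in tags:
        dsize = len(payload)
        head = struct.pack(">4sihhii", name, number, etype, esize, nelem, dsize)
        if dsize <= 4:
            entries += head + payload.ljust(4, b"\0") + b"\0\0\0\0"
        else:
            entries += head + struct.pack(">ii", data_offset + len(blob), 0)
            blob += payload

    tdir = struct.pack(">4sihhii", b"tdir", 1, 1023, 28, len(tags),
                       28 * len(tags)) + struct.pack(">ii", dir_offset, 0)
    header = b"ABIF" + struct.pack(">h", 101) + tdir
    header = header.ljust(128, b"\0")
    path.write_bytes(header + entries + blob)


def _delta_delta(values: Sequence[int], mod: int) -> list[int]:
    out = list(values)
    for _ in range(2):
        prev = 0
        for i, v in enumerate(out):
            out[i] = (v - prev) % mod
            prev = v
    return out


def _write_scf(path: Path, bases: str, quals: Sequence[int],
               traces: Sequence[Sequence[int]], peak_index: Sequence[int]) -> None:
    # SCF v3: fixed channel order A,C,G,T; samples double-delta encoded.
    n = len(bases)
    n_samples = len(traces[0])
    sample_size = 2
    samples_offset = 128
    bases_offset = samples_offset + 4 * n_samples * sample_size
    header = struct.pack(
        ">4sIIIIIIII4sIIII",
        b".scf", n_samples, samples_offset, n, 0, 0, bases_offset,
        0, bases_offset + 12 * n, b"3.00", sample_size, 0, 0, 0,
    ).ljust(128, b"\0")

    body = b""
    for trace in traces:
        body += struct.pack(f">{n_samples}H",
                            *_delta_delta(trace, 1 << 16))

    body += struct.pack(f">{n}I", *peak_index)
    chan_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = [bytearray(n) for _ in range(4)]
    for i, b in enumerate(bases):
        q = min(max(quals[i], 0), 255)
        if b in chan_of:
            probs[chan_of[b]][i] = q
        else:  # ambiguous call: same support in every channel
            for p in probs:
                p[i] = q
    for p in probs:
        body += bytes(p)
    body += bases.encode("ascii")
    body += b"\0" * (3 * n)
    path.write_bytes(header + body)


# ---------------------------------------------------------------------------
# SFF writer
# ---------------------------------------------------------------------------

_FLOW_CYCLE = "TACG"
_SFF_KEY = "TCAG"


def write_synthetic_sff(
    records: Sequence[SequenceRecord],
    path,
    clips: Optional[Sequence[tuple[int, int, int, int]]] = None,
) -> Path:
    """Write records as a valid big-endian SFF v1 file.

    Flow values are synthesized from the base calls on the standard TACG
    flow cycle: an incorporated base contributes 100 per homopolymer unit
    to its flow.  ``clips`` optionally gives per-read
    ``(clip_qual_left, clip_qual_right, clip_adapter_left,
    clip_adapter_right)`` in SFF 1-based convention (0 = absent).
    """
    path = Path(path)
    clips = clips or [(0, 0, 0, 0)] * len(records)
    if len(clips) != len(records):
        raise ValueError("one clip tuple per record required")

    # Enough flows to call the longest read even in the worst phase.
    max_len = max((len(r) for r in records), default=0)
    n_flows = max(4 * (max_len + 1), 8)
    flow_chars = (_FLOW_CYCLE * (n_flows // 4 + 1))[:n_flows]

    header_len = 31 + n_flows + len(_SFF_KEY)
    header_len_padded = (header_len + 7) // 8 * 8
    out = struct.pack(
        ">IIQIIHHHB", 0x2E736666, 1, 0, 0, len(records),
        header_len_padded, len(_SFF_KEY), n_flows, 1,
    ) + flow_chars.encode("ascii") + _SFF_KEY.encode("ascii")
    out = out.ljust(header_len_padded, b"\0")

    for rec, clip in zip(records, clips):
        flows = [0] * n_flows
        flow_index: list[int] = []
        pos = -1
        for b in rec.bases:
            target = b if b in "ACGT" else "N"
            steps = 0
            p = pos
            if target == "N":
                # no incorporation signal; attribute to the next flow
                p = pos + 1
                steps = p - pos
            elif flow_chars[pos] == target if pos >= 0 else False:
                steps = 0  # homopolymer extension of the current flow
            else:
                p = pos + 1
                steps = 1
                while flow_chars[p % n_flows] != target:
                    p += 1
                    steps += 1
            if p >= n_flows:
                raise ValueError("flow budget exceeded (read too long)")
            if target != "N":
                flows[p] += 100
            flow_index.append(steps)
            pos = p
        name = rec.read_id.encode("ascii")
        nb = len(rec.bases)
        rh = struct.pack(">HHIHHHH", 0, len(name), nb, *clip) + name
        rh_len = (len(rh) + 7) // 8 * 8
        rh = struct.pack(">HHIHHHH", rh_len, len(name), nb, *clip) + name
        rh = rh.ljust(rh_len, b"\0")
        data = struct.pack(f">{n_flows}H", *flows)
        data += bytes(min(i, 255) for i in flow_index)
        data += rec.bases.encode("ascii")
        data += bytes(min(max(q, 0), 255) for q in rec.quals)
        data = data.ljust((len(data) + 7) // 8 * 8, b"\0")
        out += rh + data
    path.write_bytes(out)
    return path


# ---------------------------------------------------------------------------
# Text-format writers (independent of seqio)
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[SequenceRecord], path,
                offset: int = 33) -> Path:
    """Write FASTQ at a chosen Phred offset (33 or 64) for encoding tests."""
    if offset not in (33, 64):
        raise ValueError("offset must be 33 or 64")
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            qual = "".join(chr(q + offset) for q in rec.quals)
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")
    return path


def write_fasta_qual(records: Iterable[SequenceRecord], fasta_path,
                     qual_path, width: int = 60) -> tuple[Path, Path]:
    """Write a FASTA file and its QUAL twin."""
    fasta_path, qual_path = Path(fasta_path), Path(qual_path)
    with open(fasta_path, "w", newline="\n") as fa, \
            open(qual_path, "w", newline="\n") as qu:
        for rec in records:
            fa.write(f">{rec.read_id}\n")
            for i in range(0, len(rec.bases), width):
                fa.write(rec.bases[i:i + width] + "\n")
            qu.write(f">{rec.read_id}\n")
            qu.write(" ".join(str(q) for q in rec.quals) + "\n")
    return fasta_path, qual_path


def as_flow_records(records: Sequence[SequenceRecord],
                    clips: Sequence[tuple[int, int, int, int]]) -> list[FlowRecord]:
    """Helper: attach clip tuples to plain records (for clip-logic tests)."""
    out = []
    for rec, (cql, cqr, cal, car) in zip(records, clips):
        out.append(FlowRecord(
            read_id=rec.read_id, bases=rec.bases, quals=list(rec.quals),
            clip_qual_left=cql, clip_qual_right=cqr,
            clip_adapter_left=cal, clip_adapter_right=car,
        ))
    return out
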