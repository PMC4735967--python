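"""Reading native sequencing formats and writing unified Sanger FASTQ.

Supported inputs are the formats the four platforms actually emit:

* **AB1 (ABIF)** — Applied Biosystems tagged binary container holding the
  Sanger chromatogram (big-endian directory of 28-byte entries).
* **SCF v3** — the Staden trace container (delta-delta encoded samples).
* **SFF v1** — the 454/Ion Torrent flowgram container (big-endian).
* **FASTA + QUAL** — paired text files (454 legacy output).
* **FASTQ** — Phred+33 ("Sanger") or legacy Phred+64 encoding.

All readers return :class:`~seqsanitize.records.SequenceRecord` (or a
subclass) with plain Sanger-scale Phred integers; the only writer emits
Phred+33 FASTQ, the package's unified output encoding.

The ABIF, SCF and SFF readers are implemented natively against the public
format specifications so that tag selection (e.g. the base-caller's
``PBAS.1``/``PCON.1`` entries rather than the user-edited copies) and
verbatim SFF clip coordinates are under this package's control.  FASTQ and
FASTA/QUAL parsing is delegated to Biopython.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .errors import FormatError, ParseError, PairingError, RecordError
from .records import (
    MAX_PHRED,
    ChromatogramRecord,
    FlowRecord,
    SequenceRecord,
)

logger = logging.getLogger(__name__)

FORMAT_LABELS = ("ab1", "scf", "sff", "fastq", "fasta_qual", "unknown")

_SFF_MAGIC = 0x2E736666  # ".sff"


# ---------------------------------------------------------------------------
# Format detection
# ---------------------------------------------------------------------------

def detect_format(path) -> str:
    """Classify a file as one of ``ab1, scf, sff, fastq, fasta_qual, unknown``.

    Binary magic bytes are checked first (``ABIF``, ``.scf``, ``.sff`` at
    offset 0); failing that the head of the file is sniffed as text: a
    first non-blank ``@`` with a ``+`` separator inside the first record
    means FASTQ, a leading ``>`` means FASTA (a FASTA/QUAL candidate).
    Files shorter than 8 bytes are ``unknown``.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            head = fh.read(8)
            if len(head) < 8:
                return "unknown"
            if head[:4] == b"ABIF":
                return "ab1"
            if head[:4] == b".scf":
                return "scf"
            if head[:4] == b".sff":
                return "sff"
            fh.seek(0)
            return _sniff_text(fh)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc


def _sniff_text(fh) -> str:
    try:
        text = fh.read(8192).decode("ascii")
    except UnicodeDecodeError:
        return "unknown"
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return "unknown"
    first = lines[0].lstrip()
    if first.startswith("@"):
        # '+' separator expected on the third line of the first record
        if len(lines) >= 3 and lines[2].startswith("+"):
            return "fastq"
        if len(lines) < 3:  # truncated head of a fastq is still fastq-like
            return "fastq"
        return "unknown"
    if first.startswith(">"):
        return "fasta_qual"
    return "unknown"


# ---------------------------------------------------------------------------
# ABIF (AB1)
# ---------------------------------------------------------------------------

def _abif_entries(data: bytes, path) -> dict[tuple[str, int], bytes]:
    """Parse the ABIF directory into ``{(tag_name, tag_number): raw bytes}``."""
    if data[:4] != b"ABIF":
        raise FormatError(f"{path}: bad ABIF magic")
    if len(data) < 34:
        raise ParseError(f"{path}: truncated ABIF header")
    # header dir entry ("tdir") at offset 6 points at the directory
    (_, _, _, _, nelem, _, dir_offset, _) = struct.unpack(">4sihhiiii", data[6:34])
    entries: dict[tuple[str, int], bytes] = {}
    for i in range(nelem):
        off = dir_offset + 28 * i
        raw = data[off:off + 28]
        if len(raw) < 28:
            raise ParseError(f"{path}: truncated ABIF directory at entry {i}")
        name, number, _etype, _esize, _n, dsize = struct.unpack(">4sihhii", raw[:20])
        if dsize <= 4:  # data stored inline in the offset field
            payload = raw[20:20 + dsize]
        else:
            (doff,) = struct.unpack(">i", raw[20:24])
            payload = data[doff:doff + dsize]
            if len(payload) < dsize:
                raise ParseError(
                    f"{path}: ABIF entry {name.decode(errors='replace')}.{number} "
                    "points past end of file"
                )
        entries[(name.decode("ascii", errors="replace"), number)] = payload
    return entries


def _read_abif(path) -> ChromatogramRecord:
    data = Path(path).read_bytes()
    entries = _abif_entries(data, path)
    for tag in ("PBAS", "PCON"):
        if (tag, 1) not in entries:
            raise ParseError(f"{path}: mandatory ABIF tag {tag}.1 missing")
    bases = entries[("PBAS", 1)].decode("ascii").upper()
    quals = [min(max(q, 0), MAX_PHRED) for q in entries[("PCON", 1)]]

    traces = None
    channel_order = "ACGT"
    peak_index = None
    if ("PLOC", 1) in entries:
        raw = entries[("PLOC", 1)]
        peak_index = list(struct.unpack(f">{len(raw) // 2}h", raw))
    if all(("DATA", n) in entries for n in (9, 10, 11, 12)) and ("FWO_", 1) in entries:
        channel_order = entries[("FWO_", 1)].decode("ascii").upper()
        traces = []
        for n in (9, 10, 11, 12):
            raw = entries[("DATA", n)]
            traces.append(list(struct.unpack(f">{len(raw) // 2}h", raw)))
    rec = ChromatogramRecord(
        read_id=Path(path).stem,
        bases=bases,
        quals=quals,
        traces=traces,
        channel_order=channel_order,
        peak_index=peak_index,
    )
    return rec.validate()


# ---------------------------------------------------------------------------
# SCF v3
# ---------------------------------------------------------------------------

_SCF_HEADER = ">4sIIIIIIII4sIIII"  # up to private_offset; 18 spare words follow


def _read_scf(path) -> ChromatogramRecord:
    data = Path(path).read_bytes()
    if data[:4] != b".scf":
        raise FormatError(f"{path}: bad SCF magic")
    if len(data) < 128:
        raise ParseError(f"{path}: truncated SCF header")
    (_, n_samples, samples_offset, n_bases, _lclip, _rclip, bases_offset,
     _csize, _coff, version, sample_size, _code_set, _psize, _poff) = \
        struct.unpack(_SCF_HEADER, data[:56])
    try:
        ver = float(version.decode("ascii"))
    except ValueError:
        raise ParseError(f"{path}: unreadable SCF version field {version!r}")
    if ver < 3.0:
        raise FormatError(f"{path}: SCF version {ver} unsupported (need >= 3.00)")
    if sample_size not in (1, 2):
        raise ParseError(f"{path}: bad SCF sample_size {sample_size}")

    # Samples block: four channels (A, C, G, T) stored sequentially, each
    # double-delta encoded; decoding is two cumulative sums modulo the
    # sample word size.
    mod = 1 << (8 * sample_size)
    fmt = "B" if sample_size == 1 else "H"
    traces = []
    pos = samples_offset
    for _chan in range(4):
        end = pos + n_samples * sample_size
        if end > len(data):
            raise ParseError(f"{path}: SCF samples block truncated")
        vals = list(struct.unpack(f">{n_samples}{fmt}", data[pos:end]))
        for _ in range(2):  # undo double delta
            acc = 0
            for i, v in enumerate(vals):
                acc = (acc + v) % mod
                vals[i] = acc
        traces.append(vals)
        pos = end

    # Bases block: peak offsets, four per-channel probability arrays,
    # base calls, then 3*n spare bytes.
    pos = bases_offset
    end = pos + 4 * n_bases
    if len(data) < bases_offset + 8 * n_bases:
        raise ParseError(f"{path}: SCF bases block truncated")
    peak_index = list(struct.unpack(f">{n_bases}I", data[pos:end]))
    probs = []
    pos = end
    for _chan in range(4):
        probs.append(data[pos:pos + n_bases])
        pos += n_bases
    bases = data[pos:pos + n_bases].decode("ascii").upper()
    chan_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    quals = []
    for i, b in enumerate(bases):
        if b in chan_of:
            q = probs[chan_of[b]][i]
        else:  # ambiguous call: take the best supported channel
            q = max(p[i] for p in probs)
        quals.append(min(max(q, 0), MAX_PHRED))

    rec = ChromatogramRecord(
        read_id=Path(path).stem,
        bases=bases,
        quals=quals,
        traces=traces,
        channel_order="ACGT",
        peak_index=peak_index,
    )
    return rec.validate()


def read_chromatogram(path, format: Optional[str] = None) -> ChromatogramRecord:
    """Read a single Sanger trace file (AB1 or SCF v3).

    One trace file holds exactly one read.  For ABIF the base-caller's
    entries are used: bases from ``PBAS.1``, qualities from ``PCON.1``,
    peak positions from ``PLOC.1`` and the processed traces from
    ``DATA.9``–``DATA.12`` in ``FWO_.1`` channel order.  Qualities are
    clamped into ``[0, 93]``.
    """
    fmt = format or detect_format(path)
    if fmt == "ab1":
        return _read_abif(path)
    if fmt == "scf":
        return _read_scf(path)
    raise FormatError(f"{path}: not a chromatogram format (detected {fmt!r})")


# ---------------------------------------------------------------------------
# SFF v1
# ---------------------------------------------------------------------------

def read_sff(path) -> Iterator[FlowRecord]:
    """Stream the reads of an SFF v1 file as :class:`FlowRecord`.

    The index section, if present, is skipped; vendor clip coordinates are
    preserved verbatim (applying them is the conversion stage's decision).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(31)
        if len(header) < 31:
            raise ParseError(f"{path}: truncated SFF header")
        (magic, version, index_offset, index_length, n_reads,
         header_length, key_length, n_flows, flow_fmt) = \
            struct.unpack(">IIQIIHHHB", header)
        if magic != _SFF_MAGIC:
            raise FormatError(f"{path}: bad SFF magic")
        if version != 1:
            raise FormatError(f"{path}: unsupported SFF version {version}")
        if flow_fmt != 1:
            raise FormatError(f"{path}: unsupported flowgram format code {flow_fmt}")
        flow_chars = fh.read(n_flows).decode("ascii")
        fh.read(key_length)
        fh.seek(header_length)

        for idx in range(n_reads):
            if index_offset and fh.tell() == index_offset:
                fh.seek(index_offset + _pad8(index_length))
            rh = fh.read(16)
            if len(rh) < 16:
                raise ParseError(f"{path}: truncated read header at read {idx}")
            (rh_len, name_len, n_bases, cql, cqr, cal, car) = \
                struct.unpack(">HHIHHHH", rh)
            name = fh.read(name_len).decode("ascii")
            fh.seek(rh_len - 16 - name_len, 1)
            body_len = 2 * n_flows + 3 * n_bases
            body = fh.read(_pad8(body_len))
            if len(body) < body_len:
                raise ParseError(f"{path}: truncated read data at read {idx} ({name})")
            flow_values = list(struct.unpack(f">{n_flows}H", body[:2 * n_flows]))
            p = 2 * n_flows
            flow_index = list(body[p:p + n_bases])
            p += n_bases
            bases = body[p:p + n_bases].decode("ascii").upper()
            p += n_bases
            quals = [min(q, MAX_PHRED) for q in body[p:p + n_bases]]
            yield FlowRecord(
                read_id=name,
                bases=bases,
                quals=quals,
                flow_values=flow_values,
                flow_chars=flow_chars,
                flow_index=flow_index,
                clip_qual_left=cql,
                clip_qual_right=cqr,
                clip_adapter_left=cal,
                clip_adapter_right=car,
            ).validate()


def _pad8(n: int) -> int:
    return (n + 7) // 8 * 8


# ---------------------------------------------------------------------------
# FASTA + QUAL
# ---------------------------------------------------------------------------

def read_fasta_qual(fasta_path, qual_path) -> Iterator[SequenceRecord]:
    """Pair a FASTA file with its QUAL twin record-by-record.

    Records must appear in the same order with matching identifiers and
    agreeing lengths; violations raise :class:`PairingError` /
    :class:`RecordError` naming the offending records.
    """
    fa_iter = SeqIO.parse(str(fasta_path), "fasta")
    q_iter = SeqIO.parse(str(qual_path), "qual")
    k = 0
    while True:
        fa = next(fa_iter, None)
        q = next(q_iter, None)
        if fa is None and q is None:
            return
        if fa is None or q is None:
            longer = qual_path if fa is None else fasta_path
            raise PairingError(
                f"{fasta_path} / {qual_path}: unequal record counts "
                f"(extra records in {longer})"
            )
        if fa.id != q.id:
            raise PairingError(
                f"record {k}: FASTA id {fa.id!r} != QUAL id {q.id!r}"
            )
        quals = list(q.letter_annotations["phred_quality"])
        bases = str(fa.seq).upper()
        if len(bases) != len(quals):
            raise RecordError(
                f"record {fa.id!r}: {len(bases)} bases but {len(quals)} qualities"
            )
        yield SequenceRecord(
            read_id=fa.id,
            bases=bases,
            quals=[min(max(v, 0), MAX_PHRED) for v in quals],
        ).validate()
        k += 1


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def detect_fastq_encoding(path, probe_reads: int = 10000) -> str:
    """Infer the Phred offset of a FASTQ file: ``"phred33"`` or ``"phred64"``.

    The minimum quality character code *m* over the first ``probe_reads``
    records decides: ``m < 64`` forces phred33 (codes 59–63 are illegal in
    standard phred64 data); when every code is >= 64 the file is treated as
    legacy phred64 — such data could in principle be uniformly high-quality
    phred33, so the resolution is logged.
    """
    path = Path(path)
    min_code = None
    n = 0
    with open(path, "rb") as fh:
        while n < probe_reads:
            head = fh.readline()
            if not head:
                break
            if not head.strip():
                continue
            if not head.startswith(b"@"):
                raise FormatError(f"{path}: expected '@' header, got {head[:20]!r}")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline().rstrip(b"\r\n")
            if not plus.startswith(b"+") or not qual:
                raise FormatError(f"{path}: malformed FASTQ record {n}")
            if len(qual) != len(seq.rstrip(b"\r\n")):
                raise FormatError(f"{path}: quality length mismatch in record {n}")
            lo = min(qual)
            min_code = lo if min_code is None else min(min_code, lo)
            n += 1
    if n == 0:
        raise FormatError(f"{path}: no parsable FASTQ records")
    if min_code < 64:
        return "phred33"
    logger.info(
        "%s: all quality codes >= 64 in %d probed reads; assuming phred64",
        path, n,
    )
    return "phred64"


def read_fastq(path, encoding: str = "phred33",
               pair_role: str = "single") -> Iterator[SequenceRecord]:
    """Stream a FASTQ file at a known quality encoding.

    ``encoding`` is ``"phred33"`` or ``"phred64"`` (see
    :func:`detect_fastq_encoding`).  Bases are upper-cased; a quality
    character that would decode to a negative Phred value, or a truncated
    final record, raises :class:`ParseError`.
    """
    if encoding not in ("phred33", "phred64"):
        raise ValueError(f"unknown encoding {encoding!r}")
    bio_fmt = "fastq" if encoding == "phred33" else "fastq-illumina"
    try:
        for rec in SeqIO.parse(str(path), bio_fmt):
            quals = list(rec.letter_annotations["phred_quality"])
            yield SequenceRecord(
                read_id=rec.description.split()[0] if rec.description else rec.id,
                bases=str(rec.seq).upper(),
                quals=[min(q, MAX_PHRED) for q in quals],
                pair_role=pair_role,
            ).validate()
    except ValueError as exc:  # Biopython's parse/offset errors
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# FASTQ output (always Sanger / Phred+33)
# ---------------------------------------------------------------------------

def write_fastq_sanger(records: Iterable[SequenceRecord], path) -> int:
    """Write records as Phred+33 FASTQ; returns the number written.

    Qualities above 93 are clamped to 93 (the highest encodable value) with
    a logged warning.  Output is byte-stable for identical input.
    """
    n = 0
    clamped = 0
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            if len(rec.bases) != len(rec.quals):
                raise RecordError(
                    f"record {rec.read_id!r}: bases/quals length mismatch"
                )
            chars = []
            for q in rec.quals:
                if q > MAX_PHRED:
                    q = MAX_PHRED
                    clamped += 1
                if q < 0:
                    raise RecordError(
                        f"record {rec.read_id!r}: negative quality {q}"
                    )
                chars.append(chr(q + 33))
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n{''.join(chars)}\n")
            n += 1
    if clamped:
        logger.warning(
            "%s: clamped %d quality values above %d", path, clamped, MAX_PHRED
        )
    return n
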