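"""Core read containers shared by every pipeline stage.

A read is a :class:`SequenceRecord`: an identifier, an upper-case IUPAC
base string, one Phred quality integer per base and a pair role.  Sanger
chromatograms and 454/Ion Torrent flowgram reads extend it with the
platform-specific signal data needed by base-call refinement and vendor
clipping.

Quality values are plain Sanger-scale Phred integers throughout the
package; encoding offsets (+33 / +64) exist only at the FASTQ boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import RecordError

#: Upper-case IUPAC nucleotide alphabet (including U for completeness).
IUPAC_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")

#: Maximum quality representable in Sanger FASTQ (chr 126 == '~').
MAX_PHRED = 93

#: IUPAC single-letter code for each set of unambiguous bases.
IUPAC_CODE_FOR_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One sequencing read with per-base Phred qualities.

    Parameters
    ----------
    read_id:
        Read identifier without the leading ``@``/``>``.
    bases:
        Upper-case IUPAC nucleotide string.
    quals:
        One Phred integer per base, each in ``[0, 93]``.
    pair_role:
        ``"single"``, ``"forward"`` or ``"reverse"``.
    """

    read_id: str
    bases: str
    quals: list[int]
    pair_role: str = "single"

    def __len__(self) -> int:
        return len(self.bases)

    def validate(self) -> "SequenceRecord":
        """Check record invariants; return self or raise :class:`RecordError`."""
        if len(self.bases) != len(self.quals):
            raise RecordError(
                f"record {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            bad = next(q for q in self.quals if q < 0 or q > MAX_PHRED)
            raise RecordError(
                f"record {self.read_id!r}: quality {bad} outside [0, {MAX_PHRED}]"
            )
        bad_chars = set(self.bases) - IUPAC_ALPHABET
        if bad_chars:
            raise RecordError(
                f"record {self.read_id!r}: non-IUPAC characters {sorted(bad_chars)}"
            )
        if self.pair_role not in ("single", "forward", "reverse"):
            raise RecordError(
                f"record {self.read_id!r}: bad pair_role {self.pair_role!r}"
            )
        return self

    def slice(self, start: int, stop: int) -> "SequenceRecord":
        """Return a copy restricted to ``bases[start:stop]`` (quals in lockstep)."""
        return replace(self, bases=self.bases[start:stop], quals=self.quals[start:stop])


@dataclass
class ChromatogramRecord(SequenceRecord):
    """A Sanger read plus the four-channel trace it was called from.

    ``traces`` holds four equal-length signal arrays in file order;
    ``channel_order`` is the permutation of ``"ACGT"`` mapping array index
    to base (ABIF ``FWO_`` field).  ``peak_index`` gives, for each called
    base, the sample index of its peak.  Trace data is optional: records
    built from files lacking trace blocks carry ``None`` and base-call
    refinement refuses them.
    """

    traces: Optional[list[list[int]]] = None
    channel_order: str = "ACGT"
    peak_index: Optional[list[int]] = None

    def validate(self) -> "ChromatogramRecord":
        super().validate()
        if self.traces is not None:
            if len(self.traces) != 4:
                raise RecordError(f"record {self.read_id!r}: need 4 trace channels")
            lengths = {len(t) for t in self.traces}
            if len(lengths) != 1:
                raise RecordError(
                    f"record {self.read_id!r}: unequal trace channel lengths {lengths}"
                )
            if sorted(self.channel_order) != list("ACGT"):
                raise RecordError(
                    f"record {self.read_id!r}: channel_order {self.channel_order!r} "
                    "is not a permutation of ACGT"
                )
        if self.peak_index is not None:
            if len(self.peak_index) != len(self.bases):
                raise RecordError(
                    f"record {self.read_id!r}: {len(self.peak_index)} peak indices "
                    f"for {len(self.bases)} bases"
                )
            if self.traces is not None:
                n = len(self.traces[0])
                if any(p < 0 or p >= n for p in self.peak_index):
                    raise RecordError(
                        f"record {self.read_id!r}: peak index out of trace range"
                    )
            if any(b >= a for a, b in zip(self.peak_index[1:], self.peak_index)):
                raise RecordError(
                    f"record {self.read_id!r}: peak_index not strictly increasing"
                )
        return self

    def signal_at(self, position: int) -> dict[str, int]:
        """Per-base signal height at the peak of the called base ``position``."""
        peak = self.peak_index[position]
        return {
            base: self.traces[chan][peak]
            for chan, base in enumerate(self.channel_order)
        }


@dataclass
class FlowRecord(SequenceRecord):
    """A 454 / Ion Torrent read from an SFF file.

    Clip coordinates follow the SFF convention: 1-based inclusive, with 0
    meaning "absent".  They are preserved verbatim from the file; applying
    them is a separate pipeline decision.
    """

    flow_values: list[int] = field(default_factory=list)
    flow_chars: str = ""
    flow_index: list[int] = field(default_factory=list)
    clip_qual_left: int = 0
    clip_qual_right: int = 0
    clip_adapter_left: int = 0
    clip_adapter_right: int = 0

    def validate(self) -> "FlowRecord":
        super().validate()
        n = len(self.bases)
        for name in ("clip_qual_left", "clip_qual_right",
                     "clip_adapter_left", "clip_adapter_right"):
            v = getattr(self, name)
            if v != 0 and not (1 <= v <= n):
                raise RecordError(
                    f"record {self.read_id!r}: {name}={v} outside [1, {n}]"
                )
        return self

    def effective_clip(self) -> tuple[int, int]:
        """0-based half-open ``(start, stop)`` combining vendor clip points.

        Left boundary is the stricter (larger) of the quality and adapter
        left clips; right boundary the stricter (smaller) of the non-zero
        right clips, per the SFF specification's reading of 0 as "no clip".
        """
        n = len(self.bases)
        left = max(self.clip_qual_left, self.clip_adapter_left, 1) - 1
        rights = [c for c in (self.clip_qual_right, self.clip_adapter_right) if c > 0]
        right = min(rights) if rights else n
        return left, max(left, right)
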