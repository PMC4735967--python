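"""Demultiplexing pooled NGS reads by 5'-anchored MID barcodes.

Multiplexed sequencing prepends a short sample-specific barcode (MID,
"Multiplexed Identifier") to each read.  This module assigns every read
to at most one sample by Hamming distance between each barcode and the
read prefix of equal length, removes the barcode (and its qualities) from
assigned reads, and writes one FASTQ per sample plus an ``unassigned``
bin.  For paired-end data the barcode is expected on the forward read
only; the mate follows its forward read's bin.

Assignment is conservative: a read matching two barcodes equally well is
left unassigned rather than being given to an arbitrary sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

from .errors import ContractError
from .records import SequenceRecord
from .seqio import write_fastq_sanger

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BarcodeSpec:
    """One sample's MID barcode."""

    sample_id: str
    mid: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.mid:
            raise ContractError(f"sample {self.sample_id!r}: empty barcode")
        bad = set(self.mid.upper()) - set("ACGT")
        if bad:
            raise ContractError(
                f"sample {self.sample_id!r}: barcode has non-ACGT characters {sorted(bad)}"
            )
        if self.max_mismatch < 0:
            raise ContractError("max_mismatch must be >= 0")


def validate_barcode_table(table: Iterable[BarcodeSpec],
                           max_mismatch: int = 0) -> list[BarcodeSpec]:
    """Check that barcodes are usable together.

    All MIDs must be distinct; equal-length MIDs closer than
    ``2 * max_mismatch + 1`` in Hamming distance cannot be told apart at
    that tolerance, which is reported as a warning (assignment then relies
    on the tie -> unassigned rule).
    """
    specs = list(table)
    mids = [s.mid.upper() for s in specs]
    if len(set(mids)) != len(mids):
        dupes = sorted({m for m in mids if mids.count(m) > 1})
        raise ContractError(f"duplicate barcodes in table: {dupes}")
    for a, b in combinations(specs, 2):
        if len(a.mid) == len(b.mid):
            d = _hamming(a.mid.upper(), b.mid.upper())
            if d <= 2 * max_mismatch:
                logger.warning(
                    "barcodes %s (%s) and %s (%s) are Hamming distance %d apart; "
                    "ambiguous at max_mismatch=%d",
                    a.sample_id, a.mid, b.sample_id, b.mid, d, max_mismatch,
                )
    return specs


def _hamming(mid: str, prefix: str) -> int:
    # N in the read counts as a mismatch against any barcode base
    return sum(1 for m, p in zip(mid, prefix) if m != p)


def assign_barcode(
    record: SequenceRecord,
    table: Iterable[BarcodeSpec],
    max_mismatch: int = 0,
) -> tuple[Optional[str], SequenceRecord]:
    """Assign a read to a sample and strip the barcode prefix.

    Returns ``(sample_id, trimmed_record)`` on an unambiguous assignment,
    ``(None, record)`` otherwise.  Barcodes longer than the read cannot
    match and are skipped.  With mixed-length barcode sets the longest
    length is tried first; within a length the unique minimum-distance
    candidate within ``max_mismatch`` wins, and ties leave the read
    unassigned.
    """
    specs = list(table)
    if not specs:
        raise ContractError("demultiplexing requested without barcodes")
    read = record.bases.upper()
    for length in sorted({len(s.mid) for s in specs}, reverse=True):
        if length > len(read):
            continue
        prefix = read[:length]
        candidates = []
        for spec in specs:
            if len(spec.mid) != length:
                continue
            d = _hamming(spec.mid.upper(), prefix)
            if d <= max_mismatch:
                candidates.append((d, spec))
        if not candidates:
            continue
        best = min(d for d, _ in candidates)
        winners = [spec for d, spec in candidates if d == best]
        if len(winners) != 1:
            return None, record
        return winners[0].sample_id, record.slice(length, len(record))
    return None, record


def demultiplex(
    reads,
    table: Iterable[BarcodeSpec],
    out_dir,
    max_mismatch: int = 0,
    paired: bool = False,
) -> dict[str, int]:
    """Split a read stream (or pair stream) into per-sample FASTQ files.

    ``reads`` yields :class:`SequenceRecord` (single-end) or
    ``(forward, reverse)`` tuples (paired-end, ``paired=True``); the
    barcode is read from the forward mate only.  Writes
    ``<sample>.fastq`` (or ``<sample>_R1/_R2.fastq``) plus an
    ``unassigned`` bin under ``out_dir`` and returns read (or pair)
    counts per bin.  Every input read lands in exactly one bin.
    """
    specs = validate_barcode_table(table, max_mismatch)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bins: dict[str, list] = {s.sample_id: [] for s in specs}
    bins[UNASSIGNED] = []
    n_in = 0
    for item in reads:
        n_in += 1
        if paired:
            fwd, rev = item
            sample, trimmed = assign_barcode(fwd, specs, max_mismatch)
            bins[sample or UNASSIGNED].append((trimmed, rev))
        else:
            sample, trimmed = assign_barcode(item, specs, max_mismatch)
            bins[sample or UNASSIGNED].append(trimmed)

    counts: dict[str, int] = {}
    for sample, members in bins.items():
        counts[sample] = len(members)
        if paired:
            write_fastq_sanger((f for f, _ in members),
                               out_dir / f"{sample}_R1.fastq")
            write_fastq_sanger((r for _, r in members),
                               out_dir / f"{sample}_R2.fastq")
        else:
            write_fastq_sanger(iter(members), out_dir / f"{sample}.fastq")
    assert sum(counts.values()) == n_in  # partition property
    return counts
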