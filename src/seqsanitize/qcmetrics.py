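"""Per-sample QC statistics and HTML/TSV reporting.

For every sample the pipeline computes the same battery of statistics
twice — on the raw converted reads ("before") and on the final cleaned
reads ("after") — so data quality improvements are directly comparable:
per-position quality distribution, read length histogram, mean GC
content, sequence duplication levels and overrepresented sequences.

Everything is accumulated in a single streaming pass.  The renderers are
pure formatting: every number in a report is the corresponding
:class:`QCStats` field, never re-derived, and each HTML table has a
machine-readable tab-separated twin.
"""

from __future__ import annotations

import html
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import SeqSanitizeError
from .records import MAX_PHRED, SequenceRecord

#: A sequence is overrepresented when it exceeds this fraction of reads.
OVERREP_FRACTION = 0.001
#: Cap on the overrepresented-sequences list in reports.
OVERREP_CAP = 20
#: Cap on distinct sequences tracked for duplication statistics.
DUP_TRACK_CAP = 500_000

# GC definition: S (G-or-C) counts as GC, W (A-or-T) as AT; all other
# ambiguity codes and N are excluded from the denominator.
_GC_CHARS = frozenset("GCS")
_GC_DENOM_CHARS = frozenset("ACGTSW")


@dataclass
class PositionStats:
    """Quality summary for one read position (1-based)."""

    position: int
    count: int
    mean: float
    q1: int
    median: int
    q3: int


class QCStats:
    """Streaming aggregate of read-level QC statistics.

    Feed records with :meth:`update`; summary properties may be read at
    any time.  ``gc_percent`` is the per-read GC percentage averaged over
    reads (reads with no unambiguous base are skipped); with zero reads
    it is reported as 0 and ``gc_defined`` is False.
    """

    def __init__(self) -> None:
        self.n_reads = 0
        self.n_bases = 0
        self.length_hist: Counter = Counter()
        self._gc_sum = 0.0
        self._gc_reads = 0
        # per-position quality histogram, grown on demand: [pos, qual]
        self._pos_qual = np.zeros((0, MAX_PHRED + 1), dtype=np.int64)
        self._seq_counts: Counter = Counter()
        self._seq_overflow = 0

    # -- accumulation -----------------------------------------------------

    def update(self, record: SequenceRecord) -> None:
        self.n_reads += 1
        n = len(record)
        self.n_bases += n
        self.length_hist[n] += 1
        denom = sum(1 for b in record.bases if b in _GC_DENOM_CHARS)
        if denom:
            gc = sum(1 for b in record.bases if b in _GC_CHARS)
            self._gc_sum += 100.0 * gc / denom
            self._gc_reads += 1
        if n > self._pos_qual.shape[0]:
            grown = np.zeros((n, MAX_PHRED + 1), dtype=np.int64)
            grown[: self._pos_qual.shape[0]] = self._pos_qual
            self._pos_qual = grown
        for i, q in enumerate(record.quals):
            self._pos_qual[i, min(max(q, 0), MAX_PHRED)] += 1
        if record.bases in self._seq_counts or \
                len(self._seq_counts) < DUP_TRACK_CAP:
            self._seq_counts[record.bases] += 1
        else:
            self._seq_overflow += 1

    def extend(self, records: Iterable[SequenceRecord]) -> "QCStats":
        for rec in records:
            self.update(rec)
        return self

    # -- summaries --------------------------------------------------------

    @property
    def gc_defined(self) -> bool:
        return self._gc_reads > 0

    @property
    def gc_percent(self) -> float:
        return self._gc_sum / self._gc_reads if self._gc_reads else 0.0

    @property
    def mean_quality(self) -> float:
        total = int(self._pos_qual.sum())
        if total == 0:
            return 0.0
        quals = np.arange(MAX_PHRED + 1)
        return float((self._pos_qual.sum(axis=0) * quals).sum() / total)

    @property
    def duplication_hist(self) -> dict[int, int]:
        """copy-number -> number of distinct sequences seen that many times."""
        out: Counter = Counter()
        for c in self._seq_counts.values():
            out[c] += 1
        return dict(sorted(out.items()))

    @property
    def overrepresented(self) -> list[tuple[str, int, float]]:
        """(sequence, count, percent) for sequences above the threshold."""
        if self.n_reads == 0:
            return []
        cutoff = max(1, int(np.ceil(OVERREP_FRACTION * self.n_reads)))
        hits = [
            (seq, c, 100.0 * c / self.n_reads)
            for seq, c in self._seq_counts.items()
            if c > cutoff
        ]
        hits.sort(key=lambda t: (-t[1], t[0]))
        return hits[:OVERREP_CAP]

    def per_position(self) -> list[PositionStats]:
        """Quality summary per position (nearest-rank quartiles)."""
        out = []
        quals = np.arange(MAX_PHRED + 1)
        for pos in range(self._pos_qual.shape[0]):
            hist = self._pos_qual[pos]
            count = int(hist.sum())
            if count == 0:
                continue
            cum = np.cumsum(hist)
            mean = float((hist * quals).sum() / count)

            def rank(p: float) -> int:
                # nearest-rank quantile on the histogram
                k = max(1, int(np.ceil(p * count)))
                return int(np.searchsorted(cum, k))

            out.append(PositionStats(
                position=pos + 1, count=count, mean=mean,
                q1=rank(0.25), median=rank(0.5), q3=rank(0.75),
            ))
        return out

    def check_invariants(self) -> None:
        assert sum(self.length_hist.values()) == self.n_reads
        assert sum(k * v for k, v in self.length_hist.items()) == self.n_bases
        assert 0.0 <= self.gc_percent <= 100.0


def accumulate_stats(reads: Iterable[SequenceRecord]) -> QCStats:
    """Single-pass QC statistics over a read stream (empty stream allowed)."""
    return QCStats().extend(reads)


@dataclass
class SampleResult:
    """One sample's outcome for the cohort summary table."""

    patient_id: str
    reads_before: int = 0
    reads_after: int = 0
    gc_before: float = 0.0
    gc_after: float = 0.0
    report_before: str = ""
    report_after: str = ""
    fastq_paths: list = field(default_factory=list)
    removed_by: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)
    failed: bool = False
    error: str = ""

    def __post_init__(self) -> None:
        if self.reads_after > self.reads_before:
            raise SeqSanitizeError(
                f"sample {self.patient_id}: reads_after > reads_before"
            )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_REPORT_CSS = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 2px 8px; text-align: right; }
th { background: #eee; }
h2 { border-bottom: 2px solid #444; }
.warn { color: #a00; font-weight: bold; }
"""


def _table(headers: Sequence[str], rows: Sequence[Sequence]) -> str:
    head = "".join(f"<th>{html.escape(str(h))}</th>" for h in headers)
    body = "\n".join(
        "<tr>" + "".join(f"<td>{html.escape(str(c))}</td>" for c in row) + "</tr>"
        for row in rows
    )
    return f"<table><tr>{head}</tr>\n{body}\n</table>"


def _write_tsv(path: Path, headers: Sequence[str],
               rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(headers) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _stats_tables(stats: QCStats, phase: str):
    pos_rows = [
        (phase, p.position, p.count, f"{p.mean:.2f}", p.q1, p.median, p.q3)
        for p in stats.per_position()
    ]
    len_rows = [(phase, ln, c) for ln, c in sorted(stats.length_hist.items())]
    dup_rows = [(phase, k, v) for k, v in stats.duplication_hist.items()]
    over_rows = [
        (phase, seq, c, f"{pct:.3f}") for seq, c, pct in stats.overrepresented
    ]
    return pos_rows, len_rows, dup_rows, over_rows


def _stats_section(stats: QCStats, phase: str) -> str:
    parts = [f"<h2>{phase.capitalize()} QC</h2>"]
    if stats.n_reads == 0:
        parts.append('<p class="warn">0 reads survived</p>')
    gc = f"{stats.gc_percent:.2f}" if stats.gc_defined else "n/a"
    parts.append(_table(
        ["reads", "bases", "mean quality", "GC %"],
        [[stats.n_reads, stats.n_bases, f"{stats.mean_quality:.2f}", gc]],
    ))
    pos_rows, len_rows, dup_rows, over_rows = _stats_tables(stats, phase)
    parts.append("<h3>Per-position quality</h3>")
    parts.append(_table(
        ["position", "count", "mean", "Q1", "median", "Q3"],
        [r[1:] for r in pos_rows],
    ))
    parts.append("<h3>Read length distribution</h3>")
    parts.append(_table(["length", "count"], [r[1:] for r in len_rows]))
    parts.append("<h3>Sequence duplication levels</h3>")
    parts.append(_table(["copies", "distinct sequences"],
                        [r[1:] for r in dup_rows]))
    parts.append("<h3>Overrepresented sequences</h3>")
    if over_rows:
        parts.append(_table(["sequence", "count", "percent"],
                            [r[1:] for r in over_rows]))
    else:
        parts.append("<p>none</p>")
    return "\n".join(parts)


def render_qc_report(before: QCStats, after: QCStats, out_path) -> Path:
    """Write a standalone before/after QC report plus TSV sidecars.

    The HTML holds a "before" and an "after" section with the full table
    battery; the same numbers go to ``<stem>_per_position.tsv``,
    ``<stem>_length_hist.tsv``, ``<stem>_duplication.tsv`` and
    ``<stem>_overrepresented.tsv`` with a leading ``phase`` column.
    """
    out_path = Path(out_path)
    title = f"QC report: {out_path.stem}"
    doc = (
        f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title><style>{_REPORT_CSS}</style>"
        f"</head><body><h1>{html.escape(title)}</h1>\n"
        + _stats_section(before, "before")
        + "\n"
        + _stats_section(after, "after")
        + "\n</body></html>\n"
    )
    out_path.write_text(doc)

    b = _stats_tables(before, "before")
    a = _stats_tables(after, "after")
    stem = out_path.with_suffix("")
    _write_tsv(Path(f"{stem}_per_position.tsv"),
               ["phase", "position", "count", "mean", "q1", "median", "q3"],
               b[0] + a[0])
    _write_tsv(Path(f"{stem}_length_hist.tsv"),
               ["phase", "length", "count"], b[1] + a[1])
    _write_tsv(Path(f"{stem}_duplication.tsv"),
               ["phase", "copies", "distinct"], b[2] + a[2])
    _write_tsv(Path(f"{stem}_overrepresented.tsv"),
               ["phase", "sequence", "count", "percent"], b[3] + a[3])
    return out_path


SUMMARY_BASE_COLUMNS = [
    "patient_id", "reads_before", "reads_after",
    "gc_before", "gc_after", "status",
    "report_before", "report_after", "fastq",
]


def render_summary_table(results: Sequence[SampleResult], out_path,
                         manifest_ids: Optional[Sequence[str]] = None) -> Path:
    """Write the cohort summary (one row per sample) as HTML plus TSV twin.

    Optional manifest/clinical columns carried in ``result.extra`` become
    additional columns; absent values render as empty cells.  When
    ``manifest_ids`` is given, every manifest sample must have a result.
    """
    out_path = Path(out_path)
    if manifest_ids is not None:
        missing = [pid for pid in manifest_ids
                   if pid not in {r.patient_id for r in results}]
        if missing:
            raise SeqSanitizeError(
                f"summary: no result for patient ids {missing}"
            )
    extra_cols: list[str] = []
    for r in results:
        for k in r.extra:
            if k not in extra_cols:
                extra_cols.append(k)

    headers = SUMMARY_BASE_COLUMNS + extra_cols
    rows = []
    links = []
    for r in results:
        row = [
            r.patient_id, r.reads_before, r.reads_after,
            f"{r.gc_before:.2f}", f"{r.gc_after:.2f}",
            "failed" if r.failed else "ok",
            r.report_before, r.report_after,
            ";".join(str(p) for p in r.fastq_paths),
        ] + [r.extra.get(k, "") for k in extra_cols]
        rows.append(row)
        links.append(r)

    # HTML with hyperlinked report / FASTQ cells
    body_rows = []
    for r, row in zip(links, rows):
        cells = [html.escape(str(c)) for c in row]
        if r.report_before:
            cells[6] = f'<a href="{html.escape(str(r.report_before))}">before</a>'
        if r.report_after:
            cells[7] = f'<a href="{html.escape(str(r.report_after))}">after</a>'
        if r.fastq_paths:
            cells[8] = " ".join(
                f'<a href="{html.escape(str(p))}">{html.escape(Path(str(p)).name)}</a>'
                for p in r.fastq_paths
            )
        body_rows.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
    head = "".join(f"<th>{html.escape(h)}</th>" for h in headers)
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>QC summary</title><style>{_REPORT_CSS}</style></head><body>"
        "<h1>QC summary</h1>"
        f"<table><tr>{head}</tr>\n" + "\n".join(body_rows) + "\n</table>"
        "</body></html>\n"
    )
    out_path.write_text(doc)
    _write_tsv(out_path.with_suffix(".tsv"), headers, rows)
    return out_path
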