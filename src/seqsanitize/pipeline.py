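"""Cohort orchestration: manifest parsing, per-sample stage flow, outputs.

The pipeline takes three text inputs — a *target file* (one row per
sample/patient), an optional *adapter-primer file* and a key=value
*options file* — and runs every sample through the platform-appropriate
stage order:

* Sanger traces: read chromatogram -> refine ambiguous calls -> convert
  -> primer/adapter trimming -> N/quality end trimming -> read filter ->
  statistics and report.
* NGS reads: convert to Phred+33 -> demultiplex (unless already done) ->
  adapter/primer trimming -> duplicate filter -> low-complexity filter
  -> N/quality end trimming -> read filter -> pair synchronization ->
  statistics and report.

Samples are independent and may be processed concurrently; results are
identical to serial execution regardless of worker count.  A failing
sample is reported as failed in the summary without stopping the cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .basecall import AmbiguityParams, refine_ambiguous_calls
from .demux import BarcodeSpec, demultiplex
from .errors import ContractError, OptionsError, SeqSanitizeError
from .filtering import (
    FilterParams,
    fails_complexity,
    filter_duplicates,
    normalize_mate_id,
    passes_filters,
    synchronize_pairs,
)
from .qcmetrics import (
    QCStats,
    SampleResult,
    accumulate_stats,
    render_qc_report,
    render_summary_table,
)
from .records import FlowRecord, SequenceRecord
from .seqio import (
    detect_fastq_encoding,
    detect_format,
    read_chromatogram,
    read_fasta_qual,
    read_fastq,
    read_sff,
    write_fastq_sanger,
)
from .trimming import (
    AdapterSpec,
    TrimParams,
    trim_adapters_primers,
    trim_quality_ends,
    trim_terminal_ns,
)

logger = logging.getLogger(__name__)

PLATFORMS = ("sanger", "illumina", "454", "iontorrent")
_NGS_PLATFORMS = ("illumina", "454", "iontorrent")

_FORMAT_PLATFORM = {
    "ab1": "sanger",
    "scf": "sanger",
    "sff": "454",
    "fastq": "illumina",
    "fasta_qual": "454",
}


# ---------------------------------------------------------------------------
# Target file
# ---------------------------------------------------------------------------

@dataclass
class SampleRow:
    """One validated row of the target file."""

    patient_id: str
    platform: str
    read1_path: Optional[Path] = None
    read2_path: Optional[Path] = None
    trace_paths: list[Path] = field(default_factory=list)
    mid: Optional[str] = None
    demultiplexed: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def paired(self) -> bool:
        return self.read2_path is not None


@dataclass
class SampleManifest:
    rows: list[SampleRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


_KNOWN_COLUMNS = {
    "patient_id", "platform", "read1", "read2", "traces",
    "mid", "demultiplexed",
}
_TRUE_WORDS = {"1", "true", "yes", "y"}


def parse_target_file(path) -> SampleManifest:
    """Parse and validate the tab-separated target file.

    ``Patient_ID`` is mandatory and must be unique.  Recognized optional
    columns (case-insensitive): ``Platform``, ``Read1``, ``Read2``,
    ``Traces`` (semicolon-separated Sanger trace paths), ``MID``,
    ``Demultiplexed``.  Any other column is carried verbatim into the
    summary table.  Platforms are inferred from file contents when the
    column is absent; every referenced path must exist.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "patient_id" not in cols:
        raise OptionsError(f"{path}: missing mandatory Patient_ID column")

    ids = df[cols["patient_id"]].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise OptionsError(f"{path}: duplicate Patient_ID values {dupes}")
    if any(not i.strip() for i in ids):
        raise OptionsError(f"{path}: empty Patient_ID value")

    base_dir = path.parent
    rows: list[SampleRow] = []
    missing: list[str] = []

    def resolve(p: str) -> Path:
        q = Path(p)
        if not q.is_absolute():
            q = base_dir / q
        if not q.exists():
            missing.append(str(q))
        return q

    for _, rec in df.iterrows():
        def get(name: str) -> str:
            return str(rec[cols[name]]).strip() if name in cols else ""

        read1 = resolve(get("read1")) if get("read1") else None
        read2 = resolve(get("read2")) if get("read2") else None
        traces = [resolve(p.strip()) for p in get("traces").split(";")
                  if p.strip()]
        platform = get("platform").lower()
        if not platform:
            probe = traces[0] if traces else read1
            if probe is not None and probe.exists():
                platform = _FORMAT_PLATFORM.get(detect_format(probe), "")
        if platform not in PLATFORMS:
            raise OptionsError(
                f"{path}: sample {rec[cols['patient_id']]!r}: unknown or "
                f"undetectable platform {platform!r}"
            )
        if platform == "sanger" and not traces:
            if read1 is not None:
                traces = [read1]
                read1 = None
            else:
                raise OptionsError(
                    f"{path}: sample {rec[cols['patient_id']]!r}: Sanger row "
                    "needs trace paths"
                )
        if platform != "sanger" and read1 is None:
            raise OptionsError(
                f"{path}: sample {rec[cols['patient_id']]!r}: missing Read1"
            )
        mid = get("mid").upper() or None
        demux_flag = get("demultiplexed").lower()
        demultiplexed = (demux_flag in _TRUE_WORDS) if demux_flag else mid is None
        extra = {
            c: str(rec[c]).strip()
            for c in df.columns if c.lower() not in _KNOWN_COLUMNS
        }
        rows.append(SampleRow(
            patient_id=str(rec[cols["patient_id"]]).strip(),
            platform=platform,
            read1_path=read1,
            read2_path=read2,
            trace_paths=traces,
            mid=mid,
            demultiplexed=demultiplexed,
            extra=extra,
        ))
    if missing:
        raise OptionsError(f"{path}: referenced files do not exist: {missing}")
    return SampleManifest(rows)


# ---------------------------------------------------------------------------
# Adapter-primer file
# ---------------------------------------------------------------------------

def parse_adapter_file(path: Optional[str]) -> list[AdapterSpec]:
    """Parse the 4-column adapter-primer table.

    Columns: feature-type (``adapter``/``primer``), id, forward sequence,
    reverse sequence; either sequence may be empty (``-`` or blank) but
    not both.  A missing file yields the empty list, making the trimming
    stage a no-op.
    """
    if path is None:
        return []
    path = Path(path)
    if not path.exists():
        return []
    specs: list[AdapterSpec] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0].lower().replace("-", "_") == "feature_type":
            continue
        if len(fields) != 4:
            raise OptionsError(
                f"{path}:{lineno}: expected 4 tab-separated columns, "
                f"got {len(fields)}"
            )
        ftype, fid, fwd, rev = (f.strip() for f in fields)
        fwd = "" if fwd in ("-", ".") else fwd.upper()
        rev = "" if rev in ("-", ".") else rev.upper()
        try:
            specs.append(AdapterSpec(ftype.lower(), fid, fwd, rev))
        except ContractError as exc:
            raise OptionsError(f"{path}:{lineno}: {exc}") from exc
    return specs


# ---------------------------------------------------------------------------
# Options file
# ---------------------------------------------------------------------------

def _parse_bool(v: str) -> bool:
    return v.lower() in _TRUE_WORDS


#: key -> (type constructor, default).  ``filter.max_len`` uses 0 for
#: "unlimited"; ``filter.complexity_method`` accepts ``none`` to disable.
OPTION_SCHEMA: dict[str, tuple] = {
    "basecall.ratio_threshold": (float, 0.5),
    "basecall.scope": (str, "n_only"),
    "demux.max_mismatch": (int, 0),
    "trim.kmer": (int, 10),
    "trim.max_mismatch": (int, 2),
    "trim.min_overlap": (int, 5),
    "trim.q_trim": (int, 20),
    "trim.window": (int, 5),
    "filter.dup_mode": (str, "exact"),
    "filter.complexity_method": (str, "dust"),
    "filter.complexity_threshold": (str, "default"),
    "filter.min_mean_q": (float, 20.0),
    "filter.min_len": (int, 50),
    "filter.min_len_sanger": (int, 100),
    "filter.max_len": (int, 0),
    "workers": (int, 1),
    "seed": (int, 0),
}


@dataclass
class PipelineConfig:
    """Validated effective configuration (flat dotted key=value schema)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: d for k, (_t, d) in OPTION_SCHEMA.items()}
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def workers(self) -> int:
        return max(1, int(self.values["workers"]))

    def ambiguity_params(self) -> AmbiguityParams:
        return AmbiguityParams(
            ratio_threshold=self.values["basecall.ratio_threshold"],
            recall_scope=self.values["basecall.scope"],
        )

    def trim_params(self) -> TrimParams:
        return TrimParams(
            kmer=self.values["trim.kmer"],
            max_mismatch=self.values["trim.max_mismatch"],
            min_overlap=self.values["trim.min_overlap"],
            q_trim=self.values["trim.q_trim"],
            window=self.values["trim.window"],
        )

    def filter_params(self, platform: str) -> FilterParams:
        thr = self.values["filter.complexity_threshold"]
        method = self.values["filter.complexity_method"].lower()
        max_len = self.values["filter.max_len"] or None
        if platform == "sanger":
            # duplicate/contamination screening is an NGS-only stage
            method = "none"
            min_len = self.values["filter.min_len_sanger"]
        else:
            min_len = self.values["filter.min_len"]
        return FilterParams(
            dup_mode=frozenset(
                m.strip() for m in self.values["filter.dup_mode"].split(",")
                if m.strip()
            ),
            complexity_method=None if method == "none" else method,
            complexity_threshold=None if thr == "default" else float(thr),
            min_mean_q=self.values["filter.min_mean_q"],
            min_len=min_len,
            max_len=max_len,
        )

    def echo(self, path) -> Path:
        """Write the effective configuration as a reusable options file."""
        path = Path(path)
        lines = [f"{k} = {self.values[k]}" for k in sorted(self.values)]
        path.write_text("\n".join(lines) + "\n")
        return path


def parse_options(path: Optional[str]) -> PipelineConfig:
    """Parse the key=value options file against the closed schema.

    ``#`` starts a comment; omitted keys take their defaults; an unknown
    key is fatal (it is almost certainly a typo).  A missing or ``None``
    path yields the full default configuration.
    """
    values: dict = {}
    if path is not None and Path(path).exists():
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise OptionsError(f"{path}:{lineno}: expected key = value")
            key, _, raw = stripped.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in OPTION_SCHEMA:
                raise OptionsError(f"{path}:{lineno}: unknown option {key!r}")
            ctor, _default = OPTION_SCHEMA[key]
            try:
                values[key] = ctor(raw)
            except ValueError as exc:
                raise OptionsError(
                    f"{path}:{lineno}: bad value for {key!r}: {raw!r}"
                ) from exc
    return PipelineConfig(values)


# ---------------------------------------------------------------------------
# Conversion helpers
# ---------------------------------------------------------------------------

def _apply_vendor_clips(rec: FlowRecord) -> SequenceRecord:
    start, stop = rec.effective_clip()
    return SequenceRecord(
        read_id=rec.read_id,
        bases=rec.bases[start:stop],
        quals=rec.quals[start:stop],
        pair_role=rec.pair_role,
    )


def load_ngs_records(path, pair_role: str = "single",
                     qual_path=None) -> list[SequenceRecord]:
    """Read any supported NGS file into Sanger-scale records.

    SFF reads have their vendor clip points applied here (the stricter of
    the quality and adapter clips on each side), before the package's own
    trimming.  FASTQ encoding is auto-detected.
    """
    fmt = detect_format(path)
    if fmt == "sff":
        return [_apply_vendor_clips(r) for r in read_sff(path)]
    if fmt == "fastq":
        enc = detect_fastq_encoding(path)
        return [dataclasses.replace(r, pair_role=pair_role)
                for r in read_fastq(path, enc)]
    if fmt == "fasta_qual":
        if qual_path is None:
            qual_path = _guess_qual_path(path)
        return list(read_fasta_qual(path, qual_path))
    raise SeqSanitizeError(f"{path}: unsupported NGS input format {fmt!r}")


def _guess_qual_path(fasta_path) -> Path:
    fasta_path = Path(fasta_path)
    for cand in (fasta_path.with_suffix(".qual"),
                 Path(str(fasta_path) + ".qual")):
        if cand.exists():
            return cand
    raise SeqSanitizeError(f"{fasta_path}: no QUAL twin found")


def load_sanger_records(trace_paths: Sequence[Path],
                        params: AmbiguityParams) -> list[SequenceRecord]:
    """Read trace files and refine ambiguous calls (one read per file)."""
    out = []
    for p in trace_paths:
        chrom = read_chromatogram(p)
        try:
            out.append(refine_ambiguous_calls(chrom, params))
        except ContractError:
            logger.warning("%s: no trace data; skipping call refinement", p)
            out.append(SequenceRecord(
                read_id=chrom.read_id, bases=chrom.bases,
                quals=list(chrom.quals),
            ))
    return out


# ---------------------------------------------------------------------------
# Per-sample processing
# ---------------------------------------------------------------------------

def _clean_single(records: list[SequenceRecord], platform: str,
                  adapters: list[AdapterSpec], config: PipelineConfig,
                  stages: list, removed_by: dict) -> list[SequenceRecord]:
    tp = config.trim_params()
    fp = config.filter_params(platform)

    n0 = len(records)
    records = [trim_adapters_primers(r, adapters, tp) for r in records]
    stages.append(("trim_features", n0, len(records)))

    if platform != "sanger":
        records, removed = filter_duplicates(records, fp.dup_mode)
        removed_by["duplicate"] = removed_by.get("duplicate", 0) + removed
        stages.append(("filter_duplicates", n0, len(records)))
        n1 = len(records)
        kept = [r for r in records if not fails_complexity(r.bases, fp)]
        removed_by["complexity"] = removed_by.get("complexity", 0) + (n1 - len(kept))
        records = kept
        stages.append(("filter_complexity", n1, len(records)))

    n2 = len(records)
    records = [trim_quality_ends(trim_terminal_ns(r), tp.q_trim, tp.window)
               for r in records]
    stages.append(("trim_ends", n2, len(records)))

    survivors = []
    for r in records:
        ok, why = passes_filters(r, fp)
        if ok:
            survivors.append(r)
        else:
            removed_by[why] = removed_by.get(why, 0) + 1
    stages.append(("read_filter", n2, len(survivors)))
    return survivors


def _process_sample(row: SampleRow, adapters: list[AdapterSpec],
                    config: PipelineConfig, out_dir: Path) -> SampleResult:
    stages: list = []
    removed_by: dict = {}
    tp = config.trim_params()
    fp = config.filter_params(row.platform)

    if row.platform == "sanger":
        records = load_sanger_records(row.trace_paths,
                                      config.ambiguity_params())
        stages.append(("basecall+convert", len(row.trace_paths), len(records)))
        before = accumulate_stats(records)
        survivors = _clean_single(records, "sanger", adapters, config,
                                  stages, removed_by)
        after = accumulate_stats(survivors)
        fq = out_dir / f"{row.patient_id}.fastq"
        write_fastq_sanger(iter(survivors), fq)
        fastq_paths = [fq]
    elif not row.paired:
        records = load_ngs_records(row.read1_path)
        stages.append(("convert", len(records), len(records)))
        before = accumulate_stats(records)
        survivors = _clean_single(records, row.platform, adapters, config,
                                  stages, removed_by)
        after = accumulate_stats(survivors)
        fq = out_dir / f"{row.patient_id}.fastq"
        write_fastq_sanger(iter(survivors), fq)
        fastq_paths = [fq]
    else:
        fwd = load_ngs_records(row.read1_path, pair_role="forward")
        rev = load_ngs_records(row.read2_path, pair_role="reverse")
        if len(fwd) != len(rev):
            raise SeqSanitizeError(
                f"sample {row.patient_id}: R1 has {len(fwd)} reads but "
                f"R2 has {len(rev)}"
            )
        stages.append(("convert", len(fwd), len(fwd)))
        before = accumulate_stats(fwd + rev)

        n0 = len(fwd)
        fwd = [trim_adapters_primers(r, adapters, tp, "forward") for r in fwd]
        rev = [trim_adapters_primers(r, adapters, tp, "reverse") for r in rev]
        stages.append(("trim_features", n0, len(fwd)))

        pairs, removed = filter_duplicates(list(zip(fwd, rev)), fp.dup_mode,
                                           paired=True)
        removed_by["duplicate"] = removed
        stages.append(("filter_duplicates", n0, len(pairs)))

        def clean_side(side: list[SequenceRecord]) -> dict[str, SequenceRecord]:
            ok: dict[str, SequenceRecord] = {}
            for r in side:
                if fails_complexity(r.bases, fp):
                    continue
                r = trim_quality_ends(trim_terminal_ns(r), tp.q_trim, tp.window)
                passed, _why = passes_filters(r, fp)
                if passed:
                    ok[normalize_mate_id(r.read_id)] = r
            return ok

        fwd_in = [f for f, _ in pairs]
        rev_in = [r for _, r in pairs]
        fwd_ok = clean_side(fwd_in)
        rev_ok = clean_side(rev_in)
        stages.append(("read_filter", len(pairs),
                       min(len(fwd_ok), len(rev_ok))))
        out_f, out_r = synchronize_pairs(
            fwd_in, rev_in, set(fwd_ok), set(rev_ok))
        out_f = [fwd_ok[normalize_mate_id(r.read_id)] for r in out_f]
        out_r = [rev_ok[normalize_mate_id(r.read_id)] for r in out_r]
        # a pair is lost when either mate fails trimming/filtering
        removed_by["filtered_or_unpaired"] = len(pairs) - len(out_f)
        stages.append(("synchronize_pairs", len(pairs), len(out_f)))

        after = accumulate_stats(out_f + out_r)
        fq1 = out_dir / f"{row.patient_id}_R1.fastq"
        fq2 = out_dir / f"{row.patient_id}_R2.fastq"
        write_fastq_sanger(iter(out_f), fq1)
        write_fastq_sanger(iter(out_r), fq2)
        fastq_paths = [fq1, fq2]

    report = out_dir / f"{row.patient_id}_qc.html"
    render_qc_report(before, after, report)
    reads_before = before.n_reads if not row.paired else before.n_reads // 2
    reads_after = after.n_reads if not row.paired else after.n_reads // 2
    return SampleResult(
        patient_id=row.patient_id,
        reads_before=reads_before,
        reads_after=reads_after,
        gc_before=before.gc_percent,
        gc_after=after.gc_percent,
        report_before=str(report),
        report_after=str(report),
        fastq_paths=[str(p) for p in fastq_paths],
        removed_by=removed_by,
        stages=stages,
        extra=dict(row.extra),
    )


# ---------------------------------------------------------------------------
# Demultiplexing pre-pass
# ---------------------------------------------------------------------------

def _demux_prepass(manifest: SampleManifest, config: PipelineConfig,
                   out_dir: Path) -> dict[str, dict[str, int]]:
    """Split shared multiplexed input files into per-sample FASTQ.

    Rows that share a ``Read1`` path, carry a MID and are not flagged as
    demultiplexed are grouped; each group's pooled file is read once,
    split by barcode, and every row's input paths are rewritten to its
    per-sample bin.  Returns per-group bin counts (keyed by pooled path).
    """
    groups: dict[tuple, list[SampleRow]] = {}
    for row in manifest:
        if row.platform != "sanger" and row.mid and not row.demultiplexed:
            groups.setdefault((str(row.read1_path), str(row.read2_path)),
                              []).append(row)
    counts: dict[str, dict[str, int]] = {}
    mm = config["demux.max_mismatch"]
    for gi, ((r1, _r2), rows) in enumerate(sorted(groups.items())):
        table = [BarcodeSpec(row.patient_id, row.mid) for row in rows]
        ddir = out_dir / "demux" / f"pool{gi}"
        first = rows[0]
        if first.paired:
            fwd = load_ngs_records(first.read1_path, "forward")
            rev = load_ngs_records(first.read2_path, "reverse")
            counts[r1] = demultiplex(zip(fwd, rev), table, ddir,
                                     max_mismatch=mm, paired=True)
            for row in rows:
                row.read1_path = ddir / f"{row.patient_id}_R1.fastq"
                row.read2_path = ddir / f"{row.patient_id}_R2.fastq"
                row.demultiplexed = True
        else:
            reads = load_ngs_records(first.read1_path)
            counts[r1] = demultiplex(iter(reads), table, ddir,
                                     max_mismatch=mm)
            for row in rows:
                row.read1_path = ddir / f"{row.patient_id}.fastq"
                row.demultiplexed = True
    return counts


# ---------------------------------------------------------------------------
# Cohort runner
# ---------------------------------------------------------------------------

def run_pipeline(
    manifest: SampleManifest,
    adapters: list[AdapterSpec],
    config: PipelineConfig,
    out_dir,
) -> tuple[list[SampleResult], Path]:
    """Run the full QC workflow over a cohort.

    Returns the per-sample results (manifest order) and the path of the
    summary HTML.  Per-sample outputs are written under ``out_dir``; the
    effective configuration is echoed to ``effective_options.txt`` so a
    run can be reproduced from its own output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.echo(out_dir / "effective_options.txt")

    demux_counts = _demux_prepass(manifest, config, out_dir)
    for pool, cts in demux_counts.items():
        logger.info("demultiplexed %s: %s", pool, cts)

    def run_one(row: SampleRow) -> SampleResult:
        try:
            return _process_sample(row, adapters, config, out_dir)
        except Exception as exc:  # failing sample must not stop the cohort
            logger.error("sample %s failed: %s", row.patient_id, exc)
            return SampleResult(patient_id=row.patient_id, failed=True,
                                error=str(exc), extra=dict(row.extra))

    if config.workers == 1:
        results = [run_one(row) for row in manifest]
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(run_one, manifest.rows))

    summary = render_summary_table(
        results, out_dir / "summary.html",
        manifest_ids=[row.patient_id for row in manifest],
    )
    for res, row in zip(results, manifest):
        logger.info(
            "sample %s (%s): %d -> %d reads%s",
            res.patient_id, row.platform, res.reads_before, res.reads_after,
            " [FAILED]" if res.failed else "",
        )
    return results, summary
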