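"""Format detection, native readers, encoding handling, FASTQ output."""

import numpy as np
import pytest
from Bio import SeqIO as BioSeqIO

from seqsanitize import fixtures as fx
from seqsanitize import seqio
from seqsanitize.errors import (
    FormatError,
    PairingError,
    ParseError,
    RecordError,
)
from seqsanitize.records import SequenceRecord


@pytest.fixture
def reads():
    reads, _ = fx.generate_reads(5, fx.LengthModel(mean=60, sd=10), seed=11)
    return reads


class TestDetectFormat:
    def test_magic_bytes(self, tmp_path, reads):
        ab1 = fx.write_synthetic_trace(reads[0], "ab1", tmp_path / "x.bin")
        scf = fx.write_synthetic_trace(reads[0], "scf", tmp_path / "y.bin")
        sff = fx.write_synthetic_sff(reads, tmp_path / "z.bin")
        assert seqio.detect_format(ab1) == "ab1"
        assert seqio.detect_format(scf) == "scf"
        assert seqio.detect_format(sff) == "sff"

    def test_text_sniffing(self, tmp_path):
        fq = tmp_path / "a.txt"
        fq.write_text("@r1\nACGT\n+\nIIII\n")
        assert seqio.detect_format(fq) == "fastq"
        fa = tmp_path / "b.txt"
        fa.write_text(">r1\nACGT\n")
        assert seqio.detect_format(fa) == "fasta_qual"

    def test_short_and_binary_garbage_unknown(self, tmp_path):
        short = tmp_path / "short"
        short.write_bytes(b"ABC")
        assert seqio.detect_format(short) == "unknown"
        rng = np.random.default_rng(3)
        junk = tmp_path / "junk"
        junk.write_bytes(bytes(rng.integers(128, 256, size=100, dtype=np.uint8)))
        assert seqio.detect_format(junk) == "unknown"

    def test_every_fixture_format_detected(self, tmp_path, reads):
        fq33 = fx.write_fastq(reads, tmp_path / "r.fastq", 33)
        fa, qu = fx.write_fasta_qual(reads, tmp_path / "r.fa", tmp_path / "r.qual")
        assert seqio.detect_format(fq33) == "fastq"
        assert seqio.detect_format(fa) == "fasta_qual"


class TestChromatograms:
    @pytest.mark.parametrize("fmt", ["ab1", "scf"])
    def test_round_trip(self, tmp_path, reads, fmt):
        for rec in reads:
            path = fx.write_synthetic_trace(rec, fmt, tmp_path / f"{rec.read_id}.{fmt}")
            got = seqio.read_chromatogram(path)
            assert got.bases == rec.bases
            assert got.quals == rec.quals
            assert got.peak_index is not None and len(got.peak_index) == len(rec)

    def test_ab1_nonstandard_channel_order(self, tmp_path):
        # plant a G peak at base 0 with FWO_=GATC: the reader must map the
        # first data channel to G, recovering the planted signal
        rec = SequenceRecord("t", "GACT", [30, 30, 30, 30])
        path = fx.write_synthetic_trace(rec, "ab1", tmp_path / "t.ab1",
                                        channel_order="GATC")
        got = seqio.read_chromatogram(path)
        assert got.channel_order == "GATC"
        sig = got.signal_at(0)
        assert max(sig, key=sig.get) == "G"

    def test_scf_ambiguous_bases_round_trip(self, tmp_path):
        rec = SequenceRecord("t", "NNGA", [10, 20, 30, 40])
        path = fx.write_synthetic_trace(rec, "scf", tmp_path / "t.scf")
        got = seqio.read_chromatogram(path)
        assert got.bases == "NNGA"
        assert got.quals == [10, 20, 30, 40]

    def test_bad_magic_rejected(self, tmp_path):
        bad = tmp_path / "bad.ab1"
        bad.write_bytes(b"XXXX" + b"\0" * 200)
        with pytest.raises(FormatError):
            seqio.read_chromatogram(bad, "ab1")

    def test_missing_mandatory_tag_named(self, tmp_path, reads):
        path = fx.write_synthetic_trace(reads[0], "ab1", tmp_path / "t.ab1")
        data = bytearray(path.read_bytes())
        idx = data.find(b"PCON")
        data[idx:idx + 4] = b"XXXX"
        path.write_bytes(bytes(data))
        with pytest.raises(ParseError, match="PCON"):
            seqio.read_chromatogram(path)

    def test_scf_v2_rejected(self, tmp_path, reads):
        path = fx.write_synthetic_trace(reads[0], "scf", tmp_path / "t.scf")
        data = bytearray(path.read_bytes())
        data[36:40] = b"2.00"  # version field
        path.write_bytes(bytes(data))
        with pytest.raises(FormatError, match="version"):
            seqio.read_chromatogram(path)

    def test_truncated_file_rejected(self, tmp_path, reads):
        path = fx.write_synthetic_trace(reads[0], "ab1", tmp_path / "t.ab1")
        path.write_bytes(path.read_bytes()[:150])
        with pytest.raises(ParseError):
            seqio.read_chromatogram(path)


class TestSff:
    def test_round_trip_and_clip_passthrough(self, tmp_path, reads):
        clips = [(5, 0, 0, 0), (0, 0, 2, 3), (0, 0, 0, 0), (1, 4, 0, 0),
                 (2, 0, 3, 0)]
        path = fx.write_synthetic_sff(reads, tmp_path / "r.sff", clips=clips)
        got = list(seqio.read_sff(path))
        assert [g.read_id for g in got] == [r.read_id for r in reads]
        for g, r, clip in zip(got, reads, clips):
            assert g.bases == r.bases
            assert g.quals == r.quals
            assert (g.clip_qual_left, g.clip_qual_right,
                    g.clip_adapter_left, g.clip_adapter_right) == clip

    def test_agrees_with_biopython_parser(self, tmp_path, reads):
        # independent third-party parser as oracle for bases/qualities
        path = fx.write_synthetic_sff(reads, tmp_path / "r.sff")
        ours = list(seqio.read_sff(path))
        theirs = list(BioSeqIO.parse(str(path), "sff"))
        assert len(ours) == len(theirs)
        for a, b in zip(ours, theirs):
            assert a.bases == str(b.seq).upper()
            assert a.quals == b.letter_annotations["phred_quality"]

    def test_empty_sff(self, tmp_path):
        path = fx.write_synthetic_sff([], tmp_path / "e.sff")
        assert list(seqio.read_sff(path)) == []

    def test_wrong_version_rejected(self, tmp_path, reads):
        path = fx.write_synthetic_sff(reads, tmp_path / "r.sff")
        data = bytearray(path.read_bytes())
        data[7] = 2  # version word becomes 2
        path.write_bytes(bytes(data))
        with pytest.raises(FormatError, match="version"):
            list(seqio.read_sff(path))


class TestFastaQual:
    def test_pairing(self, tmp_path, reads):
        fa, qu = fx.write_fasta_qual(reads, tmp_path / "r.fa", tmp_path / "r.qual")
        got = list(seqio.read_fasta_qual(fa, qu))
        for g, r in zip(got, reads):
            assert (g.read_id, g.bases, g.quals) == (r.read_id, r.bases, r.quals)

    def test_id_mismatch(self, tmp_path):
        (tmp_path / "a.fa").write_text(">r1\nACGT\n")
        (tmp_path / "a.qual").write_text(">r2\n20 20 20 20\n")
        with pytest.raises(PairingError, match="r1.*r2"):
            list(seqio.read_fasta_qual(tmp_path / "a.fa", tmp_path / "a.qual"))

    def test_length_mismatch(self, tmp_path):
        (tmp_path / "a.fa").write_text(">r1\nACGT\n")
        (tmp_path / "a.qual").write_text(">r1\n20 20 20\n")
        with pytest.raises(RecordError, match="r1"):
            list(seqio.read_fasta_qual(tmp_path / "a.fa", tmp_path / "a.qual"))


class TestFastqEncoding:
    def test_low_code_forces_phred33(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fq.write_text("@r1\nACGT\n+\n#III\n")  # '#' == 35
        assert seqio.detect_fastq_encoding(fq) == "phred33"

    def test_all_high_codes_resolved_as_phred64(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fq.write_text("@r1\nACGT\n+\nBBhh\n")  # codes 66..104
        assert seqio.detect_fastq_encoding(fq) == "phred64"

    def test_code_59_is_phred33(self, tmp_path):
        # ';' (59) is illegal in standard phred64 data
        fq = tmp_path / "a.fastq"
        fq.write_text("@r1\nACGT\n+\n;III\n")
        assert seqio.detect_fastq_encoding(fq) == "phred33"

    def test_empty_file_rejected(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fq.write_text("")
        with pytest.raises(FormatError):
            seqio.detect_fastq_encoding(fq)


class TestFastqIO:
    def test_offset_arithmetic(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fq.write_text("@r1\nACGT\n+\n!!!I\n")
        (rec,) = seqio.read_fastq(fq, "phred33")
        assert rec.quals == [0, 0, 0, 40]
        fq.write_text("@r1\nACGT\n+\n@@@h\n")
        (rec,) = seqio.read_fastq(fq, "phred64")
        assert rec.quals == [0, 0, 0, 40]

    def test_negative_phred_rejected(self, tmp_path):
        fq = tmp_path / "a.fastq"
        fq.write_text("@r1\nACGT\n+\n  !I\n")  # ' ' == 32 < offset
        with pytest.raises(ParseError):
            list(seqio.read_fastq(fq, "phred33"))

    def test_write_example(self, tmp_path):
        rec = SequenceRecord("r1", "ACGT", [0, 20, 40, 93])
        out = tmp_path / "o.fastq"
        assert seqio.write_fastq_sanger([rec], out) == 1
        assert out.read_text() == "@r1\nACGT\n+\n!5I~\n"

    def test_write_empty_stream(self, tmp_path):
        out = tmp_path / "o.fastq"
        assert seqio.write_fastq_sanger([], out) == 0
        assert out.read_text() == ""

    def test_phred64_to_sanger_preserves_qualities(self, tmp_path):
        reads, _ = fx.generate_reads(20, seed=5)
        p64 = fx.write_fastq(reads, tmp_path / "r64.fastq", 64)
        converted = list(seqio.read_fastq(p64, "phred64"))
        out = tmp_path / "o.fastq"
        seqio.write_fastq_sanger(iter(converted), out)
        back = list(seqio.read_fastq(out, "phred33"))
        for a, r in zip(back, reads):
            assert a.quals == r.quals

    def test_write_read_identity(self, tmp_path):
        reads, _ = fx.generate_reads(30, seed=6)
        out = tmp_path / "o.fastq"
        seqio.write_fastq_sanger(iter(reads), out)
        back = list(seqio.read_fastq(out, "phred33"))
        assert [(r.read_id, r.bases, r.quals) for r in back] == \
               [(r.read_id, r.bases, r.quals) for r in reads]
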