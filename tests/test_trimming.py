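"""Adapter/primer location and the end-trimming cascade."""

import pytest

from conftest import (
    ADAPTER_SEQ,
    PRIMER_SEQ,
    make_trim_construct,
    mutate,
    oracle_locate,
    random_seq,
)
from seqsanitize.errors import ContractError
from seqsanitize.records import SequenceRecord
from seqsanitize.trimming import (
    AdapterSpec,
    TrimParams,
    locate_adapter,
    trim_adapters_primers,
    trim_cascade,
    trim_quality_ends,
    trim_terminal_ns,
)

PARAMS = TrimParams()
SPECS = [
    AdapterSpec("primer", "P1", PRIMER_SEQ),
    AdapterSpec("adapter", "A1", ADAPTER_SEQ),
]


def rec(bases: str, quals=None, role="single") -> SequenceRecord:
    return SequenceRecord("r", bases, quals or [35] * len(bases), role)


class TestLocateAdapter:
    def test_exact_appended_occurrence(self):
        read = "ACGTACGTAC" + ADAPTER_SEQ
        m = locate_adapter(read, ADAPTER_SEQ, PARAMS)
        assert (m.start, m.end, m.mismatches) == (10, 10 + len(ADAPTER_SEQ), 0)

    def test_single_substitution_same_coordinates(self, rng):
        read = "ACGTACGTAC" + mutate(rng, ADAPTER_SEQ, 1)
        m = locate_adapter(read, ADAPTER_SEQ, PARAMS)
        assert (m.start, m.end, m.mismatches) == (10, 10 + len(ADAPTER_SEQ), 1)

    def test_terminal_partial_overlap(self):
        read = "ACGTACGTACGTACGTACGT" + ADAPTER_SEQ[:6]
        m = locate_adapter(read, ADAPTER_SEQ, PARAMS)
        assert (m.start, m.end, m.mismatches) == (20, 26, 0)

    def test_overlap_below_min_overlap_ignored(self):
        read = "ACGTACGTACGTACGTACGT" + ADAPTER_SEQ[:4]
        assert locate_adapter(read, ADAPTER_SEQ, PARAMS) is None

    def test_n_counts_as_mismatch(self):
        read = ADAPTER_SEQ.replace(ADAPTER_SEQ[5], "N", 1)
        m = locate_adapter(read, ADAPTER_SEQ, PARAMS)
        assert m is not None and m.mismatches >= 1

    def test_empty_adapter_rejected(self):
        with pytest.raises(ContractError):
            locate_adapter("ACGT", "", PARAMS)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(500):
            read = random_seq(rng, int(rng.integers(15, 120)))
            if rng.random() < 0.5:  # plant an occurrence half the time
                pos = int(rng.integers(0, max(1, len(read) - 40)))
                sub = mutate(rng, ADAPTER_SEQ, int(rng.integers(0, 3)))
                read = read[:pos] + sub + read[pos + len(sub):]
            m = locate_adapter(read, ADAPTER_SEQ, PARAMS)
            o = oracle_locate(read, ADAPTER_SEQ, PARAMS)
            got = (m.start, m.end, m.mismatches) if m else None
            want = (o.start, o.end, o.mismatches) if o else None
            assert got == want, read

    def test_short_adapter_falls_back_to_full_scan(self):
        # shorter than the seed k-mer: every offset must still be examined
        params = TrimParams(min_overlap=6)
        read = "TTTTTTGGGCCCTTTTTT"
        m = locate_adapter(read, "GGGCCC", params)
        assert (m.start, m.end, m.mismatches) == (6, 12, 0)


class TestFeatureTrimming:
    def test_5prime_primer_clip(self):
        insert = "GATTACAGATTACAGATTACA"
        r = rec(PRIMER_SEQ + insert)
        out = trim_adapters_primers(r, SPECS, PARAMS)
        assert out.bases == insert

    def test_3prime_adapter_clip(self):
        insert = "GATTACAGATTACAGATTACA"
        r = rec(insert + ADAPTER_SEQ + "TTTT")
        out = trim_adapters_primers(r, SPECS, PARAMS)
        assert out.bases == insert

    def test_pure_adapter_read_becomes_empty(self):
        out = trim_adapters_primers(rec(ADAPTER_SEQ), SPECS, PARAMS)
        assert len(out) == 0

    def test_unanchored_primer_not_clipped(self):
        # primer in the middle of a read is not a 5' feature
        insert = "GATTACAGATTACA"
        r = rec(insert + PRIMER_SEQ + insert)
        out = trim_adapters_primers(r, SPECS, PARAMS)
        assert out.bases == r.bases

    def test_reverse_seq_searched_as_revcomp(self):
        from seqsanitize.records import reverse_complement
        spec = AdapterSpec("adapter", "A2", "", ADAPTER_SEQ)
        insert = "GATTACAGATTACAGATTACA"
        r = rec(insert + reverse_complement(ADAPTER_SEQ))
        out = trim_adapters_primers(r, [spec], PARAMS)
        assert out.bases == insert

    def test_reverse_mate_sees_reverse_primer_at_its_5prime(self):
        # the reverse PCR primer is the first thing a reverse mate reads
        spec = AdapterSpec("primer", "P2", "", PRIMER_SEQ)
        insert = "GATTACAGATTACAGATTACA"
        r = rec(PRIMER_SEQ + insert, role="reverse")
        out = trim_adapters_primers(r, [spec], PARAMS)
        assert out.bases == insert
        # the same spec leaves a forward mate alone (no forward sequence)
        f = rec(PRIMER_SEQ + insert, role="forward")
        # revcomp(reverse primer) is searched on forward mates; it is not
        # present here, so only the anchored literal could match -- and
        # it must not, because orientation flips the searched sequence
        out_f = trim_adapters_primers(f, [spec], PARAMS)
        assert out_f.bases == f.bases

    def test_planted_construct_recovery(self, rng):
        for _ in range(300):
            r, insert, pmm, amm = make_trim_construct(rng, PARAMS)
            out = trim_cascade(r, SPECS, PARAMS)
            assert out.bases == insert, (pmm, amm)

    def test_cascade_idempotent(self, rng):
        for _ in range(100):
            r, _, _, _ = make_trim_construct(rng, PARAMS)
            once = trim_cascade(r, SPECS, PARAMS)
            twice = trim_cascade(once, SPECS, PARAMS)
            assert (twice.bases, twice.quals) == (once.bases, once.quals)


class TestEndTrimming:
    @pytest.mark.parametrize("bases,expected", [
        ("NNACGTNN", "ACGT"),
        ("ACNGT", "ACNGT"),
        ("NNNN", ""),
        ("ACGT", "ACGT"),
    ])
    def test_terminal_ns(self, bases, expected):
        out = trim_terminal_ns(rec(bases))
        assert out.bases == expected
        assert len(out.quals) == len(expected)

    def test_per_base_quality_rule(self):
        r = rec("ACGTCGA", [2, 2, 30, 30, 30, 2, 2])
        out = trim_quality_ends(r, q_trim=20, window=1)
        assert out.quals == [30, 30, 30]
        assert out.bases == "GTC"

    def test_high_quality_read_unchanged(self):
        r = rec("ACGT", [30, 25, 22, 40])
        assert trim_quality_ends(r, 20, 1) is r

    def test_interior_low_quality_kept(self):
        r = rec("ACG", [30, 2, 30])
        out = trim_quality_ends(r, 20, 1)
        assert out.quals == [30, 2, 30]

    def test_windowed_mean_rule(self):
        # window of 2: terminal pair mean 16 < 20 drops bases until the
        # window mean clears the threshold
        r = rec("ACGTAC", [30, 30, 30, 30, 2, 30])
        out = trim_quality_ends(r, q_trim=20, window=2)
        assert out.quals == [30, 30, 30, 30]

    def test_all_low_quality_empties_read(self):
        r = rec("ACGT", [2, 2, 2, 2])
        out = trim_quality_ends(r, 20, 5)
        assert len(out) == 0

    def test_trimming_never_lengthens(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 80))
            r = rec(random_seq(rng, n),
                    [int(q) for q in rng.integers(0, 45, size=n)])
            out = trim_quality_ends(trim_terminal_ns(r), 20, 5)
            assert len(out) <= len(r)
            assert len(out.bases) == len(out.quals)
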