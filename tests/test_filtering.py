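"""Duplicate removal, complexity scoring, thresholds, pair consistency."""

import itertools

import pytest

from conftest import oracle_duplicates, oracle_dust, oracle_entropy, random_seq
from seqsanitize.errors import ContractError, PairingError
from seqsanitize.filtering import (
    FilterParams,
    complexity_score,
    filter_duplicates,
    normalize_mate_id,
    passes_filters,
    synchronize_pairs,
)
from seqsanitize.records import SequenceRecord, reverse_complement


def rec(bases: str, rid: str = "r", quals=None) -> SequenceRecord:
    return SequenceRecord(rid, bases, quals or [30] * len(bases))


class TestDuplicates:
    def test_exact_collapses_to_first(self):
        reads = [rec("ACGTACGT", f"r{i}") for i in range(3)]
        kept, removed = filter_duplicates(reads, {"exact"})
        assert [k.read_id for k in kept] == ["r0"]
        assert removed == 2

    def test_prefix_of_kept_longer_read_removed(self):
        reads = [rec("ACGTACGT", "long"), rec("ACGTAC", "short")]
        kept, removed = filter_duplicates(reads, {"exact", "prefix"})
        assert [k.read_id for k in kept] == ["long"]
        assert removed == 1

    def test_prefix_arriving_first_is_kept(self):
        reads = [rec("ACGTAC", "short"), rec("ACGTACGT", "long")]
        kept, _ = filter_duplicates(reads, {"exact", "prefix"})
        assert [k.read_id for k in kept] == ["short", "long"]

    def test_revcomp_duplicate_removed(self):
        reads = [rec("AAGC", "a"), rec(reverse_complement("AAGC"), "b")]
        kept, removed = filter_duplicates(reads, {"exact", "revcomp"})
        assert [k.read_id for k in kept] == ["a"]
        assert removed == 1

    def test_paired_keyed_on_concatenation(self):
        pairs = [
            (rec("ACGT", "p1"), rec("TTTT", "p1")),
            (rec("ACGT", "p2"), rec("TTTT", "p2")),  # same pair content
            (rec("ACGT", "p3"), rec("CCCC", "p3")),  # differs in mate 2
        ]
        kept, removed = filter_duplicates(pairs, {"exact"}, paired=True)
        assert [f.read_id for f, _ in kept] == ["p1", "p3"]
        assert removed == 1

    @pytest.mark.parametrize("modes", [
        set(c) for n in range(1, 4)
        for c in itertools.combinations(["exact", "prefix", "revcomp"], n)
    ])
    def test_matches_pairwise_oracle(self, modes, rng):
        # short alphabet-limited reads force plenty of collisions
        seqs = ["".join(rng.choice(list("AC"), size=int(rng.integers(3, 8))))
                for _ in range(200)]
        reads = [rec(s, f"r{i}") for i, s in enumerate(seqs)]
        kept, removed = filter_duplicates(reads, modes)
        want = oracle_duplicates(seqs, modes)
        assert [k.read_id for k in kept] == [f"r{i}" for i in want]
        assert removed == len(seqs) - len(want)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ContractError):
            filter_duplicates([], {"fuzzy"})


class TestComplexity:
    def test_homopolymer_extremes(self):
        assert complexity_score("A" * 10, "dust") == 100.0
        assert complexity_score("A" * 10, "entropy") == 0.0

    def test_all_distinct_3mers_score_zero_dust(self):
        # de Bruijn-style sequence: every 3-mer occurs once
        seq = "AACAGATCCGCTGGTTA"
        words = [seq[i:i + 3] for i in range(len(seq) - 2)]
        assert len(set(words)) == len(words)
        assert complexity_score(seq, "dust") == 0.0

    def test_short_sequences_score_zero(self):
        assert complexity_score("AC", "dust") == 0.0
        assert complexity_score("ACG", "dust") == 0.0

    def test_non_iupac_rejected(self):
        with pytest.raises(ContractError):
            complexity_score("ACXT", "dust")

    @pytest.mark.parametrize("method,oracle", [
        ("dust", oracle_dust), ("entropy", oracle_entropy),
    ])
    def test_matches_3mer_counting_oracle(self, method, oracle, rng):
        for _ in range(500):
            n = int(rng.integers(3, 100))
            # mixed alphabet sizes generate the whole score range
            k = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list("ACGT")[:k], size=n))
            assert complexity_score(seq, method) == pytest.approx(oracle(seq))

    def test_reversal_plus_complement_oracle_equivalence(self, rng):
        # dust is not generally invariant under reverse complement, but
        # implementation and oracle must transform identically
        for _ in range(50):
            seq = random_seq(rng, 40)
            rc = reverse_complement(seq)
            assert complexity_score(rc, "dust") == pytest.approx(oracle_dust(rc))


class TestThresholds:
    def test_boundary_equality_passes(self):
        params = FilterParams(min_mean_q=20, min_len=1, complexity_method=None)
        ok, why = passes_filters(rec("ACGT", quals=[20] * 4), params)
        assert ok and why is None

    def test_mean_quality_arithmetic(self):
        params = FilterParams(min_mean_q=20, min_len=1)
        ok, why = passes_filters(rec("AC", quals=[10, 20]), params)
        assert not ok and why == "min_mean_q"

    def test_length_bounds(self):
        params = FilterParams(min_len=50, min_mean_q=0)
        ok, why = passes_filters(rec("A" * 49, quals=[30] * 49), params)
        assert not ok and why == "min_len"
        params = FilterParams(min_len=1, max_len=10, min_mean_q=0,
                              complexity_method=None)
        ok, why = passes_filters(rec("ACGTACGTACGT"), params)
        assert not ok and why == "max_len"

    def test_low_complexity_fails(self):
        params = FilterParams(min_len=1, min_mean_q=0)
        ok, why = passes_filters(rec("A" * 60), params)
        assert not ok and why == "complexity"

    def test_full_accounting_on_synthetic_reads(self, rng):
        params = FilterParams(min_mean_q=20, min_len=30, max_len=80)
        reads = []
        for i in range(5000):
            n = int(rng.integers(10, 100))
            if rng.random() < 0.1:
                bases = "A" * n  # planted low-complexity
            else:
                bases = random_seq(rng, n)
            quals = [int(q) for q in rng.integers(5, 45, size=n)]
            reads.append(rec(bases, f"r{i}", quals))
        kept = 0
        removed: dict[str, int] = {}
        for r in reads:
            ok, why = passes_filters(r, params)
            if ok:
                kept += 1
                assert sum(r.quals) / len(r) >= 20
                assert 30 <= len(r) <= 80
            else:
                removed[why] = removed.get(why, 0) + 1
        assert kept + sum(removed.values()) == len(reads)
        assert removed.get("complexity", 0) > 0


class TestPairSync:
    def mates(self, ids, side):
        return [rec("ACGT", f"{i}/{1 if side == 'f' else 2}") for i in ids]

    def test_intersection_rule(self):
        fwd = self.mates(["r1", "r2", "r3"], "f")
        rev = self.mates(["r1", "r2", "r3"], "r")
        out_f, out_r = synchronize_pairs(fwd, rev, {"r1", "r2", "r3"},
                                         {"r1", "r3"})
        ids_f = [normalize_mate_id(r.read_id) for r in out_f]
        ids_r = [normalize_mate_id(r.read_id) for r in out_r]
        assert ids_f == ids_r == ["r1", "r3"]

    def test_disjoint_survivors_empty_output(self):
        fwd = self.mates(["r1", "r2"], "f")
        rev = self.mates(["r1", "r2"], "r")
        out_f, out_r = synchronize_pairs(fwd, rev, {"r1"}, {"r2"})
        assert out_f == [] and out_r == []

    def test_identical_survivors_preserve_order(self):
        ids = ["r3", "r1", "r2"]
        fwd = self.mates(ids, "f")
        rev = self.mates(ids, "r")
        out_f, out_r = synchronize_pairs(fwd, rev, set(ids), set(ids))
        assert [normalize_mate_id(r.read_id) for r in out_f] == ids
        assert [normalize_mate_id(r.read_id) for r in out_r] == ids

    def test_duplicate_id_within_side_rejected(self):
        fwd = self.mates(["r1", "r1"], "f")
        rev = self.mates(["r1", "r2"], "r")
        with pytest.raises(PairingError, match="r1"):
            synchronize_pairs(fwd, rev, {"r1"}, {"r1"})

    @pytest.mark.parametrize("raw,normalized", [
        ("read7/1", "read7"),
        ("read7/2", "read7"),
        ("M01234:55:000-A1 1:N:0:ACGT", "M01234:55:000-A1"),
        ("plain", "plain"),
    ])
    def test_mate_id_normalization(self, raw, normalized):
        assert normalize_mate_id(raw) == normalized
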