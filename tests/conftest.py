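"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force
(all-offsets alignment, O(n^2) pairwise duplicate comparison, direct
3-mer counting) so the package's optimized implementations are checked
against code that shares none of their logic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from math import ceil

import numpy as np
import pytest
from hypothesis import settings

from seqsanitize.records import SequenceRecord, reverse_complement
from seqsanitize.trimming import TrimParams

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

# Realistic fixed feature sequences: a TruSeq-style adapter and an
# M13-style sequencing primer.  Both are long enough that k-mer seeding
# (kmer=10) is guaranteed to find any occurrence with <= 2 substitutions.
ADAPTER_SEQ = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
PRIMER_SEQ = "TGTAAAACGACGGCCAGTGAATTGTAATACG"


# ---------------------------------------------------------------------------
# Brute-force adapter-location oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleMatch:
    start: int
    end: int
    mismatches: int


def oracle_locate(read: str, adapter: str, params: TrimParams) -> OracleMatch | None:
    """All-offsets ungapped alignment, no seeding, no early exit."""
    read, adapter = read.upper(), adapter.upper()
    L, A = len(read), len(adapter)
    best = None
    for off in range(0, L - params.min_overlap + 1):
        length = min(A, L - off)
        if length < A and length < params.min_overlap:
            continue
        mm = sum(1 for i in range(length) if read[off + i] != adapter[i])
        budget = ceil(params.max_mismatch * length / A)
        if length == A:
            budget = params.max_mismatch
        if mm <= budget:
            cand = (mm, off, length)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    mm, off, length = best
    return OracleMatch(off, off + length, mm)


# ---------------------------------------------------------------------------
# O(n^2) duplicate-filter oracle
# ---------------------------------------------------------------------------

def oracle_duplicates(seqs: list[str], modes: set[str]) -> list[int]:
    """Indices of surviving reads under pairwise comparison to all kept."""
    kept: list[int] = []
    for i, s in enumerate(seqs):
        dup = False
        for j in kept:
            t = seqs[j]
            if "exact" in modes and s == t:
                dup = True
            if "prefix" in modes and len(s) <= len(t) and t.startswith(s):
                dup = True
            if "revcomp" in modes and s == reverse_complement(t):
                dup = True
            if dup:
                break
        if not dup:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# Direct 3-mer complexity oracles
# ---------------------------------------------------------------------------

def oracle_dust(seq: str) -> float:
    words = [seq[i:i + 3] for i in range(len(seq) - 2)]
    if not words:
        return 0.0
    counts = Counter(words)
    raw = sum(c * (c - 1) / 2 for c in counts.values())
    n = len(words)
    maxraw = n * (n - 1) / 2
    return 100.0 * raw / maxraw if maxraw else 0.0


def oracle_entropy(seq: str) -> float:
    words = [seq[i:i + 3] for i in range(len(seq) - 2)]
    if not words:
        return 0.0
    counts = Counter(words)
    n = len(words)
    denom = math.log(min(n, 64))
    if denom == 0:
        return 0.0
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return max(0.0, 100.0 * h / denom)


# ---------------------------------------------------------------------------
# Planted trimming constructs
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


def make_trim_construct(rng: np.random.Generator, params: TrimParams,
                        insert_len: int = 60) -> tuple[SequenceRecord, str, int, int]:
    """primer + insert + adapter read with planted substitution counts.

    The insert is rejection-sampled so that neither feature matches
    anywhere inside it under ``params`` (otherwise the planted truth
    would be ambiguous: a trimmer has no way to distinguish a real
    read-through from an insert that happens to contain the adapter).
    Returns ``(record, insert, primer_mm, adapter_mm)``.
    """
    from seqsanitize.trimming import locate_adapter

    while True:
        insert = random_seq(rng, insert_len)
        if locate_adapter(insert, ADAPTER_SEQ, params) is not None:
            continue
        pm = locate_adapter(insert, PRIMER_SEQ, params)
        if pm is not None:
            continue
        break
    primer_mm = int(rng.integers(0, params.max_mismatch + 1))
    adapter_mm = int(rng.integers(0, params.max_mismatch + 1))
    primer = mutate(rng, PRIMER_SEQ, primer_mm)
    adapter = mutate(rng, ADAPTER_SEQ, adapter_mm)
    bases = primer + insert + adapter
    rec = SequenceRecord("construct", bases, [35] * len(bases))
    return rec, insert, primer_mm, adapter_mm


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
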