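"""Read-level filters: duplicates, low complexity, thresholds, pair sync.

PCR over-amplification produces duplicate reads that inflate allele
frequencies downstream; repetitive or adapter-dimer junk shows up as
low-complexity sequence.  This module removes both, applies the final
quality/length thresholds, and restores paired-end consistency: a pair
survives only if *both* mates survive, so the forward and reverse output
files always contain the same reads in the same order.

Duplicate detection is streaming and keeps the first occurrence of each
duplicate group.  Low complexity is scored on overlapping 3-mers by
either the DUST self-similarity statistic or normalized Shannon entropy,
both on a 0–100 scale.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ContractError, PairingError
from .records import IUPAC_ALPHABET, SequenceRecord, reverse_complement

DUP_MODES = ("exact", "prefix", "revcomp")

#: Reads scoring above this DUST value (0-100) fail the complexity filter.
DUST_FAIL_ABOVE = 7.0
#: Reads scoring below this entropy value (0-100) fail the complexity filter.
ENTROPY_FAIL_BELOW = 30.0


@dataclass
class FilterParams:
    """Thresholds for the read-filtering stage.

    dup_mode:
        Subset of ``{"exact", "prefix", "revcomp"}``; default exact only.
    complexity_method:
        ``"dust"`` (fails when score > threshold), ``"entropy"`` (fails
        when score < threshold) or ``None`` to disable the check.
    complexity_threshold:
        0-100; defaults to 7 for dust and 30 for entropy when left None.
    min_mean_q:
        Minimum mean Phred quality per read (default 20).
    min_len / max_len:
        Inclusive length bounds; ``max_len=None`` means unlimited.
        Short-read platforms default to 50; Sanger reads are longer and
        default to 100 in the pipeline's per-platform override.
    """

    dup_mode: frozenset = frozenset({"exact"})
    complexity_method: Optional[str] = "dust"
    complexity_threshold: Optional[float] = None
    min_mean_q: float = 20.0
    min_len: int = 50
    max_len: Optional[int] = None

    def __post_init__(self) -> None:
        self.dup_mode = frozenset(self.dup_mode)
        bad = self.dup_mode - set(DUP_MODES)
        if bad:
            raise ContractError(f"unknown dup_mode values {sorted(bad)}")
        if self.complexity_method not in (None, "dust", "entropy"):
            raise ContractError(
                f"unknown complexity_method {self.complexity_method!r}"
            )
        if self.max_len is not None and self.min_len > self.max_len:
            raise ContractError("min_len must be <= max_len")
        if self.complexity_threshold is not None and not (
                0 <= self.complexity_threshold <= 100):
            raise ContractError("complexity_threshold must be in [0, 100]")

    @property
    def effective_complexity_threshold(self) -> Optional[float]:
        if self.complexity_method is None:
            return None
        if self.complexity_threshold is not None:
            return self.complexity_threshold
        return DUST_FAIL_ABOVE if self.complexity_method == "dust" \
            else ENTROPY_FAIL_BELOW


# ---------------------------------------------------------------------------
# Duplicate filtering
# ---------------------------------------------------------------------------

class _DuplicateScreen:
    """Streaming membership test against all previously kept sequences."""

    def __init__(self, dup_mode: frozenset):
        self.dup_mode = dup_mode
        self.exact: set[str] = set()
        self.prefixes: set[str] = set()
        self.revcomps: set[str] = set()

    def is_duplicate(self, seq: str) -> bool:
        if "exact" in self.dup_mode and seq in self.exact:
            return True
        if "prefix" in self.dup_mode and seq in self.prefixes:
            return True
        if "revcomp" in self.dup_mode and seq in self.revcomps:
            return True
        return False

    def keep(self, seq: str) -> None:
        self.exact.add(seq)
        if "prefix" in self.dup_mode:
            for i in range(1, len(seq) + 1):
                self.prefixes.add(seq[:i])
        if "revcomp" in self.dup_mode:
            self.revcomps.add(reverse_complement(seq))


def filter_duplicates(
    reads: Iterable,
    dup_mode: Iterable[str] = ("exact",),
    paired: bool = False,
) -> tuple[list, int]:
    """Remove duplicate reads, keeping the first occurrence of each group.

    Modes (combinable): ``exact`` removes reads with identical base
    strings; ``prefix`` removes a read equal to a 5' prefix of an
    already-kept longer read; ``revcomp`` removes a read identical to the
    reverse complement of a kept read.  Paired streams (``paired=True``,
    items are ``(fwd, rev)`` tuples) are keyed on the concatenation of
    both mates.  Returns ``(survivors, removed_count)``.
    """
    mode = frozenset(dup_mode)
    bad = mode - set(DUP_MODES)
    if bad:
        raise ContractError(f"unknown dup_mode values {sorted(bad)}")
    screen = _DuplicateScreen(mode)
    kept = []
    removed = 0
    for item in reads:
        if paired:
            key = item[0].bases + item[1].bases
        else:
            key = item.bases
        if screen.is_duplicate(key):
            removed += 1
        else:
            screen.keep(key)
            kept.append(item)
    return kept, removed


# ---------------------------------------------------------------------------
# Low-complexity scoring
# ---------------------------------------------------------------------------

def complexity_score(bases: str, method: str = "dust") -> float:
    """Low-complexity score of a sequence on a 0-100 scale.

    ``dust``: over the ``L - 2`` overlapping 3-mers, the self-similarity
    ``raw = sum_t c_t (c_t - 1) / 2`` is normalized by its maximum
    ``(L-2)(L-3)/2`` (a homopolymer scores 100, all-distinct 3-mers 0).

    ``entropy``: Shannon entropy of the 3-mer distribution normalized by
    ``log(min(L-2, 64))`` and scaled to 0-100 (a homopolymer scores 0,
    maximally diverse 3-mers 100).

    Sequences shorter than 3 score 0 under both methods.
    """
    seq = bases.upper()
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ContractError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    n_words = len(seq) - 2
    if n_words < 1:
        return 0.0
    counts = Counter(seq[i:i + 3] for i in range(n_words))
    if method == "dust":
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        maxraw = n_words * (n_words - 1) / 2
        return 100.0 * raw / maxraw if maxraw > 0 else 0.0
    if method == "entropy":
        denom = math.log(min(n_words, 64))
        if denom == 0:  # single 3-mer: no diversity measurable
            return 0.0
        h = -sum((c / n_words) * math.log(c / n_words) for c in counts.values())
        return max(0.0, 100.0 * h / denom)
    raise ContractError(f"unknown complexity method {method!r}")


def fails_complexity(bases: str, params: FilterParams) -> bool:
    """Whether a sequence fails the configured low-complexity screen."""
    thr = params.effective_complexity_threshold
    if thr is None:
        return False
    score = complexity_score(bases, params.complexity_method)
    if params.complexity_method == "dust":
        return score > thr
    return score < thr


# ---------------------------------------------------------------------------
# Threshold filter
# ---------------------------------------------------------------------------

def passes_filters(record: SequenceRecord,
                   params: FilterParams) -> tuple[bool, Optional[str]]:
    """Apply the final read thresholds.

    Returns ``(True, None)`` when the read passes mean quality, length
    bounds and the complexity screen; otherwise ``(False, criterion)``
    with the first failed criterion (``min_mean_q``, ``min_len``,
    ``max_len`` or ``complexity``) for QC accounting.
    """
    if len(record) == 0:
        return False, "min_len"
    if sum(record.quals) / len(record.quals) < params.min_mean_q:
        return False, "min_mean_q"
    if len(record) < params.min_len:
        return False, "min_len"
    if params.max_len is not None and len(record) > params.max_len:
        return False, "max_len"
    if fails_complexity(record.bases, params):
        return False, "complexity"
    return True, None


# ---------------------------------------------------------------------------
# Paired-end consistency
# ---------------------------------------------------------------------------

_MATE_SUFFIX = re.compile(r"/[12]$")


def normalize_mate_id(read_id: str) -> str:
    """Strip mate decorations: trailing ``/1``/``/2`` and Casava suffixes."""
    base = read_id.split()[0] if read_id else read_id
    return _MATE_SUFFIX.sub("", base)


def synchronize_pairs(
    fwd: Sequence[SequenceRecord],
    rev: Sequence[SequenceRecord],
    fwd_survivors: set[str],
    rev_survivors: set[str],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep only pairs whose both mates survived, in original order.

    ``fwd``/``rev`` are the original per-side streams; survivor sets hold
    normalized ids.  If one read of a pair is lost to trimming or
    filtering, its mate is excluded too, so both output id sequences are
    identical.  A duplicate id within one side is an error.
    """
    def index(side, name):
        seen = {}
        for rec in side:
            key = normalize_mate_id(rec.read_id)
            if key in seen:
                raise PairingError(f"duplicate read id {key!r} in {name} stream")
            seen[key] = rec
        return seen

    fwd_by_id = index(fwd, "forward")
    rev_by_id = index(rev, "reverse")
    keep = {nid for nid in fwd_survivors if nid in rev_survivors}
    out_f, out_r = [], []
    for rec in fwd:
        nid = normalize_mate_id(rec.read_id)
        if nid in keep and nid in rev_by_id:
            out_f.append(rec)
            out_r.append(rev_by_id[nid])
    return out_f, out_r
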