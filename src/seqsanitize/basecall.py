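"""Refinement of ambiguous Sanger base calls from trace signals.

Capillary base callers emit ``N`` wherever the chromatogram signal is not
clearly attributable to a single dye.  At such positions the trace often
shows two (or three) channels of comparable height — e.g. an A and a G
peak of similar size — and the more informative call is the IUPAC
ambiguity code for exactly that set of competing channels (``R`` for A/G,
``Y`` for C/T, and so on).

The rule implemented here is a transparent peak-height ratio: at a base's
peak position, every channel whose signal is at least ``ratio_threshold``
times the strongest channel is "competing", and the call becomes the
IUPAC code of the competing set.  This is a deliberately simple,
deterministic stand-in for proprietary trace re-callers; it does not
attempt statistical heterozygote detection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .records import IUPAC_CODE_FOR_SET, ChromatogramRecord, SequenceRecord


@dataclass
class AmbiguityParams:
    """Settings for trace-based call refinement.

    ratio_threshold:
        A secondary channel competes when its signal at the peak position
        is ``>= ratio_threshold *`` the primary signal.  In ``(0, 1]``;
        default 0.5.
    recall_scope:
        ``"n_only"`` (default) re-examines only positions called ``N``;
        ``"all_positions"`` re-examines every base.
    """

    ratio_threshold: float = 0.5
    recall_scope: str = "n_only"

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio_threshold <= 1.0):
            raise ValueError(
                f"ratio_threshold must be in (0, 1], got {self.ratio_threshold}"
            )
        if self.recall_scope not in ("n_only", "all_positions"):
            raise ValueError(f"bad recall_scope {self.recall_scope!r}")


def competing_bases(signals: dict[str, int], ratio_threshold: float) -> frozenset:
    """The set of channels within ``ratio_threshold`` of the strongest one.

    All-zero signals give the empty set (no information at this position).
    """
    top = max(signals.values())
    if top <= 0:
        return frozenset()
    return frozenset(
        b for b, s in signals.items() if s >= ratio_threshold * top
    )


def refine_ambiguous_calls(
    chrom: ChromatogramRecord,
    params: AmbiguityParams | None = None,
) -> SequenceRecord:
    """Re-call ambiguous positions of a chromatogram read.

    For each position in scope the four channel signals at that base's
    peak are compared; the call becomes the IUPAC code of the competing
    channel set (one base -> that base, two -> R/Y/S/W/K/M, three ->
    B/D/H/V, four or no signal -> N).  Qualities and read length are
    preserved; out-of-scope positions are untouched.

    Raises :class:`ContractError` when the record carries no trace or peak
    data — the caller should skip refinement for such reads.
    """
    params = params or AmbiguityParams()
    if chrom.traces is None or chrom.peak_index is None:
        raise ContractError(
            f"record {chrom.read_id!r} has no trace/peak data; "
            "skip base-call refinement for this read"
        )
    new_bases = list(chrom.bases)
    for i, base in enumerate(new_bases):
        if params.recall_scope == "n_only" and base != "N":
            continue
        comp = competing_bases(chrom.signal_at(i), params.ratio_threshold)
        if not comp:
            new_bases[i] = "N"
        else:
            new_bases[i] = IUPAC_CODE_FOR_SET[comp]
    return SequenceRecord(
        read_id=chrom.read_id,
        bases="".join(new_bases),
        quals=list(chrom.quals),
        pair_role=chrom.pair_role,
    )
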