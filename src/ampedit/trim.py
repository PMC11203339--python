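"""Boundary determination: anchor merged reads to the reference termini.

The first and last ``anchor_len`` (default 15) bases of the reference are
located in each aggregated read by approximate matching, allowing a
combined budget of ``max_errors`` (default 2) mismatches or indels per
anchor; bases outside the anchored interval are trimmed, so surviving
reads begin and end with the reference boundaries. Reads in which either
anchor cannot be placed are discarded into an "unanchored" bin that is
reported, never silently dropped.

Anchors are taken from the mutant reference; the HDR allele shares both
15-bp termini (the edit is interior), so anchoring is allele-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .amplicon import NucleotideSequence
from .merge import MergedRead

__all__ = ["TrimmedRead", "TrimStats", "locate_anchor", "trim_to_boundaries", "trim_reads"]


@dataclass
class TrimmedRead:
    id: str
    bases: str
    qualities: object = None


@dataclass
class TrimStats:
    n_input: int = 0
    n_anchored: int = 0
    n_unanchored: int = 0


def locate_anchor(
    merged: MergedRead | str,
    anchor: NucleotideSequence | str,
    end: str,
    max_errors: int = 2,
) -> int | None:
    """Best approximate occurrence of a reference-terminus anchor.

    Finds the minimum-error placement of ``anchor`` inside the merged
    sequence (mismatches and indels each count one error, up to
    ``max_errors``). Returns the 1-based merged-coordinate of the anchor's
    first base for ``end='five_prime'`` or of its last base for
    ``end='three_prime'``; ties between equally good placements are broken
    toward the outermost one (leftmost for 5', rightmost for 3').
    Returns None when no placement qualifies.
    """
    if end not in {"five_prime", "three_prime"}:
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    target = merged.bases if hasattr(merged, "bases") else merged
    query = anchor.bases if isinstance(anchor, NucleotideSequence) else anchor
    if not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations", k=max_errors)
    if res["editDistance"] < 0:
        return None
    locs = res["locations"]
    if end == "five_prime":
        return min(s for s, _ in locs) + 1
    return max(e for _, e in locs) + 1


def trim_to_boundaries(
    merged: MergedRead,
    reference: NucleotideSequence,
    anchor_len: int = 15,
    max_errors: int = 2,
) -> TrimmedRead | None:
    """Trim a merged read to the reference boundaries, or reject it.

    Returns the subsequence from the 5' anchor's first base to the 3'
    anchor's last base, or None when either anchor is missing (or the two
    anchors cross, which indicates a garbled read).
    """
    ref = reference.bases
    start = locate_anchor(merged, ref[:anchor_len], "five_prime", max_errors)
    stop = locate_anchor(merged, ref[-anchor_len:], "three_prime", max_errors)
    if start is None or stop is None or stop < start:
        return None
    quals = merged.qualities[start - 1 : stop] if merged.qualities is not None else None
    return TrimmedRead(id=merged.id, bases=merged.bases[start - 1 : stop], qualities=quals)


def trim_reads(
    merged_reads,
    reference: NucleotideSequence,
    anchor_len: int = 15,
    max_errors: int = 2,
) -> tuple[list[TrimmedRead], TrimStats]:
    stats = TrimStats()
    out = []
    for m in merged_reads:
        stats.n_input += 1
        t = trim_to_boundaries(m, reference, anchor_len, max_errors)
        if t is None:
            stats.n_unanchored += 1
        else:
            stats.n_anchored += 1
            out.append(t)
    return out, stats
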