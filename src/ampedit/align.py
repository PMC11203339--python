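"""Global alignment of aggregated reads to the reference, and variant calls.

Second phase of the amplicon pipeline. Reads are aligned globally under the
scheme match = 1, mismatch = 0, gapOpen = -2, gapExtension = 0. Because a
mismatch is free relative to a match (it merely forfeits the +1) and a gap
of any length costs a flat 2, this scoring favours one long gap over
several small gaps or runs of mismatches — the behaviour wanted for NHEJ
deletion alleles.

Since gap length is free, many co-optimal placements of a gap exist inside
repeats. Alignments are made reproducible in two steps: a deterministic DP
traceback (see ``_dp``), and homopolymer/repeat left-alignment of the
resulting insertion/deletion events in :func:`extract_variants`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .amplicon import NucleotideSequence, encode
from ._dp import align_kernel

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "VariantEvent",
    "global_align",
    "extract_variants",
]

_OP_NAMES = ("match", "mismatch", "insertion", "deletion")
_QUERY_OPS = {"match", "mismatch", "insertion"}
_REF_OPS = {"match", "mismatch", "deletion"}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment reward/penalty scores; defaults are the pipeline's own."""

    match: int = 1
    mismatch: int = 0
    gap_open: int = -2
    gap_extension: int = 0


@dataclass
class AlignmentResult:
    """A global alignment as an ordered run-length operation list."""

    ops: list[tuple[str, int]]
    score: int
    query_name: str = ""
    reference_name: str = ""

    def query_length(self) -> int:
        return sum(n for op, n in self.ops if op in _QUERY_OPS)

    def reference_length(self) -> int:
        return sum(n for op, n in self.ops if op in _REF_OPS)

    def recompute_score(self, scheme: ScoringScheme) -> int:
        score = 0
        for op, n in self.ops:
            if op == "match":
                score += scheme.match * n
            elif op == "mismatch":
                score += scheme.mismatch * n
            else:
                score += scheme.gap_open + scheme.gap_extension * (n - 1)
        return score

    def cigar(self, extended: bool = False) -> str:
        """CIGAR string; M/I/D by default, =/X/I/D when ``extended``."""
        sym = (
            {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}
            if extended
            else {"match": "M", "mismatch": "M", "insertion": "I", "deletion": "D"}
        )
        out, prev, run = [], None, 0
        for op, n in self.ops:
            s = sym[op]
            if s == prev:
                run += n
            else:
                if prev is not None:
                    out.append(f"{run}{prev}")
                prev, run = s, n
        if prev is not None:
            out.append(f"{run}{prev}")
        return "".join(out)


@dataclass(frozen=True)
class VariantEvent:
    """One insertion/deletion/substitution event in reference coordinates.

    ``reference_position`` is 1-based; for insertions it is the reference
    base after which the inserted sequence sits (0 = before the first
    base). Indels are left-aligned within homopolymer/repeat context.
    """

    type: str
    reference_position: int
    size: int
    alt_sequence: str = ""

    def span(self) -> tuple[int, int]:
        """Inclusive reference interval touched by this event."""
        if self.type == "deletion":
            return self.reference_position, self.reference_position + self.size - 1
        if self.type == "substitution":
            return self.reference_position, self.reference_position + self.size - 1
        return self.reference_position, self.reference_position + 1


def global_align(
    query: NucleotideSequence | str,
    reference: NucleotideSequence | str,
    scheme: ScoringScheme = ScoringScheme(),
) -> AlignmentResult:
    """Optimal global alignment of ``query`` against ``reference``.

    N scores as a mismatch against everything (including N), so fill bases
    from unmerged read ends can never fabricate matches. The traceback is
    deterministic; see the module docstring for the tie-break rules.
    """
    qname = getattr(query, "name", "")
    rname = getattr(reference, "name", "")
    qb = query.bases if isinstance(query, NucleotideSequence) else query.upper()
    rb = reference.bases if isinstance(reference, NucleotideSequence) else reference.upper()
    if not qb or not rb:
        raise ValueError("global_align requires non-empty sequences")
    score, ops = align_kernel(
        encode(qb),
        encode(rb),
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extension,
    )
    runs: list[tuple[str, int]] = []
    for code in ops:
        name = _OP_NAMES[code]
        if runs and runs[-1][0] == name:
            runs[-1] = (name, runs[-1][1] + 1)
        else:
            runs.append((name, 1))
    return AlignmentResult(ops=runs, score=int(score), query_name=qname, reference_name=rname)


def _merge_adjacent(events: list[VariantEvent]) -> list[VariantEvent]:
    merged: list[VariantEvent] = []
    for ev in events:
        if merged:
            prev = merged[-1]
            if (
                prev.type == ev.type == "deletion"
                and ev.reference_position == prev.reference_position + prev.size
            ):
                merged[-1] = VariantEvent(
                    "deletion", prev.reference_position, prev.size + ev.size
                )
                continue
            if (
                prev.type == ev.type == "insertion"
                and ev.reference_position == prev.reference_position
            ):
                merged[-1] = VariantEvent(
                    "insertion",
                    prev.reference_position,
                    prev.size + ev.size,
                    prev.alt_sequence + ev.alt_sequence,
                )
                continue
        merged.append(ev)
    return merged


def extract_variants(
    aln: AlignmentResult,
    query: NucleotideSequence | str,
    reference: NucleotideSequence | str,
) -> list[VariantEvent]:
    """Convert an alignment into left-normalised variant events.

    Each run of non-match operations becomes one event; adjacent runs of
    the same type are merged, and indels are shifted left while the
    reference base preceding the gap equals the gap's final base (the
    standard homopolymer/repeat normalisation), so a deletion inside an
    AAAA run is always reported at the run's leftmost position regardless
    of the DP path taken.
    """
    qb = query.bases if isinstance(query, NucleotideSequence) else query.upper()
    rb = reference.bases if isinstance(reference, NucleotideSequence) else reference.upper()
    if aln.query_length() != len(qb) or aln.reference_length() != len(rb):
        raise ValueError("alignment inconsistent with sequences")

    events: list[VariantEvent] = []
    qpos = rpos = 0  # 0-based consumed counts
    for op, n in aln.ops:
        if op == "match":
            qpos += n
            rpos += n
        elif op == "mismatch":
            events.append(
                VariantEvent("substitution", rpos + 1, n, qb[qpos : qpos + n])
            )
            qpos += n
            rpos += n
        elif op == "deletion":
            events.append(VariantEvent("deletion", rpos + 1, n))
            rpos += n
        else:  # insertion
            events.append(VariantEvent("insertion", rpos, n, qb[qpos : qpos + n]))
            qpos += n

    shifted: list[VariantEvent] = []
    for ev in events:
        if ev.type == "deletion":
            start = ev.reference_position
            # shifting the gap one left is valid iff the base before the gap
            # equals the gap's last base (0-based start+size-2 vs start-2)
            while start > 1 and rb[start + ev.size - 2] == rb[start - 2]:
                start -= 1
            shifted.append(VariantEvent("deletion", start, ev.size))
        elif ev.type == "insertion":
            pos, alt = ev.reference_position, ev.alt_sequence
            while pos > 0 and alt[-1] == rb[pos - 1]:
                alt = alt[-1] + alt[:-1]
                pos -= 1
            shifted.append(VariantEvent("insertion", pos, ev.size, alt))
        else:
            shifted.append(ev)
    shifted.sort(key=lambda e: (e.reference_position, e.type))
    return _merge_adjacent(shifted)
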