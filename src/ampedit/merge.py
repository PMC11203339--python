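"""Paired-read aggregation: reverse-complement, overlap detection, stitching.

First phase of the amplicon pipeline. The R2 read is reverse-complemented
(with its quality string reversed), the overlapping region between R1 and
rcR2 is located, and the pair is stitched into a single consensus in which
conflicting bases are resolved toward the higher Phred quality.

Overlap detection realises the "high gap penalties" intent as a gap-free
scan: under match +1 / mismatch -1 / gapOpen -10 / gapExtension -10, any
gapped local alignment is dominated by an ungapped one, so the best overlap
is found by scoring every ungapped suffix(R1)/prefix(rcR2) offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplicon import encode, revcomp

__all__ = [
    "Read",
    "ReadPair",
    "Overlap",
    "MergedRead",
    "MergeStats",
    "reverse_complement_read",
    "find_overlap",
    "stitch_pair",
    "merge_pair",
    "merge_pairs",
]


@dataclass
class Read:
    id: str
    bases: str
    qualities: np.ndarray  # per-base Phred scores

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    r1: Read
    r2: Read


@dataclass(frozen=True)
class Overlap:
    """Ungapped overlap placing rcR2 at 0-based ``offset`` within R1's frame."""

    offset: int
    length: int
    mismatches: int


@dataclass
class MergedRead:
    id: str
    bases: str
    qualities: np.ndarray
    overlap_start: int = 0  # 1-based inclusive, merged coordinates
    overlap_end: int = 0
    merge_status: str = "merged"


@dataclass
class MergeStats:
    n_pairs: int = 0
    n_merged: int = 0
    overlap_lengths: dict[int, int] = field(default_factory=dict)


def reverse_complement_read(r: Read) -> Read:
    """Reverse-complement the bases and reverse the quality scores."""
    return Read(r.id, revcomp(r.bases), r.qualities[::-1].copy())


def _overlap_match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matches between a-suffix and b-prefix for every overlap length.

    Returns ``counts`` where ``counts[L-1]`` is the number of agreeing
    positions between ``a[-L:]`` and ``b[:L]``, for L = 1..min(len(a),
    len(b)), computed with one cross-correlation per nucleotide channel.
    N (code 4) matches nothing.
    """
    la, lb = len(a), len(b)
    lmax = min(la, lb)
    total = np.zeros(la + lb - 1)
    for code in range(4):
        total += np.correlate(
            (a == code).astype(np.float64), (b == code).astype(np.float64), "full"
        )
    # in 'full' mode, placing b at a-offset s lands at index s + lb - 1, so
    # overlap length L (a-suffix vs b-prefix) lives at index la + lb - 1 - L
    counts = total[-lmax:][::-1]
    return np.rint(counts).astype(np.int64)


def find_overlap(
    r1: Read,
    rc_r2: Read,
    min_overlap: int = 15,
    max_error_rate: float = 0.1,
) -> Overlap | None:
    """Best-scoring ungapped overlap between R1 and the reverse-complemented R2.

    Scores every candidate overlap length with match +1 / mismatch -1 and
    returns the best one, provided it is at least ``min_overlap`` long and
    its mismatch fraction does not exceed ``max_error_rate``; otherwise
    ``None``. Score ties are broken toward the longest overlap (the
    dovetail geometry expected of an amplicon pair).
    """
    if not len(r1) or not len(rc_r2):
        return None
    a, b = encode(r1.bases), encode(rc_r2.bases)
    matches = _overlap_match_counts(a, b)
    lengths = np.arange(1, len(matches) + 1)
    scores = 2 * matches - lengths  # matches - mismatches
    best = int(np.flatnonzero(scores == scores.max())[-1])  # longest on ties
    L = int(lengths[best])
    mism = int(L - matches[best])
    if L < min_overlap or mism / L > max_error_rate:
        return None
    return Overlap(offset=len(a) - L, length=L, mismatches=mism)


def stitch_pair(r1: Read, rc_r2: Read, overlap: Overlap) -> MergedRead:
    """Stitch a pair at its overlap into one consensus read.

    Outside the overlap, bases and qualities are copied from whichever read
    covers the position. Inside it, agreeing bases keep the higher of the
    two qualities; at conflicts the higher-quality base wins (quality ties
    go to R1). Positions covered by neither read — possible only when the
    overlap leaves a gap — are filled with N at quality 0.
    """
    off = overlap.offset
    n1, n2 = len(r1), len(rc_r2)
    total = max(n1, off + n2)
    bases = np.full(total, ord("N"), dtype=np.uint8)
    quals = np.zeros(total, dtype=np.int16)

    b1 = np.frombuffer(r1.bases.encode("ascii"), dtype=np.uint8)
    b2 = np.frombuffer(rc_r2.bases.encode("ascii"), dtype=np.uint8)
    bases[:n1] = b1
    quals[:n1] = r1.qualities
    # rcR2 segment outside the overlap
    tail_start = max(n1, off)
    bases[tail_start:] = b2[tail_start - off :]
    quals[tail_start:] = rc_r2.qualities[tail_start - off :]

    lo, hi = off, min(n1, off + n2)  # overlap interval in merged coordinates
    if hi > lo:
        q1 = r1.qualities[lo:hi]
        q2 = rc_r2.qualities[lo - off : hi - off]
        s2 = b2[lo - off : hi - off]
        s1 = b1[lo:hi]
        take2 = q2 > q1  # quality tie -> keep the R1 base
        bases[lo:hi] = np.where(take2, s2, s1)
        quals[lo:hi] = np.where(s1 == s2, np.maximum(q1, q2), np.where(take2, q2, q1))

    return MergedRead(
        id=r1.id,
        bases=bases.tobytes().decode("ascii"),
        qualities=quals,
        overlap_start=lo + 1,
        overlap_end=hi,
        merge_status="merged",
    )


def merge_pair(
    pair: ReadPair, min_overlap: int = 15, max_error_rate: float = 0.1
) -> MergedRead:
    """Full aggregation of one pair; unmergeable pairs are flagged, not dropped."""
    rc2 = reverse_complement_read(pair.r2)
    ov = find_overlap(pair.r1, rc2, min_overlap, max_error_rate)
    if ov is None:
        return MergedRead(
            id=pair.r1.id,
            bases="",
            qualities=np.zeros(0, dtype=np.int16),
            merge_status="unmerged",
        )
    return stitch_pair(pair.r1, rc2, ov)


def merge_pairs(
    pairs, min_overlap: int = 15, max_error_rate: float = 0.1
) -> tuple[list[MergedRead], MergeStats]:
    stats = MergeStats()
    merged = []
    for pair in pairs:
        stats.n_pairs += 1
        m = merge_pair(pair, min_overlap, max_error_rate)
        if m.merge_status == "merged":
            stats.n_merged += 1
            L = m.overlap_end - m.overlap_start + 1
            stats.overlap_lengths[L] = stats.overlap_lengths.get(L, 0) + 1
            merged.append(m)
    return merged, stats
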