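"""Unique-sequence aggregation and HDR / NHEJ / unmodified calling.

After merging and boundary trimming, all unique aggregated sequences are
counted, each unique sequence is classified once, and per-sample
percentages are computed over the classified reads.

The calling rules are explicit and tunable through
:class:`ClassificationPolicy`:

* A read is **HDR** when its alignment to the HDR allele shows no
  insertion/deletion event inside the analysis window around the cut site
  and the bases aligned to the restored target position and to every
  silent marker position equal the HDR allele.
* Otherwise the read is aligned to the mutant reference; any
  insertion/deletion event inside the window makes it **NHEJ** (this
  includes imperfect HDR — reads carrying the restored base plus an
  indel — per the indel-over-HDR precedence), and a read with no window
  indel is **unmodified**.
* Substitutions never change a read's class: the assay's signal is the
  single-base restoration, the markers and the indels, so a
  substitution-sensitive rule would be hostage to the sequencing error
  rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import AlleleSet, encode
from .align import ScoringScheme, global_align, extract_variants

__all__ = [
    "ClassificationPolicy",
    "UniqueSequenceTable",
    "EditingSummary",
    "EmptySampleError",
    "aggregate_unique",
    "classify_sequence",
    "classify_table",
    "summarize_editing",
    "background_subtract",
]

CLASSES = ("hdr", "nhej", "unmodified")


class EmptySampleError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationPolicy:
    """Tunable calling rules; defaults are deliberately conservative."""

    analysis_window: int = 20  # +/- nt around the cut site for indel calling
    hdr_requires_all_markers: bool = True
    substitution_tolerance: int | None = None  # None = unlimited
    precedence: str = "indel-over-hdr"

    def __post_init__(self) -> None:
        if self.analysis_window < 1:
            raise ValueError("analysis_window must be >= 1")
        if self.precedence != "indel-over-hdr":
            raise ValueError("only indel-over-hdr precedence is supported")


@dataclass
class UniqueSequenceTable:
    """Distinct aggregated sequences with read counts and (optional) classes."""

    sequences: list[str]
    counts: list[int]
    classes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        data = {"sequence": self.sequences, "read_count": self.counts}
        if self.classes:
            data["class"] = self.classes
        return pd.DataFrame(data)


@dataclass
class EditingSummary:
    """Per-sample editing-outcome report.

    Percentages are computed over classified reads (those surviving merge
    and anchoring); stage attrition is carried alongside so nothing is
    silently dropped.
    """

    n_total_pairs: int
    n_merged: int
    n_anchored: int
    n_classified: int
    class_counts: dict[str, int]
    hdr_pct: float
    indel_pct: float
    unmodified_pct: float
    reference_name: str = ""

    def as_dict(self) -> dict:
        return {
            "n_total_pairs": self.n_total_pairs,
            "n_merged": self.n_merged,
            "n_anchored": self.n_anchored,
            "n_classified": self.n_classified,
            "class_counts": dict(self.class_counts),
            "hdr_pct": self.hdr_pct,
            "indel_pct": self.indel_pct,
            "unmodified_pct": self.unmodified_pct,
            "reference_name": self.reference_name,
        }


def aggregate_unique(trimmed_sequences) -> UniqueSequenceTable:
    """Group identical sequences; descending count, ties lexicographic."""
    counter = Counter(
        s.bases if hasattr(s, "bases") else s for s in trimmed_sequences
    )
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return UniqueSequenceTable(
        sequences=[s for s, _ in items], counts=[c for _, c in items]
    )


def _hamming(a: str, b: str) -> int:
    return int(np.count_nonzero(encode(a) != encode(b)))


def _window_events(events, cut_site: int, window: int) -> list:
    lo, hi = cut_site - window, cut_site + window
    hits = []
    for ev in events:
        if ev.type == "substitution":
            continue
        s, e = ev.span()
        if e >= lo and s <= hi:
            hits.append(ev)
    return hits


def _events_and_lookup(seq: str, ref: str, ref_name: str, scheme: ScoringScheme):
    """Alignment events plus a query-base lookup by reference position.

    Fast path: when the sequences have equal length and differ at no more
    than four positions, the identity alignment is provably optimal under
    the default scheme (a gapped alternative forfeits at least two gap
    openings plus one unaligned base, i.e. five matches), so no DP is run.
    """
    if len(seq) == len(ref) and _hamming(seq, ref) <= 4:
        return [], (lambda pos: seq[pos - 1])
    aln = global_align(seq, ref, scheme)
    events = extract_variants(aln, seq, ref)

    qmap: dict[int, int] = {}  # 1-based ref pos -> 0-based query index (or -1)
    qpos = rpos = 0
    for op, n in aln.ops:
        if op in ("match", "mismatch"):
            for k in range(n):
                qmap[rpos + k + 1] = qpos + k
            qpos += n
            rpos += n
        elif op == "deletion":
            for k in range(n):
                qmap[rpos + k + 1] = -1
            rpos += n
        else:
            qpos += n

    def lookup(pos: int) -> str:
        qi = qmap.get(pos, -1)
        return seq[qi] if qi >= 0 else ""

    return events, lookup


def classify_sequence(
    seq: str,
    alleles: AlleleSet,
    policy: ClassificationPolicy = ClassificationPolicy(),
    scheme: ScoringScheme = ScoringScheme(),
) -> str:
    """Call one trimmed sequence as ``hdr``, ``nhej`` or ``unmodified``."""
    site = alleles.edit_site
    window = policy.analysis_window

    hdr_events, hdr_base = _events_and_lookup(
        seq, alleles.hdr.bases, alleles.hdr.name, scheme
    )
    if not _window_events(hdr_events, alleles.cut_site_hdr, window):
        required = [site.target_position]
        if policy.hdr_requires_all_markers:
            required.extend(site.marker_positions)
        if all(hdr_base(p) == alleles.hdr.bases[p - 1] for p in required):
            return "hdr"

    mut_events, _ = _events_and_lookup(
        seq, alleles.mutant.bases, alleles.mutant.name, scheme
    )
    if _window_events(mut_events, alleles.cut_site_mutant, window):
        return "nhej"
    return "unmodified"


def classify_table(
    table: UniqueSequenceTable,
    alleles: AlleleSet,
    policy: ClassificationPolicy = ClassificationPolicy(),
    scheme: ScoringScheme = ScoringScheme(),
) -> UniqueSequenceTable:
    table.classes = [
        classify_sequence(s, alleles, policy, scheme) for s in table.sequences
    ]
    return table


def summarize_editing(
    table: UniqueSequenceTable,
    n_total_pairs: int,
    n_merged: int,
    n_anchored: int,
    reference_name: str = "",
) -> EditingSummary:
    """Percentages over classified reads, with stage attrition alongside."""
    if not table.classes or len(table.classes) != len(table.sequences):
        raise ValueError("table must be classified first")
    n_classified = table.total_reads
    if n_classified == 0:
        raise EmptySampleError("no classified reads in sample")
    counts = {c: 0 for c in CLASSES}
    for cls, n in zip(table.classes, table.counts):
        counts[cls] += n
    pct = {c: 100.0 * counts[c] / n_classified for c in CLASSES}
    return EditingSummary(
        n_total_pairs=n_total_pairs,
        n_merged=n_merged,
        n_anchored=n_anchored,
        n_classified=n_classified,
        class_counts=counts,
        hdr_pct=pct["hdr"],
        indel_pct=pct["nhej"],
        unmodified_pct=pct["unmodified"],
        reference_name=reference_name,
    )


def background_subtract(treated: EditingSummary, control: EditingSummary) -> float:
    """Indel percentage of a treated sample above its untreated control.

    Both summaries must come from the same amplicon; the result is clamped
    at zero (an off-target site whose apparent indel rate is below the
    control's noise floor reports 0).
    """
    if treated.reference_name != control.reference_name:
        raise ValueError(
            f"amplicon mismatch: {treated.reference_name!r} vs {control.reference_name!r}"
        )
    return max(0.0, treated.indel_pct - control.indel_pct)
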