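"""Amplicon/allele data model and small CRISPR design computations.

This module defines the sequence containers used throughout the package and
the desk-top design utilities that accompany an HDR gene-correction
experiment: building the wild-type / mutant / HDR allele trio around a
single-base deletion, predicting the frameshift consequence of that
deletion, in-silico PCR, Cas9 cleavage-fragment prediction and a simple
Hamming off-target scan.

Coordinates are 1-based and inclusive at every public interface, matching
HGVS-style numbering (the pathogenic allele modelled here is a c.517delC
single-cytosine deletion). Allele positions (``target_position``,
``marker_positions``, ``cut_site``) are expressed in wild-type coordinates;
:class:`AlleleSet` derives the mutant-coordinate cut site needed when the
mutant allele serves as the alignment reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "NucleotideSequence",
    "EditSite",
    "AlleleSet",
    "GuideSpec",
    "FrameshiftReport",
    "PcrProduct",
    "OfftargetHit",
    "build_allele_set",
    "predict_frameshift_consequence",
    "insilico_pcr",
    "predict_cleavage_fragments",
    "scan_offtargets",
    "synthetic_cybb_allele_set",
]

_ALPHABET = set("ACGTN")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i


def encode(bases: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as a uint8 array (A=0..N=4)."""
    return _ENCODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def revcomp(bases: str) -> str:
    return str(Seq(bases).reverse_complement())


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the {A, C, G, T, N} alphabet.

    Input is normalised to upper case; IUPAC ambiguity codes other than N
    are rejected to keep alignment semantics unambiguous.
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        upper = self.bases.upper()
        if not upper:
            raise ValueError("empty sequence")
        bad = set(upper) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-ACGTN symbols: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", upper)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(revcomp(self.bases), name=self.name)


@dataclass(frozen=True)
class EditSite:
    """Annotation of the edited locus, in wild-type (1-based) coordinates.

    ``target_position`` is the deleted base (the c.517 equivalent),
    ``cut_site`` the blunt double-strand break (between ``cut_site`` and
    ``cut_site + 1``), and ``marker_positions`` the silent substitutions the
    HDR donor carries in the guide/PAM region to block re-cutting.
    """

    target_position: int
    cut_site: int
    marker_positions: tuple[int, ...] = ()
    guide_strand: str = "+"

    def __post_init__(self) -> None:
        if self.guide_strand not in {"+", "-"}:
            raise ValueError("guide_strand must be '+' or '-'")
        if self.target_position < 1 or self.cut_site < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.target_position in self.marker_positions:
            raise ValueError("marker positions must differ from target_position")


@dataclass(frozen=True)
class AlleleSet:
    """The wild-type / mutant / HDR allele trio of one edited amplicon.

    ``mutant`` (the single-base-deletion allele) is the reference all reads
    are aligned to; ``hdr`` is the wild type with the donor's silent marker
    substitutions applied, so it is one base longer than the mutant.
    """

    mutant: NucleotideSequence
    wildtype: NucleotideSequence
    hdr: NucleotideSequence
    edit_site: EditSite

    def __post_init__(self) -> None:
        wt, mut, hdr = self.wildtype.bases, self.mutant.bases, self.hdr.bases
        t = self.edit_site.target_position
        if not (1 <= t <= len(wt)):
            raise ValueError("target_position outside wildtype")
        if mut != wt[: t - 1] + wt[t:]:
            raise ValueError("mutant is not wildtype with target base deleted")
        if len(hdr) != len(mut) + 1:
            raise ValueError("HDR allele must be one base longer than mutant")
        if len(hdr) != len(wt):
            raise ValueError("HDR and wildtype alleles must have equal length")
        diffs = tuple(i + 1 for i, (a, b) in enumerate(zip(hdr, wt)) if a != b)
        if diffs != tuple(sorted(self.edit_site.marker_positions)):
            raise ValueError(
                f"HDR differs from wildtype at {diffs}, expected markers "
                f"{tuple(sorted(self.edit_site.marker_positions))}"
            )
        for p in self.edit_site.marker_positions:
            if not (1 <= p <= len(wt)):
                raise ValueError("marker position outside wildtype")

    @property
    def cut_site_mutant(self) -> int:
        """Cut site in mutant (reference) coordinates."""
        cs = self.edit_site.cut_site
        return cs if cs < self.edit_site.target_position else cs - 1

    @property
    def cut_site_hdr(self) -> int:
        """Cut site in HDR-allele coordinates (same frame as wild type)."""
        return self.edit_site.cut_site


@dataclass(frozen=True)
class GuideSpec:
    """An SpCas9 guide: protospacer (20 or 21 nt) plus a PAM pattern.

    A 21-mer models a guide extended by one nucleotide in the 5' direction
    so that it matches the mutant allele with full complementarity. The PAM
    pattern may use N as a wildcard (default NGG).
    """

    protospacer: str
    pam: str = "NGG"
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())
        if len(self.protospacer) not in (20, 21):
            raise ValueError("protospacer length must be 20 or 21 nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be over ACGT")
        if len(self.pam) != 3 or set(self.pam) - set("ACGTN"):
            raise ValueError("PAM must be a 3-nt ACGTN pattern")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class FrameshiftReport:
    missense_count: int
    stop_found: bool
    stop_codon_index: int | None = None

    def __post_init__(self) -> None:
        if self.stop_found != (self.stop_codon_index is not None):
            raise ValueError("stop_codon_index must be present iff stop_found")


@dataclass(frozen=True)
class PcrProduct:
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("length must equal end - start + 1")


@dataclass(frozen=True)
class OfftargetHit:
    subject_name: str
    position: int
    strand: str
    mismatch_count: int
    aligned_site_sequence: str
    pam_sequence: str


def build_allele_set(
    wildtype: NucleotideSequence,
    target_position: int,
    marker_edits: list[tuple[int, str]] = (),
    *,
    cut_site: int | None = None,
    guide_strand: str = "+",
) -> AlleleSet:
    """Derive the mutant and HDR alleles from the wild type.

    The mutant allele deletes the single base at ``target_position``; the
    HDR allele applies the silent ``marker_edits`` (position, new base) to
    the wild type. ``cut_site`` defaults to the target position.
    """
    wt = wildtype.bases
    if not (1 <= target_position <= len(wt)):
        raise ValueError("target_position out of range")
    mutant = wt[: target_position - 1] + wt[target_position:]
    hdr = list(wt)
    positions = []
    for pos, base in marker_edits:
        base = base.upper()
        if not (1 <= pos <= len(wt)):
            raise ValueError(f"marker position {pos} out of range")
        if base not in _ALPHABET - {"N"}:
            raise ValueError(f"marker base {base!r} is not a concrete nucleotide")
        if base == wt[pos - 1]:
            raise ValueError(
                f"marker at {pos} equals the wildtype base (not a substitution)"
            )
        hdr[pos - 1] = base
        positions.append(pos)
    site = EditSite(
        target_position=target_position,
        cut_site=cut_site if cut_site is not None else target_position,
        marker_positions=tuple(sorted(positions)),
        guide_strand=guide_strand,
    )
    name = wildtype.name or "amplicon"
    return AlleleSet(
        mutant=NucleotideSequence(mutant, f"{name}_mutant"),
        wildtype=NucleotideSequence(wt, f"{name}_wildtype"),
        hdr=NucleotideSequence("".join(hdr), f"{name}_hdr"),
        edit_site=site,
    )


def predict_frameshift_consequence(
    cds: NucleotideSequence, deletion_position: int
) -> FrameshiftReport:
    """Consequence of a single-base deletion within a coding sequence.

    Deletes the base at ``deletion_position``, translates the mutant CDS
    from codon 1 with the standard genetic code, and counts — starting at
    the first codon whose sequence is changed by the shift — the number of
    missense (non-stop) codons before the first stop codon. The stop codon
    itself is not counted. If no stop occurs before the end of the
    sequence, ``stop_found`` is False and the count runs to the end.
    """
    seq = cds.bases
    if not seq.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if not (1 <= deletion_position <= len(seq)):
        raise ValueError("deletion_position out of range")
    mutant = seq[: deletion_position - 1] + seq[deletion_position:]
    n_codons = len(mutant) // 3
    protein = str(Seq(mutant[: n_codons * 3]).translate())
    first_affected = (deletion_position - 1) // 3 + 1
    missense = 0
    for idx in range(first_affected, n_codons + 1):
        if protein[idx - 1] == "*":
            return FrameshiftReport(missense, True, idx)
        missense += 1
    return FrameshiftReport(missense, False, None)


def _pam_matches(site: str, pattern: str) -> bool:
    return len(site) == len(pattern) and all(
        p == "N" or s == p for s, p in zip(site, pattern)
    )


def _mismatches(a: str, b: str) -> int:
    # N never matches a concrete base, nor another N
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def insilico_pcr(
    template: NucleotideSequence,
    fwd_primer: NucleotideSequence,
    rev_primer: NucleotideSequence,
    max_mismatch: int = 0,
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a linear template.

    The forward primer must match the plus strand and the reverse
    complement of the reverse primer a downstream window, each with at most
    ``max_mismatch`` mismatches and an exact match over the three 3'-terminal
    bases of each primer (primer-extension logic). Product length is counted
    primer-inclusive; products are returned ordered by start.
    """
    t = template.bases
    f = fwd_primer.bases
    r_rc = revcomp(rev_primer.bases)
    if len(f) < 15 or len(rev_primer.bases) < 15:
        raise ValueError("primers must be at least 15 nt")
    if len(t) <= max(len(f), len(r_rc)):
        raise ValueError("template must be longer than both primers")

    fwd_sites = []  # (0-based start, mismatches)
    for i in range(len(t) - len(f) + 1):
        window = t[i : i + len(f)]
        if window[-3:] != f[-3:]:
            continue
        m = _mismatches(window, f)
        if m <= max_mismatch:
            fwd_sites.append((i, m))
    rev_sites = []
    for j in range(len(t) - len(r_rc) + 1):
        window = t[j : j + len(r_rc)]
        # the reverse primer's 3' terminus maps to the 5' end of its
        # plus-strand footprint
        if window[:3] != r_rc[:3]:
            continue
        m = _mismatches(window, r_rc)
        if m <= max_mismatch:
            rev_sites.append((j, m))

    products = []
    for i, fm in fwd_sites:
        for j, rm in rev_sites:
            if j >= i + len(f):
                products.append(
                    PcrProduct(
                        start=i + 1,
                        end=j + len(r_rc),
                        length=j + len(r_rc) - i,
                        fwd_mismatches=fm,
                        rev_mismatches=rm,
                    )
                )
    products.sort(key=lambda p: (p.start, p.end))
    return products


def _find_guide_sites(amplicon: str, guide: GuideSpec) -> list[tuple[int, str]]:
    """All exact protospacer+PAM occurrences; (0-based cut index, strand).

    The cut index is the number of amplicon bases 5' of the blunt cut on
    the plus strand (SpCas9 cuts 3 bp 5' of the PAM).
    """
    sites = []
    L = len(guide.protospacer)
    for strand in "+-":
        seq = amplicon if strand == "+" else revcomp(amplicon)
        for i in range(len(seq) - L - 2):
            if seq[i : i + L] != guide.protospacer:
                continue
            if not _pam_matches(seq[i + L : i + L + 3], guide.pam):
                continue
            cut = i + L - 3  # bases 5' of the cut, in this strand's frame
            if strand == "-":
                cut = len(seq) - cut
            sites.append((cut, strand))
    return sites


def predict_cleavage_fragments(
    amplicon: NucleotideSequence, guide: GuideSpec
) -> tuple[int, int]:
    """Fragment lengths produced by Cas9 cleavage of a PCR product.

    Requires the protospacer+PAM to occur exactly once on either strand;
    the blunt cut falls 3 bp 5' of the PAM, so the fragment lengths always
    sum to the amplicon length.
    """
    sites = _find_guide_sites(amplicon.bases, guide)
    if len(sites) != 1:
        raise ValueError(
            f"protospacer+PAM occurs {len(sites)} times in {amplicon.name!r}; "
            "need exactly one site"
        )
    cut, _ = sites[0]
    return cut, len(amplicon.bases) - cut


def scan_offtargets(
    guide: GuideSpec,
    subjects: list[NucleotideSequence],
    max_mismatches: int = 4,
) -> list[OfftargetHit]:
    """Hamming-distance off-target scan over both strands of each subject.

    Slides the protospacer over every window of each subject (and its
    reverse complement), reporting windows with at most ``max_mismatches``
    mismatches that are immediately followed by the PAM pattern. No bulges
    are considered. ``position`` is the 1-based plus-strand coordinate of
    the leftmost base of the protospacer footprint. Hits are sorted by
    mismatch count, then subject order, position and strand.
    """
    if not subjects:
        raise ValueError("subjects must be non-empty")
    L = len(guide.protospacer)
    proto = encode(guide.protospacer)
    pam_idx = [k for k, p in enumerate(guide.pam) if p != "N"]
    pam_codes = encode("".join(guide.pam[k] for k in pam_idx)) if pam_idx else None

    hits = []
    for order, subject in enumerate(subjects):
        n = len(subject.bases)
        if n < L + 3:
            continue
        for strand in "+-":
            seq = subject.bases if strand == "+" else revcomp(subject.bases)
            arr = encode(seq)
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)[: n - L - 2]
            # N (code 4) in the subject never matches the protospacer
            mm = (windows != proto).sum(axis=1)
            ok = mm <= max_mismatches
            if pam_idx:
                for k, code in zip(pam_idx, pam_codes):
                    ok &= arr[L + k : L + k + len(windows)] == code
            for i in np.flatnonzero(ok):
                pos = i + 1 if strand == "+" else n - i - L + 1
                hits.append(
                    (
                        int(mm[i]),
                        order,
                        int(pos),
                        strand,
                        OfftargetHit(
                            subject_name=subject.name,
                            position=int(pos),
                            strand=strand,
                            mismatch_count=int(mm[i]),
                            aligned_site_sequence=seq[i : i + L],
                            pam_sequence=seq[i + L : i + L + 3],
                        ),
                    )
                )
    hits.sort(key=lambda h: h[:4])
    return [h[4] for h in hits]


def synthetic_cybb_allele_set(seed: int = 7042517) -> tuple[AlleleSet, GuideSpec]:
    """A synthetic stand-in for the Cybb exon-6 amplicon of the study system.

    The real amplicon sequence is not publicly printed, so this constructs a
    random 274-bp mutant (single-base-deletion) reference with the same
    structure: a 21-nt protospacer that matches the mutant allele with full
    complementarity (modelling a guide extended by one nucleotide at its 5'
    end), a TGG PAM, a blunt cut site 3 bp 5' of the PAM, the deleted
    cytosine restored at the cut in the wild type, and two silent marker
    substitutions (one in the guide footprint, one destroying the PAM) in
    the HDR allele. Entirely synthetic; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    bases = list("ACGT"[i] for i in rng.integers(0, 4, size=274))
    # PAM at mutant 1-based 162..164; protospacer at 141..161 (21-mer)
    bases[161:164] = list("TGG")
    # the restored base is a C inserted between mutant positions 158/159;
    # keep its neighbours non-C so the insertion position is unambiguous
    for idx in (157, 158):
        if bases[idx] == "C":
            bases[idx] = "A"
    mutant = "".join(bases)
    wildtype = NucleotideSequence(mutant[:158] + "C" + mutant[158:], "cybb_synthetic")
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    markers = [(150, transition[wildtype.bases[149]]), (164, "A")]
    alleles = build_allele_set(
        wildtype, target_position=159, marker_edits=markers, cut_site=158
    )
    guide = GuideSpec(protospacer=alleles.mutant.bases[140:161], pam="NGG")
    return alleles, guide
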