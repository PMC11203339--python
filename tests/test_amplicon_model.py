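"""Allele construction and the CRISPR design utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampedit.amplicon import (
    GuideSpec,
    NucleotideSequence,
    build_allele_set,
    insilico_pcr,
    predict_cleavage_fragments,
    predict_frameshift_consequence,
    revcomp,
    scan_offtargets,
)
from oracles import brute_force_offtarget_windows
from conftest import random_seq

DNA = st.text(alphabet="ACGT", min_size=2, max_size=60)


class TestNucleotideSequence:
    def test_normalizes_case_and_validates_alphabet(self):
        assert NucleotideSequence("acgtn").bases == "ACGTN"
        with pytest.raises(ValueError):
            NucleotideSequence("ACGR")  # IUPAC ambiguity codes are rejected
        with pytest.raises(ValueError):
            NucleotideSequence("")


class TestBuildAlleleSet:
    def test_deletion_and_marker_application(self):
        wt = NucleotideSequence("AAACGTTT")
        al = build_allele_set(wt, target_position=4)
        assert al.mutant.bases == "AAAGTTT"
        assert al.hdr.bases == "AAACGTTT"

        al = build_allele_set(wt, target_position=4, marker_edits=[(7, "A")])
        assert al.hdr.bases == "AAACGTAT"
        assert al.mutant.bases == "AAAGTTT"
        assert al.edit_site.marker_positions == (7,)

    def test_rejects_invalid_markers_and_positions(self):
        wt = NucleotideSequence("AAACGTTT")
        with pytest.raises(ValueError):
            build_allele_set(wt, 4, marker_edits=[(7, "T")])  # not a substitution
        with pytest.raises(ValueError):
            build_allele_set(wt, 99)
        with pytest.raises(ValueError):
            build_allele_set(wt, 4, marker_edits=[(99, "A")])

    @settings(derandomize=True, max_examples=50)
    @given(DNA, st.data())
    def test_deletion_round_trip(self, wt, data):
        """Re-inserting the deleted base into the mutant restores the wild type."""
        pos = data.draw(st.integers(1, len(wt)))
        al = build_allele_set(NucleotideSequence(wt), pos)
        rebuilt = al.mutant.bases[: pos - 1] + wt[pos - 1] + al.mutant.bases[pos - 1 :]
        assert rebuilt == wt

    def test_synthetic_allele_set_structure(self, alleles, guide):
        """The synthetic amplicon has the study's allele architecture."""
        assert len(alleles.mutant) == 274
        assert len(alleles.hdr) == len(alleles.mutant) + 1
        hamming = sum(a != b for a, b in zip(alleles.hdr.bases, alleles.wildtype.bases))
        assert hamming == 2
        # the guide matches the mutant allele with full complementarity
        assert len(guide.protospacer) == 21
        assert alleles.mutant.bases.count(guide.protospacer) == 1
        # both 15-bp termini are shared between mutant and HDR alleles
        assert alleles.mutant.bases[:15] == alleles.hdr.bases[:15]
        assert alleles.mutant.bases[-15:] == alleles.hdr.bases[-15:]


class TestFrameshift:
    @pytest.mark.parametrize(
        "cds,pos,missense,found,stop_idx",
        [
            ("ATGAAAGTAACCCTT", 7, 0, True, 3),  # shift lands directly on a stop
            ("ATGAAACCCGGG", 4, 2, False, None),  # no stop in the shifted frame
            ("ATGGTAACCCTT", 4, 0, True, 2),  # first affected codon is the stop
            ("ATGAAACCCGTAACC", 7, 1, True, 4),  # one missense codon then TAA
        ],
    )
    def test_known_consequences(self, cds, pos, missense, found, stop_idx):
        rep = predict_frameshift_consequence(NucleotideSequence(cds), pos)
        assert rep.missense_count == missense
        assert rep.stop_found is found
        assert rep.stop_codon_index == stop_idx

    def test_requires_atg_start(self):
        with pytest.raises(ValueError):
            predict_frameshift_consequence(NucleotideSequence("TTGAAACCC"), 4)


class TestInsilicoPcr:
    def test_primers_at_template_ends(self):
        rng = np.random.default_rng(1)
        t = random_seq(rng, 100)
        fwd = NucleotideSequence(t[:20], "f")
        rev = NucleotideSequence(revcomp(t[-20:]), "r")
        products = insilico_pcr(NucleotideSequence(t), fwd, rev, 0)
        assert len(products) == 1
        assert (products[0].start, products[0].end, products[0].length) == (1, 100, 100)

    def test_internal_mismatch_rejected_at_zero_tolerance(self):
        rng = np.random.default_rng(1)
        t = random_seq(rng, 100)
        f = list(t[:20])
        f[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[f[10]]
        fwd = NucleotideSequence("".join(f), "f")
        rev = NucleotideSequence(revcomp(t[-20:]), "r")
        assert insilico_pcr(NucleotideSequence(t), fwd, rev, 0) == []

    def test_planted_sites_in_random_template(self):
        """Planted primer sites yield the product found by a brute-force scan."""
        rng = np.random.default_rng(7)
        t = list(random_seq(rng, 500))
        fwd = random_seq(rng, 20)
        rev_site = random_seq(rng, 20)
        t[50:70] = fwd  # product start at 1-based 51
        t[330:350] = rev_site  # product end at 1-based 350
        template = "".join(t)
        rev = NucleotideSequence(revcomp(rev_site), "r")
        products = insilico_pcr(NucleotideSequence(template), NucleotideSequence(fwd, "f"), rev, 0)
        # brute-force: exact substring occurrences
        fwd_hits = [i for i in range(481) if template[i : i + 20] == fwd]
        rev_hits = [j for j in range(481) if template[j : j + 20] == rev_site]
        assert fwd_hits == [50] and rev_hits == [330]
        assert len(products) == 1
        p = products[0]
        assert (p.start, p.end, p.length) == (51, 350, 300)


class TestCleavageFragments:
    def test_guide_alone_forced_by_3bp_rule(self):
        proto = "GATTACAGATTACAGATTAC"
        amp = NucleotideSequence(proto + "AGG")
        assert predict_cleavage_fragments(amp, GuideSpec(proto)) == (17, 6)

    def test_minus_strand_site_matches_index_arithmetic(self):
        rng = np.random.default_rng(3)
        proto = random_seq(rng, 20)
        site = proto + "TGG"
        left = random_seq(rng, 40)
        right = random_seq(rng, 37)
        amp = left + revcomp(site) + right
        lens = predict_cleavage_fragments(NucleotideSequence(amp), GuideSpec(proto))
        # brute force: cut is 3 bp 5' of the PAM in guide orientation; on the
        # forward strand that is 6 bases into the reverse-complemented site
        len5 = len(left) + 6
        assert lens == (len5, len(amp) - len5)
        assert sum(lens) == len(amp)

    def test_fragment_sum_invariant(self, alleles, guide):
        lens = predict_cleavage_fragments(alleles.mutant, guide)
        assert sum(lens) == len(alleles.mutant)
        assert lens[0] == alleles.cut_site_mutant

    def test_ambiguous_or_absent_site_rejected(self):
        proto = "GATTACAGATTACAGATTAC"
        twice = NucleotideSequence(proto + "AGG" + proto + "AGG")
        with pytest.raises(ValueError):
            predict_cleavage_fragments(twice, GuideSpec(proto))
        with pytest.raises(ValueError):
            predict_cleavage_fragments(NucleotideSequence("ACGT" * 20), GuideSpec(proto))


class TestOfftargetScan:
    def test_perfect_site_and_pam_requirement(self):
        proto = "GATTACAGATTACAGATTAC"
        subject = NucleotideSequence("TT" + proto + "AGG" + "TT", "s")
        hits = scan_offtargets(GuideSpec(proto), [subject], 4)
        assert len(hits) == 1
        assert hits[0].mismatch_count == 0
        assert hits[0].position == 3 and hits[0].strand == "+"
        bad_pam = NucleotideSequence("TT" + proto + "ATT" + "TT", "s")
        assert scan_offtargets(GuideSpec(proto), [bad_pam], 4) == []

    def test_planted_mismatch_site_in_random_subject(self):
        rng = np.random.default_rng(11)
        proto = random_seq(rng, 20)
        site = list(proto)
        for i in (3, 9, 15):  # three mismatches
            site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
        subject = list(random_seq(rng, 2000))
        subject[1000:1020] = site
        subject[1020:1023] = "CGG"
        subject = NucleotideSequence("".join(subject), "chr_test")
        hits = scan_offtargets(GuideSpec(proto), [subject], 4)
        oracle = [
            h for h in brute_force_offtarget_windows(proto, subject.bases) if h[2] <= 4
        ]
        assert len(hits) == len(oracle)
        planted = [h for h in hits if h.position == 1001 and h.strand == "+"]
        assert len(planted) == 1 and planted[0].mismatch_count == 3

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        proto = random_seq(rng, 20)
        subject = random_seq(rng, 300)
        hits = scan_offtargets(
            GuideSpec(proto), [NucleotideSequence(subject, "s")], 12
        )
        oracle = brute_force_offtarget_windows(proto, subject)
        assert len(hits) == sum(1 for h in oracle if h[2] <= 12)
        assert hits == sorted(
            hits, key=lambda h: h.mismatch_count
        ) or [h.mismatch_count for h in hits] == sorted(h.mismatch_count for h in hits)
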