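"""Global aligner under the (1, 0, -2, 0) scheme, and variant extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampedit.align import ScoringScheme, extract_variants, global_align
from oracles import enumerate_best_score, wsb_best_score
from conftest import random_seq


def mutate(seq: str, pos0: int) -> str:
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos0] + flip[seq[pos0]] + seq[pos0 + 1 :]


class TestScores:
    def test_identity(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 60)
        aln = global_align(ref, ref)
        assert aln.score == 60 and aln.ops == [("match", 60)]

    def test_contiguous_deletion_costs_flat_two(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 50)
        q = ref[:20] + ref[30:]
        aln = global_align(q, ref)
        assert aln.score == 40 - 2
        assert [(op, n) for op, n in aln.ops if op == "deletion"] == [("deletion", 10)]

    def test_scattered_substitutions_do_not_open_gaps(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 50)
        q = mutate(mutate(mutate(ref, 5), 23), 44)
        aln = global_align(q, ref)
        assert aln.score == 50 - 3
        assert all(op in ("match", "mismatch") for op, _ in aln.ops)

    def test_n_scores_as_mismatch_never_match(self):
        ref = "ACGTACGT"
        q = "ACGNACGT"
        aln = global_align(q, ref)
        assert aln.score == 7
        assert ("mismatch", 1) in aln.ops
        # N against N is still not a match
        assert global_align("NNNN", "NNNN").score == 0

    def test_result_invariants_and_score_recompute(self):
        rng = np.random.default_rng(3)
        scheme = ScoringScheme()
        for _ in range(50):
            q = random_seq(rng, int(rng.integers(5, 40)))
            r = random_seq(rng, int(rng.integers(5, 40)))
            aln = global_align(q, r, scheme)
            assert aln.query_length() == len(q)
            assert aln.reference_length() == len(r)
            assert aln.recompute_score(scheme) == aln.score

    def test_cigar_forms(self):
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 30)
        q = ref[:10] + ref[15:]
        aln = global_align(q, ref)
        # gap placement may shift within repeat context; the shape is fixed
        assert aln.cigar().count("D") == 1 and "5D" in aln.cigar()
        assert sum(n for op, n in aln.ops if op == "match") == 25
        assert "=" in aln.cigar(extended=True) and "M" not in aln.cigar(extended=True)


class TestOracleEquivalence:
    def test_wsb_oracle_agrees_with_exhaustive_enumeration(self):
        """The general-gap DP oracle is itself validated by brute-force
        enumeration of every alignment on tiny instances."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            q = random_seq(rng, int(rng.integers(1, 6)))
            r = random_seq(rng, int(rng.integers(1, 6)))
            assert wsb_best_score(q, r) == enumerate_best_score(q, r)

    def test_aligner_matches_independent_oracle_small(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            q = random_seq(rng, int(rng.integers(1, 9)))
            r = random_seq(rng, int(rng.integers(1, 9)))
            assert global_align(q, r).score == wsb_best_score(q, r)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=10),
        st.text(alphabet="ACGTN", min_size=1, max_size=10),
    )
    def test_aligner_matches_oracle_with_ambiguity_codes(self, q, r):
        assert global_align(q, r).score == wsb_best_score(q, r)


class TestGapSemantics:
    def test_one_long_gap_beats_split_gaps(self):
        """Deleting a repeated unit must come out as a single contiguous gap
        (cost 2), not as two separate gaps (cost 4)."""
        rng = np.random.default_rng(7)
        left, unit, right = random_seq(rng, 12), random_seq(rng, 6), random_seq(rng, 12)
        ref = left + unit + unit + right
        query = left + unit + right
        aln = global_align(query, ref)
        gaps = [(op, n) for op, n in aln.ops if op in ("insertion", "deletion")]
        assert gaps == [("deletion", 6)]
        assert aln.score == len(query) - 2

    def test_gap_pair_preferred_over_mismatch_run(self):
        """A shifted segment should align via one deletion plus one insertion
        (cost 4) rather than a run of >= 5 mismatches."""
        rng = np.random.default_rng(8)
        prefix, shared = random_seq(rng, 10), random_seq(rng, 20)
        lost, gained = random_seq(rng, 6), random_seq(rng, 6)
        ref = prefix + lost + shared
        query = prefix + shared + gained
        aln = global_align(query, ref)
        assert aln.score == len(prefix) + len(shared) - 4
        ops = dict(aln.ops and [(op, n) for op, n in aln.ops if op in ("insertion", "deletion")])
        assert ops == {"deletion": 6, "insertion": 6}


class TestExtractVariants:
    def test_identity_yields_no_events(self):
        rng = np.random.default_rng(9)
        ref = random_seq(rng, 40)
        assert extract_variants(global_align(ref, ref), ref, ref) == []

    def test_single_deletion_maps_directly(self):
        rng = np.random.default_rng(10)
        ref = random_seq(rng, 40)
        q = ref[:19] + ref[22:]
        events = extract_variants(global_align(q, ref), q, ref)
        dels = [e for e in events if e.type == "deletion"]
        assert len(dels) == 1 and dels[0].size == 3
        # re-applying the deletion to the reference reproduces the query
        e = dels[0]
        assert ref[: e.reference_position - 1] + ref[e.reference_position - 1 + e.size :] == q

    def test_homopolymer_indels_left_aligned(self):
        ref = "TTGCAAAAGC"
        q_del = "TTGCAAAGC"  # one A removed from the AAAA run
        events = extract_variants(global_align(q_del, ref), q_del, ref)
        assert events == [type(events[0])("deletion", 5, 1)]
        q_ins = "TTGCAAAAAGC"
        events = extract_variants(global_align(q_ins, ref), q_ins, ref)
        assert events[0].type == "insertion"
        assert events[0].reference_position == 4  # before the run
        assert events[0].alt_sequence == "A"

    def test_inconsistent_alignment_rejected(self):
        ref = "ACGTACGT"
        aln = global_align(ref, ref)
        with pytest.raises(ValueError):
            extract_variants(aln, ref + "A", ref)
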