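# Methods

## The assay being modelled

A single-base deletion allele (the *Cybb* c.517delC equivalent) is
corrected by Cas9-induced homology-directed repair from a donor that
restores the deleted cytosine and introduces two silent substitutions in
the guide/PAM footprint. PCR of a ~274-bp window around the cut site,
sequenced as overlapping paired-end reads, samples the resulting allele
population. Three allele classes exist: HDR (reference + 1 nt, markers
present), NHEJ (reference with a small indel at the cut) and unmodified.
The package estimates their multinomial composition from the reads.

Throughout, the *mutant* (deletion) allele is the alignment reference:
it is the genotype of the treated cells, so unmodified reads match it
exactly and HDR reads appear as a 1-bp insertion plus the marker
substitutions. All user-facing coordinates are 1-based inclusive;
edit-site positions are expressed in wild-type coordinates, and the
`AlleleSet` derives the mutant-frame cut site used during classification.

## Pipeline stages and their parameters

**Merge.** R2 is reverse-complemented and quality-reversed; the best
R1/rcR2 overlap is found by scoring every ungapped offset with match +1 /
mismatch −1. This realises "local alignment with prohibitive gap
penalties" exactly: under gapOpen = gapExt = −10 no gapped local alignment
can beat an ungapped one, so the scan is both faster and provably
equivalent. Defaults: `min_overlap = 15` nt, `max_error_rate = 0.1`
(mismatch fraction inside the overlap); both exposed. At conflicts the
higher-quality base wins; quality ties keep the R1 base (deterministic).
Unmerged pairs are excluded from classification but counted.

**Trim.** The reference's first and last 15 bases are located in the
aggregate by approximate matching with a per-anchor budget of 2 errors,
mismatches and 1-bp indels counting equally (the two-error budget is
interpreted per anchor, not total). Ties go to the outermost placement,
which keeps maximal read content and makes trimming idempotent on
pipeline data. Anchor search is delegated to edlib (infix mode, k = 2);
reads missing either anchor go to a reported "unanchored" bin. Both
alleles share the amplicon termini, so anchoring is allele-neutral
(tested).

**Align.** Unique trimmed sequences are globally aligned to the reference
under match 1 / mismatch 0 / gapOpen −2 / gapExtension 0 (a three-state
Gotoh DP, numba-compiled). Consequences of this scheme, asserted as
tests: a gap of any length costs a flat 2; one contiguous gap always
beats two split gaps (Δ ≥ 2); a gap pair beats ≥ 5 mismatches. Because
gap length is free, co-optimal gap placements are common; determinism
comes from a fixed traceback preference (prefer staying in an open gap —
fewer openings — then a fixed state order) plus left-alignment of indel
events within homopolymer/repeat context during variant extraction. `N`
scores as a mismatch against everything, so fill bases can never create
matches. A fast path skips the DP when query and reference have equal
length and ≤ 4 mismatches: a gapped alternative must forfeit two gap
openings plus at least one aligned base (≥ 5 match-equivalents), so the
identity alignment is optimal there.

**Classify.** `ClassificationPolicy` makes every disputable choice
explicit:

* `analysis_window = 20` nt around the cut site: indels outside it are
  treated as artifacts, inside it as NHEJ. The window comfortably covers
  the simulated indel spectrum (≤ 10 nt deletions, ± 3 nt jitter) plus
  left-alignment drift.
* HDR requires the restored base **and** both markers with no window
  indel; a read with the restored base plus a window indel is NHEJ
  (indel-over-HDR precedence, the conservative convention).
* Substitutions never reclassify a read; otherwise calls would be hostage
  to the sequencing error rate.
* The denominator is reads surviving merge + anchoring; attrition is
  reported at every stage.

One consequence: a sequencing error on the restored base or a marker
demotes a true HDR read to NHEJ (~0.9% of HDR reads at a 0.3% error
rate). This small conservative bias is well inside binomial noise at the
sample sizes used and is visible in the recovery tests.

**Summarise.** Percentages over classified reads sum to 100 by
construction. The Results object adds binomial standard errors and Wilson
confidence intervals for each class, treating reads as independent draws
(PCR duplicates are not modelled; see limitations).

## Synthetic data generator

The generator defines the study conditions for all tests, since the
original sequencing runs are not deposited anywhere retrievable. The
default amplicon (`synthetic_cybb_allele_set`) is a **synthetic** random
274-bp mutant reference reproducing the documented architecture: a 21-nt
protospacer matching the mutant allele perfectly (a guide extended by one
5' nucleotide), TGG PAM, blunt cut 3 bp 5' of the PAM, the deleted C
restored between non-C neighbours (so the insertion position is
unambiguous), and two silent markers — one in the guide footprint, one
destroying the PAM.

Defaults and why:

* proportions 19% HDR / 75% NHEJ / 6% unmodified — the treated-sample
  composition regime of such experiments (high on-target activity with
  constitutive Cas9, HDR at clinically relevant levels);
* `read_length = 150`, fragment = whole amplicon: overlapping pairs from
  fixed PCR primers (no shearing), overlap = 2·150 − 274 = 26 nt;
* substitution error 0.003/base, weighted by the per-base Phred error
  probability and normalised so the dataset-wide mean equals the
  configured rate; qualities are Gaussian on the Phred scale
  (mean 37 → 33 across the read, sd 3, clipped to [2, 41]);
* indel spectrum: deletions of 1–10 nt (probability decaying with size)
  plus 10% +1 insertions, start jittered ± 3 nt around the cut — a
  plausible NHEJ profile; no spectrum is published for this locus;
* sequencing *indel* errors are not simulated, so per-read class truth
  stays exact; substitution-only noise is what the classifier is
  guaranteed robust to (the false-indel floor is exactly zero by
  construction and by test).

What passing tests therefore show: the pipeline recovers known
compositions from overlapping, substitution-noisy amplicon reads. What
they cannot show: robustness to PCR chimeras, polymerase slippage indels,
adapter read-through, large structural variants or sequencer-specific
error profiles — none of which are emulated.

## T7EI estimator

`indel% = 100·(1 − √(1 − fcut))`, `fcut = Σcut/(uncut + Σcut)`, assuming
random re-annealing of a two-population duplex (heterozygote fraction
2p(1−p)). The estimator is monotone, scale-invariant and bounded in
[0, 100]; a lane with no uncut band returns 100 with a saturation
warning. The provenance of the formula is the assay's standard
literature; it is stated here as an explicit assumption.

## Numerical and testing choices

* Oracles: the aligner is checked against a Waterman–Smith–Beyer
  general-gap DP (a structurally different algorithm), itself validated by
  exhaustive enumeration of all alignments on tiny instances; overlap
  detection against a naive per-offset scan; off-target scanning against
  a brute-force window enumeration; recovery tests against the
  generator's per-read truth at 3-binomial-SE tolerance.
* Problem sizes were chosen to keep the default suite in the
  low minutes: 20,000-pair libraries over ten seeds for noisy recovery,
  5,000 pairs for exact error-free recovery, 1,000 random pairs for
  alignment optimality.
* Determinism: one seeded NumPy generator per simulation with a fixed
  draw order; gzip members written with a fixed mtime so FASTQ output is
  byte-identical across runs; alignment traceback and tie-breaks fixed as
  above.
* Degenerate inputs: empty samples raise an explicit error; saturated
  T7EI lanes warn; anchors crossing each other reject the read;
  IUPAC codes other than N are rejected at sequence construction.

## Known limitations

* Reported indel event *positions* depend on the stated normalisation
  convention; other implementations of the same scoring may place
  co-optimal gaps differently (class counts are unaffected).
* No UMI deduplication, translocation/large-deletion detection or allele
  phasing; reads are treated as independent draws.
* The frameshift, in-silico PCR and off-target utilities operate on
  user-supplied sequences; validating them against a live genome
  assembly requires external data and is out of scope for the offline
  test suite.
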