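# Methods

This note documents the models, conventions and numerical choices behind
`hitikit`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where several reasonable options existed.

## Coordinates, guides and cuts

All coordinates are 0-based, half-open.  `cut_pos` names the first base 3′
of the blunt SpCas9 cut on the reference **top strand**, whichever strand
the guide binds.  The cut is placed `cut_offset` nt from the PAM-proximal
end of the 20-nt protospacer; the default `cut_offset = 3` gives the
canonical SpCas9 blunt cut between protospacer positions 16|17 (so on the
plus strand `cut_pos = protospacer_start + 17`; on the minus strand the
mirrored coordinate).  PAM patterns use IUPAC codes (default `NGG`).  `N`
in a reference never matches a protospacer base — guide placement is
conservative — and a guide must occur exactly once on either strand;
multiple occurrences raise an ambiguity error listing all positions.

## Donor anatomy and integration model

A donor cassette is `inverted site | STOP cassette | START | payload CDS |
polyA | inverted site`, where each inverted site is the reverse complement
of the concrete genomic protospacer+PAM.  Defaults:

| part | default | length | notes |
|---|---|---|---|
| STOP cassette | `TAAATAAATAAATAAATAAATAAA` | 24 nt | six TAA codons at offsets 0,4,8,…, covering all three frames; any string with ≥ 6 stops covering all frames is accepted |
| kozak START | `GCCACC` | 6 nt | consensus kozak placed directly before the payload ATG; configurable |
| IRES START | fixed synthetic 50-mer | 50 nt | a stand-in with the documented 50-nt length; the biological IRES identity is irrelevant to the integration arithmetic |
| polyA | synthetic AATAAA-bearing element | 49 nt | configurable |
| size cap | 2700 nt | — | single-AAV donor payload budget |

Integration is modelled as blunt cuts at the genomic site and at the
internal cut position of each donor flank, followed by precise ligation of
the released core (no end resection; junction indels are injected only by
the simulator).  In an inverted flank the cut sits at `pam_len +
cut_offset` from the flank's 5′ end (the mirror of the site-internal cut);
a direct-orientation flank — a design error the validator flags — is cut
at the site's own cut position, which is what makes such donors regenerate
two intact sites after forward integration.  `recleavable_sites` is
computed by an exact protospacer+PAM scan of the whole edited allele on
both strands, not assumed: forward integration of a well-formed donor
yields 0 sites, inverted integration 2, an unedited locus 1.  Re-cleavage
uses exact-match semantics (one protospacer mismatch ⇒ not cleavable);
mismatch-tolerant scoring is out of scope.

## Synthetic-data generator

The generator defines the study conditions for every downstream test.  An
`OutcomeMixture` draws each allele's fate from {unmodified, NHEJ indel,
precise HITI, imprecise HITI, inverted HITI, vector fragment} with a
seeded multinomial.  Choices:

* **NHEJ indel lengths**: truncated geometric over 1..50 (`p = 0.25`,
  mean ≈ 4 nt), deletions:insertions 3:1 — small-deletion-dominated
  spectra typical of NHEJ repair; fully configurable.  Deletions straddle
  the cut symmetrically; insertions are random bases at the cut.
* **Imprecise HITI**: the forward-integration allele with an indel at the
  5′ junction, the 3′ junction, or both (probabilities 0.4/0.4/0.2).
* **Vector fragments**: a random 50–500-nt segment of a mock AAV genome
  (two 145-nt ITR stand-ins flanking the cassette) inserted at the cut in
  random orientation.
* **Error model**: substitution-only (default rate 0) so that every
  called indel is attributable to a simulated editing event; qualities
  are constant Q30 (Phred+33) and unused downstream.
* **Read designs**: paired 150-nt amplicon reads from the two ends of each
  PCR amplicon (amplicons delimited by a shared forward primer and one
  reverse primer per allele form; the bundled design uses ~220-nt
  amplicons with the cut 105 nt from the forward primer so both mates of
  either amplicon span the ±17-nt window); single-end junction reads
  generated at 600 nt and truncated to 350 nt; capture reads drawn with
  start positions weighted `enrichment_factor` (default 50×, a free
  parameter) over regions of interest, with episomal vector molecules
  carrying copy-number weight.

Every allele record stores its generating events, and a replay function
re-derives the sequence from them; seeded runs are byte-identical.

What the generator does **not** emulate: PCR amplification bias and
chimeras, duplicate reads, quality-score structure, sequencing indel
errors (available but off by default), homology or microhomology at
junctions, and large structural rearrangements.  Passing tests therefore
demonstrate correctness of the quantification logic under clean,
fully-labelled conditions — not robustness to every artefact of real
libraries.

## Alignment

`align_local` is Smith–Waterman with affine gaps (gap of length k costs
`gap_open + k·gap_extend`), local mode, both strands, soft clips for
unaligned query ends.  The engine is Bio.Align's C implementation; CIGAR
extraction from alignment coordinates, strand policy, indel
left-normalisation, clip accounting and the `min_score` cutoff are
implemented here, and scores are cross-checked in the test suite against
an independent brute-force affine DP oracle on short random pairs.

* **Presets**: the default preset (match 1, mismatch 4, open 6, extend 1,
  min_score 20) represents real editing indels as I/D operations; the
  strict preset (match 1, mismatch 50, open 60, extend 10) transcribes the
  near-exact-identity external-aligner regime into SW terms, so any
  divergent read segment is soft-clipped — the behaviour the split-read
  procedure consumes.  Equivalence with the external aligner is claimed
  only at the level of the partial-vs-full alignment classification, not
  bit-for-bit.
* **Tie-breaks**: an exact occurrence of the query attains the maximal
  possible score and short-circuits the DP at its leftmost position;
  otherwise the engine's deterministic first optimal alignment is taken
  and indels are shifted leftward while score-preserving (the
  variant-calling left-alignment convention).
* **clip_penalty** is applied as a post-hoc per-clipped-end deduction from
  the reported score (both presets use 0).
* A best local score below `min_score` (or ≤ 0) is a no-hit value, not an
  error.  Multi-hit and split/supplementary records are out of scope; one
  best local hit per reference suffices for every procedure here.

## Windowed quantification

The cleavage window is ±`flank` nt around the cut (default 17, i.e. a
34-nt interval `[cut−17, cut+17)`), read as "17 nt upstream **and**
downstream".  A read is *modified* iff an I/D event in its CIGAR overlaps
the window; deletions occupy `[pos, pos+len)`, insertions are points
counted when `cut−flank ≤ pos ≤ cut+flank` (the closed right edge
attributes boundary ligation-point insertions to the cut).  Substitutions
never count as modification.  Reads whose alignment does not span the
whole window are uninformative and excluded from denominators.

In dual-amplicon estimation each read is assigned to the reference (wild-
type or hybrid amplicon) with the higher local score; equal scores are
ambiguous and excluded.  Hybrid-assigned reads count as HITI alleles;
wild-type-assigned, window-spanning reads are subclassified indel vs
unmodified.  The denominator is assigned reads (`assigned = unmodified +
indel + hiti`, exactly).  When `clip_penalty = 0` the assignment uses
score-only computations and extracts a full alignment only for wild-type-
assigned reads.

Junction species are `(type, length)` groups over window-spanning
junction-amplicon reads; species frequencies are computed over spanning
reads (the alternative — all reads — is a one-line change in the report
denominator) and filtered by the tissue threshold: retina 0.1%, liver
0.5%, comparison inclusive (≥), so a species at exactly the threshold is
kept.  The filter is idempotent.

## Split-read integration detection

Reads are aligned to the donor insert under the strict preset.  Alignments
with total clipping ≤ 5 nt are insert-only evidence (episomes/
concatemers); partial alignments are partitioned into the aligned insert
portion and the clipped flank (when both ends are clipped the larger clip
is the flank; the alternative — emitting both — would double-count
molecules).  Thresholds are strict inequalities: insert portion > 22 nt
and flank > 30 nt, matching "longer than".  Flanks realign against every
reference (vector genome + host chromosomes); the single best-scoring
reference collects the count, ties are ambiguous and excluded, and flanks
below `min_score` everywhere are unmapped.  On-target counting anchors on
reads whose insert alignment is partial **and** covers insert positions
[0, 10) (reverse-orientation integrations are caught because alignment is
strand-aware), realigns them to the target gene and counts overlaps with
the cleavage region; the frequency denominator is all reads overlapping
the cleavage region, a choice documented here because the source procedure
reports raw counts without a frequency formula.

## Hardy–Weinberg prediction

Genotype frequencies are `p_i²` (homozygotes) and `2·p_i·p_j`
(heterozygotes, stored once per unordered pair); the table sums to 1.  The
heterozygote adjustment halves the wild-type frequency measured in
homozygous wild-type animals and assigns an equal share to the mutant
allele (86% → 43% + 43%); remaining classes are renormalised to sum to 1,
which preserves their measured values exactly since the non-wild-type
total (1 − wt) is unchanged by the operation.

## Problem sizes and reproducibility

The bundled analyses and checks run at desk scale: the demo locus is a
383-nt reference with a 300-nt payload (425-nt cassette); dual-amplicon
estimation uses 5,000 alleles sequenced to 20,000–50,000 reads, junction
profiling 1,000–4,000 single-end reads, and capture detection 1,200–3,000
reads over a 4-chromosome 6-kb-per-chromosome mock genome — sizes at which
binomial noise on the recovered fractions is well below the effects being
measured.  All randomness flows from explicit seeds (one top-level seed
per driver, per-stage streams derived deterministically), and identical
configurations produce byte-identical FASTQ output.

## Known limitations

* The aligner is exhaustive-DP-based and unindexed; it is sized for
  amplicon references and few-kb mock chromosomes, not whole genomes.
* Dual-amplicon estimation assumes the two amplicons amplify with similar
  efficiency and length (the simulator enforces this); real PCR
  competition would bias the recovered fraction.
* Inverted-HITI alleles are not separately classified by the dual-amplicon
  quantifier: their reads assign to the wild-type amplicon (junction-
  spanning mates are excluded as non-window-covering or counted
  unmodified), mirroring the blind spot of the assay design itself.
* Junction-species isolation reports what alignment represents as a
  single I/D run; complex junctions (indel + substitution clusters) may
  fragment into several events.
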