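# Methods

This note documents the models, parameter defaults and design
decisions behind `amplitype`, and what its synthetic-data tests do and
do not demonstrate about real sequencing data.

## Problem setting

HLA-B alleles are distinguished almost entirely by exons 2 and 3,
which encode the peptide-binding domain. Typing from a ~1 kb amplicon
spanning both exons with single-molecule long reads resolves phase
(which variants co-occur on one chromosome) directly, at the cost of a
high indel-dominated per-base error rate. The package implements the
full desk-scale loop: reference handling, run simulation,
demultiplexing, QC, diploid allele-pair calling, and cohort
statistics.

## Allele references and G-groups

References are amplicon sequences with 0-based half-open exon 2/3
intervals supplied in a TSV sidecar; user-facing reports use 1-based
exon-local coordinates. Alleles with identical concatenated exon 2+3
sequence are typing-equivalent and are reported as one G-group, named
after the numerically smallest member truncated to three fields with a
trailing `G`; singleton groups keep their own name. If the smallest
member of a multi-member group has fewer than three fields the name is
padded with `1` to reach the three-field G-group form (an edge case
that cannot occur with the packaged synthetic references). In-silico
PCR matches the degenerate primer pair IUPAC-aware on both strands;
when several products are possible the shortest wins, since degenerate
primers can have spurious distal sites.

## Read simulator

The simulator is the package's study-condition generator, not a test
utility: its defaults are the conditions every stochastic test runs
under.

**Error model.** Per-base substitution 2.8%, insertion 1.0%, deletion
3.5% — a deletion-dominant 7.3% total, the legacy-2D R9-chemistry
profile. Only the total and the deletion component are well
constrained by published error characterization; the substitution/
insertion split is our choice, keeping the profile deletion-dominant.
A read walks its template base by base: delete, else emit with
possible substitution (uniform over the three alternatives), then
insert a uniform base after the position with `p_ins`.

**Repeat deletions.** Inside annotated short-tandem-repeat intervals
deletions are elevated by `repeat_del_multiplier` (default 3×). For a
perfectly periodic run the extra deletions are modeled as whole-unit
slippage: each repeat unit drops with probability
`(m − 1)·p_del/(1 − p_del)` per read (the divisor compensates overlap
with baseline deletions so the in-run per-base deletion rate is
exactly `m·p_del`). Unit slips matter because deleting a whole `GA`
unit from `(GA)n` yields the same read no matter which unit slipped,
so the aligner stacks all slip deletions on one canonical column —
which is how a 2–4 nt repeat deletion becomes a systematic,
phase-breaking pileup signal rather than diffuse noise. Single-base
deletions in an alternating repeat are *not* alignment-ambiguous and
disperse harmlessly; a per-base-only boost therefore cannot reproduce
the artifact, which is why the non-periodic remainder of a masked
interval falls back to the plain per-base multiplier.

**Templates and barcodes.** A sequencing template is
`left_tail(36) + barcode(24) + amplicon(943) + rc(barcode)(24) +
right_tail(36)` = 1,063 bp. Barcodes are random 24-mers kept at
pairwise edit distance ≥ 9. Tail and barcode sequences are synthetic;
only their lengths (and the resulting 943 → 1,063 bp shift) are
modeled on the emulated chemistry.

**Quality and depth.** Quality strings are phenomenological: one
per-read mean Q drawn from Normal(12, 3) truncated to [2, 30], applied
flat across the read. They carry no information about where errors
sit, so only mean-Q filtering should consume them. Per-sample depth is
either constant or log-normal (median 2,000, σ=1.3, clipped to
[80, 17,500]) to emulate the heavy multiplexing skew of pooled runs;
80 reads is the floor at which confident calls are still expected.

**Determinism.** One `numpy` generator seeded per run drives every
draw in a fixed order; identical seeds give byte-identical FASTQ.

## Synthetic allele set

Ten 943 bp alleles share a backbone carrying concrete realizations of
the degenerate amplification primers at its termini, exon 2 at
[64, 334), exon 3 at [580, 856), and a planted `GAGAGA-R-GAG` context
at exon 2 positions 127–136 whose R (position 133) alternates A/G
across alleles. Each allele adds four private exonic substitutions
drawn from disjoint position pools, so pairwise exon distance is ≥ 7.
Random backbone segments are generated with bounded local
repetitiveness (no homopolymer ≥ 4 bp, no 5 bp dinucleotide
alternation): short quasi-repeats concentrate baseline deletions onto
single columns at up to ~3× the nominal rate, and an unconstrained
backbone would scatter such columns through the exons, blurring the
one deliberately planted deletion-prone tract that the study design
calls for.

What this does *not* emulate: real allele databases have thousands of
alleles at much smaller (often 1 nt) pairwise exon distances,
correlated variant blocks, and length polymorphism; real nanopore
error is context-dependent beyond repeats and correlated with reported
quality; chimeric reads and 1D/2D chemistry differences are not
modeled. Passing tests demonstrate the algorithmic machinery under the
declared noise model, not clinical-grade performance on real runs.

## Demultiplexing

Each barcode and its reverse complement is aligned semi-globally
(edlib, free end gaps on the window) against the first and last 150
bases of the read; the best distance over barcodes × ends ×
orientations decides. Defaults: `max_edits` = 25% of barcode length,
`min_margin` = 2 to the runner-up; two ends confidently matching
different barcodes → unclassified. Because the template carries the
same barcode forward on the left and reverse-complemented on the
right, barcode matching is orientation-symmetric by construction; the
`orientation` field reports which barcode orientation matched, and
read strand is actually settled later at primer trimming.

## Read QC

Mean read quality averages error *probabilities*, then converts back
to Phred (so half Q10 / half Q20 is 12.6, not 15) — the convention
used by nanopore pass/fail filters. Default filter: mean Q ≥ 15 and
length within [0.8, 1.25] × amplicon (754–1179 bp for 943). N50 is the
smallest L such that reads ≥ L hold at least half of all bases.

## Genotyping engine

**Alignment.** Reads are oriented and trimmed by locating the forward
primer and the reverse-primer site (IUPAC-aware) on both strands;
trimming is refused (read passed through, strand `?`) when either
primer needs more than 25% of its length in edits. Trimmed reads are
aligned to each candidate allele with edlib in semi-global mode — free
end gaps on the allele — so partial reads pay nothing for uncovered
reference; residual tail bases appear as terminal read insertions and
never reach the exon-restricted score. Alignment traceback ties follow
edlib's deterministic internal order; all scored quantities depend
only on edit distances and on the per-column projection, both stable
across runs.

**Shortlist.** Each read votes for its minimum-distance allele(s);
the top k = 6 by votes are kept, plus any allele within 10% of the
k-th vote count. On sets of ≤ 8 alleles with k = set size this
provably equals exhaustive enumeration (asserted against a brute-force
oracle in the tests).

**Consensus.** Reads assigned to one allele are projected onto its
columns; per column the majority among {A, C, G, T, gap} wins with
ties toward the reference; a gap majority deletes the column;
insertions are kept only when more than half of the reads overlapping
the junction support one. Columns whose runner-up base/gap reaches
`het_fraction` of coverage (with at least 3 reads and coverage ≥ 6)
are flagged *mixed*.

**Why mixed columns count as mismatches.** A majority consensus of a
50/50 heterozygous pileup collapses onto whichever reference it is
compared against, so a homozygous hypothesis would score zero on
heterozygous reads if only consensus-vs-reference edits counted. A
mixed column is exactly the evidence that one reference cannot explain
the reads — the pileup analogue of an IUPAC ambiguity code in a Sanger
trace — and counts one mismatch. The threshold 0.22 separates the
three regimes of the declared noise model: heterozygous columns sit
near 0.5, repeat-slippage columns near `1 − (1 − q)^n_units` ≈
0.2–0.35, and the strongest baseline concentration (a 3 bp
homopolymer) near `3·p_del` ≈ 0.105. It deliberately sits *below* the
slippage regime so that repeat artifacts surface as mismatches to be
flagged and masked, and *above* baseline concentration so clean
samples score zero.

**Pair scoring and ranking.** Reads go to the nearer member of a
pair; equidistant reads are unassignable (counted for depth, excluded
from consensus). A pair whose rarer member draws under
`minor_fraction` = 0.2 of assignable reads is demoted to the majority
homozygote — the defense against allele dropout mimicking
heterozygosity. The pair score is the sum over both members of
consensus-vs-reference edits (mixed columns included) restricted to
exon 2+3 columns. Pairs are ranked by ascending total, then descending
minimum member support, then descending total support, then name.
Ambiguity is flagged when ≥ 2 distinct pairs tie on mismatches *and*
support: pairs whose every read is equidistant to both members (e.g.
two alleles the sample does not carry) score zero with zero support
and are not competing calls, whereas pairs differing only by intron
variants of one member tie exactly and are genuine ambiguity, reported
under one G-group name. A best pair with total > 0 is annotated
`manual-review` and the full ranked list is preserved.

**Hotspots and masked rescoring.** Mismatch positions recurring in at
least half of the top-5 pairs are reported as hotspots in 1-based
exon-local coordinates (comparable across alleles); positions inside
an allele's repeat mask are labeled repeat-associated. Masks are the
detected STR intervals padded by 3 bp on each side, because aligners
place a repeat deletion at a canonical (typically rightmost) column
that can fall just past the literal run. `rescore_masked` repeats pair
scoring with masked exon columns excluded; `adjudicate_with_mask`
rescoring of the top-10 ranked pairs is the automatic counterpart of
manually assigning the least-mismatch pair when a repeat artifact
blocks the automatic call.

**Depth floor.** Calls are refused below 20 reads unless overridden;
the floor is deliberately below the 80-read worst case the design
targets.

## Problem sizes

The test suite and acceptance checks run at desk scale by choice: 50
simulated samples at depth 80 for genotype recovery, ≥ 10⁵ simulated
bases for error-rate calibration, 12 samples × 100 reads for
demultiplexing fidelity, 1,000 random pairs against the independent
alignment oracle. The acceptance script measures simulator error rates
by global realignment of each read to its template; realignment finds
the *minimal* edit script, which occasionally merges adjacent
simulated events, so measured totals sit slightly below the generative
rate — the same property any alignment-based error estimate has.

## Known limitations

- Exon-identical alleles are inherently unresolvable by design
  (reported as G-groups); alleles differing only outside the amplicon
  are invisible.
- The caller assumes a diploid two-cluster model; copy-number
  variation, chimeras and contamination are out of scope.
- Mixed-column thresholds are calibrated to the declared error model;
  substantially different chemistries would need recalibration.
- Quality strings are a stand-in; error-aware base weighting is not
  implemented.
- No novel-allele discovery: the call space is the supplied reference
  set.
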