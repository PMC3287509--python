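# Methods

## Scope and model

The toolkit treats a bacterial genome as a string over {A,C,G,T,N} and a
tandem repeat as an array of near-identical copies of one *period*
laid head-to-tail. Strain typing rests on two observations about
endosymbiont genomes of the *Wolbachia* kind: (i) intergenic VNTR loci
expand and contract in period units while their flanks stay conserved,
so a PCR product sized from conserved-flank primers reads out copy
number; (ii) ankyrin-repeat (ANK) genes evolve by gain, loss and
shuffling of 33-aa units, so ortholog sizes differ in 99 bp steps and
unit order carries cladistic signal. Everything here is sequence
combinatorics and alignment; no thermodynamics, no read simulation, no
phylogenetic likelihood.

## Tandem repeat discovery (`trfind`)

**Seeding.** Exact k-mer matches (default k = 5) at distance
d ≤ 500 bp vote for candidate period d. Seeds at one distance are
grouped into runs (split at gaps > max(30, 2k)); runs need
max(2, ⌈0.12·d⌉) seeds and coverage of half a period before
verification. These two constants are sensitivity/speed heuristics
only — every reported array is re-scored by full alignment, so they
cannot inflate scores, only (rarely) miss very degenerate arrays.

**Verification.** Each run is verified by wraparound dynamic
programming (WDP): the candidate window is aligned against unbounded
tandem copies of a majority-vote consensus of the period-phased chunks,
the alignment path wrapping from period position p−1 back to 0. The DP
is run in a local (Smith–Waterman-style, floor-at-zero) variant so the
maximal-scoring sub-segment defines the array boundaries; the consensus
is then refined once by per-column majority vote over the aligned copies
and the window re-aligned. Scores are integers throughout
(match +2, mismatch −7, indel −7 per base), so traceback decisions are
exact. Reported quantities: period (consensus length), copy number
(total consensus positions consumed / period, one decimal, floor 1.8),
percent match/indels over alignment columns, score, and Shannon entropy
of the span's base composition. Windows above 10% N are skipped. Only
the forward strand is scanned — a tandem array is its own
reverse-complement's mirror, so the minus strand adds only duplicates.

**Harmonic reduction.** The same array surfaces at periods p, 2p, 3p….
Reports sharing ≥ 50% of their span with equal or near-multiple periods
(remainder ≤ 2) are collapsed to one representative: the top scorer,
except that a smaller-period report within 90% of the best wins.
Strictly keeping the higher score is not stable under between-copy
noise — the 2p report of a true p-array can beat p by a few points
because the two-chunk majority consensus resolves ties toward one chunk
and thereby matches that chunk exactly — and the minimal period is the
scientifically meaningful description of the array. Overlapping reports
with genuinely distinct spans (e.g. a short internal repeat inside a
larger array) are kept separately.

**Summary.** Genome-level summaries count each reported array once and
take unweighted means; total repeat coverage is the length of the
*union* of spans, so overlapping reports are not double-counted (raw
span summation is the alternative convention; union is what the
invariant `pct = 100·union/genome` assumes). Empty genomes report
absent (None) means, never zeros.

## VNTR decomposition (`vntr`)

`decompose_periods` aligns a locus against its period consensus with
the same WDP engine but gentler affine weights: match +2, mismatch −3,
gap open −5, gap extend −1. The repeat finder's 7-per-base indel cost is
a *reporting* threshold; for decomposition it would be self-defeating —
a trailing copy carrying a 25 bp deletion scores 80·2 = 160 in matches
against 175 in gap penalties and would be trimmed off by the local
alignment, though it is exactly the kind of half copy the locus notation
must capture. With affine costs such copies are bridged.

Instance boundaries are cut wherever consensus coordinate 0 is
consumed. Classification, in order of precedence:

1. **half** (0.5 copies): any internal deletion run ≥ 20 bp. The
   threshold sits between small indels tolerated inside full copies
   (observed up to 18 bp) and genuine half-copy deletions (observed
   ≥ 25 bp). Deletion runs interrupted by ≤ 2 aligned bases are merged
   (noise places the odd chance match inside a deleted block), and the
   merged length counts deleted bases only.
2. **full** (1.0): aligned fraction ≥ 0.9.
3. **partial** (aligned fraction, rounded half-even to one decimal):
   only at array ends.
4. Interior copies failing all three are called full — they are
   degraded, not structurally deleted.

Terminal groups consuming < 90% of the period are re-trimmed under a
stricter local objective (+1 per match, −3 otherwise) before
classification: the cheap gap extension otherwise chains lucky flank
matches onto a genuine partial. A surviving terminal partial must align
≥ 15% of the period at ≥ 85% identity with ≤ 10% inserted bases;
anything weaker is indistinguishable from flank and dropped. When the
flank genuinely continues the consensus for a net-positive stretch
(≈ 0.4% of AT-rich random flanks), the boundary is ambiguous in
principle and the copy number can be off by 0.1.

The copy string notation is `<full>[+<half>x0.5][+<fraction>]`, e.g.
`4+2x0.5` (copy number 5.0) or `7+0.3` (7.3).

Motif finders are exact-match and definition-driven: a direct repeat
unit is maximal (inextensible without losing occurrences), occurs ≥ 2
times non-overlapping, and must exceed 1 bit of composition entropy
(suppressing homopolymer/low-complexity hits); a dyad is a stem pair
`s[i..i+L) = revcomp(s[j..j+L))` with loop ≤ max_loop, maximal under
inward and outward extension. Inverted unit pairs are reported under
their own kind (`inverted_repeat`) rather than folded into either
category, since a 15 bp unit pair can legitimately be read as either.
Both finders are validated against brute-force enumeration.

## In-silico PCR (`mlva`)

Primer matching allows substitutions only (no indels), expands IUPAC
codes on the primer side, and scans both orientations; amplicons pair a
forward site with a downstream reverse-complement site (and the mirror
arrangement for reverse-oriented templates) up to a 5 kb product cap.
Product length spans both primer footprints, the standard convention
for printed PCR sizes. The default mismatch budget is 0: amplification
failure in diverged strains is information, so mismatch tolerance is an
explicit flag, never silently applied. All products at a locus are
reported; the human-readable "gel" report collapses lengths within 5 bp
(agarose resolution), but the data model never does. A profile is valid
only if the *wsp* control locus amplifies, mirroring its laboratory use
as an extraction control. Profile distance is Manhattan over per-locus
copy numbers with explicit NA exclusion (and the excluded-locus count
reported), since silent zeros would fabricate similarity.

## ANK architecture (`ank`)

Translation uses the bacterial code (table 11); the first in-frame stop
before 90% of the CDS is flagged premature, and all downstream analysis
works on the truncated protein — which is how a premature stop ablates
the C-terminal transmembrane segments.

Unit detection scans 33-residue windows against a packaged log-odds
profile (data/ank_seed.faa: a synthetic seed alignment of 13 units
around the canonical ankyrin consensus with its TPLH and GADVNA cores;
pseudocount 0.5, uniform background). Greedy left-to-right selection of
windows scoring ≥ 25 bits gives non-overlapping, possibly abutting
units. The threshold was calibrated on the empirical null: random
500-aa proteins peak near +3 bits while consensus-derived units at up
to 15% per-unit mutation stay above +55, so 25 sits in a wide margin of
that gap; the calibration is re-checked by the test suite's null and
recovery tests. Against profile-based annotators trained on curated
ANK families, absolute unit boundaries may differ by a few residues;
unit *counts* on tandem-ANK proteins are the robust quantity.

Transmembrane segments are maximal runs of 19-residue Kyte–Doolittle
window means > 1.6, expanded to window extent, merged across gaps
< 5 aa, reported at ≥ 15 aa. Protein masses use average (not
monoisotopic) residue masses plus one water, reported in kDa to one
decimal; X contributes the mean residue mass.

Insertion detection globally aligns gene against reference ortholog
(match 2, mismatch −7, gap open −7, extend −1 via Biopython's
PairwiseAligner) and reports reference-coordinate gaps ≥ 100 bp —
IS-element sized blocks are labelled as such at ≥ 500 bp. Orthology is
gated on the length-normalized score (score / 2·min length ≥ 0):
orthologs stay ≥ 0.5 even across a 918 bp insertion while unrelated
sequences score ≈ −0.45, a far sharper separation than per-column
identity, which the gap-affine scoring inflates on unrelated input by
aligning only sparse matches. Insertion *lengths* are exact when flanks
are unique; positions can shift by a base or two when an insertion
boundary happens to match its context.

Repeat units are multiply aligned by center-star (the unit with the
best summed pairwise score is the center; "once a gap, always a gap"
merging), adequate because units are 30–36 aa and near-equal length.
Trees are neighbor joining on p-distance (gapped columns excluded
pairwise) via scikit-bio, with negative NJ branch lengths clamped to
zero; for additive matrices NJ provably recovers the unique generating
tree, which the tests assert by patristic-distance round-trip.
Maximum-likelihood machinery is deliberately out of scope: on 33-aa
units branch support is weak no matter the optimizer, and the consumed
output is the *cluster structure* — single-linkage clusters at
p-distance 0.2 (80% identity), per-cluster unit order per strain,
duplication flags (one strain contributes adjacent indices to one
cluster) and shuffling flags (two strains' shared clusters in different
relative order).

## Synthetic data (`synthgen`)

The generator emulates the structures the analyses assume, with ground
truth serialized next to every sequence: tandem arrays with full,
internally deleted (half) and terminal partial copies; planted 15 bp
direct-repeat unit pairs and 9 + 5 + 9 bp hairpins inside periods
(boundary bases are pinned non-matching/non-pairing so planted motifs
are maximal exactly as planted); SNP noise between copies (≤ 10%);
conserved flanks whose outermost bases are the primer sites; ANK genes
back-translated from profile-consensus units (fixed most-frequent-codon
table) with optional duplications, swaps, premature stops, random
insertion blocks and two 23-aa hydrophobic tails separated by a 20-aa
hydrophilic loop. Backgrounds default to 35% GC, the AT-rich regime of
the target genomes. One seeded NumPy generator drives everything;
regeneration with the same seed is byte-identical.

What passing on synthetic data does *not* show: real VNTR periods are
not random sequence (they carry the internal structure that likely
drives slippage), real flanks are coding sequence, real ANK units
diverge position-specifically rather than i.i.d., and real data has
sequencing artefacts. The generator validates the algorithms'
contracts, not their field performance.

## Problem sizes and numerical choices

Default test and demonstration scales: genomes ≤ 30 kb, 200-replicate
recovery panels with periods 10–500 bp, copies 2–12, noise ≤ 5%
(recovery criterion: period ± 2, copies ± 0.3, ≥ 95% of replicates);
brute-force oracle comparisons on strings ≤ 100 bp (repeats) and
≤ 64 bp (motifs). These sizes exercise every code path at desk scale;
the same entry points run on 1.3 Mb genomes, where a full scan takes
minutes on one core. Rounding is half-even at one decimal wherever a
copy number is printed. Degenerate inputs: empty repeat lists summarize
to absent means; loci without alignable repeat structure return an
explicit empty decomposition rather than raising; all-identical units
produce a star tree with zero branch lengths.
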