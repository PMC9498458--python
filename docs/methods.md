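# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, in the spirit of a methods appendix.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and the circular genome

All internal coordinates are 0-based half-open; GenBank's 1-based
inclusive convention is converted at the I/O boundary only.  Features may
wrap the replication origin: their `end` then exceeds the genome length
and interval arithmetic runs on the doubled-coordinate representation
before normalization.  This keeps junction and extraction arithmetic free
of modular special cases.  Ambiguity codes beyond N are rejected on read
because every downstream codon statistic assumes unambiguous bases; N
sites are excluded from counts (numerator and denominator alike).  The
two leucine and two serine tRNAs are disambiguated by anticodon when
annotated, else by the product qualifier; unresolvable copies are kept
with a `?`-suffixed name and a warning.

## Architecture conventions

Junctions are computed between consecutive genes in genomic order
regardless of strand, because published overlap/spacer totals pool both
strands.  The two control-region-adjacent junctions are excluded from the
totals by default (`include_cr` restores them): partial control-region
assemblies make CR-flanking gaps artifacts of assembly rather than
biology.  Nested features are rejected rather than silently resolved.
The conservation identity Σ spans − Σ overlap + Σ spacer = genome length
holds exactly on every generated genome and is enforced in the acceptance
checks.

Rearrangement comparison is block-level: displaced genes are the
complement of a longest common subsequence of the two circular orders
(anchored at COX1 for rotation invariance), and the
*trnI-trnQ-trnM → trnM-trnI-trnQ* translocation is flagged as the
Lepidoptera-type TDRL pattern when and only when removing trnM reconciles
the two orders.  No general TDRL event-history reconstruction is
attempted — the flag asserts the known pattern, nothing more.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C); a zero denominator
yields a missing value, never an exception.  Per-gene skews are computed
on the **coding strand** of each gene, not the genomic majority strand:
minority-strand genes (ND1, ND4, ND4L, ND5) then show the positive GC
skews characteristic of published per-gene analyses.  Report rounding is
0.1 for percentages and 4 decimals for skews; in-memory values keep full
precision and rounding happens only in the report layer.

## Codon usage

The genetic code is fixed to the invertebrate mitochondrial code
(translation table 5, via Biopython): 62 sense codons, stops {TAA, TAG},
AGA/AGG = Ser, ATA = Met, TGA = Trp.  RSCU(c) = count(c) / mean count of
c's synonymous family; families with zero usage are reported missing
(NaN), not 0, while an absent codon of an observed family is exactly 0,
so Σ RSCU over an observed family always equals its degeneracy.  Start
codons are counted as ordinary codons; terminal stops (complete or
truncated) are trimmed before counting.  A truncated stop ("T" or "TA" at
a length ≢ 0 mod 3) is only accepted as such when the downstream feature
in transcript order begins within 5 bp — the polyadenylation-completion
rationale; otherwise the gene is classified "incomplete/unknown" with a
warning.  In-frame internal stops trigger a pseudogene warning.

## Ka/Ks (Nei–Gojobori 1986)

Site counting: each codon contributes s + n = 3 sites; mutations to stop
codons are treated as nonsynonymous rather than excluded, the simplest
self-consistent convention (the proportional-exclusion alternative is
documented here as a deviation point).  Difference counting: codon pairs
differing at k ≥ 2 positions are averaged over all k! mutational pathways
with equal weight; pathways through a stop codon are discarded and the
remainder re-weighted equally (if every pathway is blocked — which cannot
occur between sense codons under table 5 but is handled defensively —
all pathways are used).  Codons containing gaps, N or stops are deleted
pairwise.  pS = Sd/S and pN = Nd/N receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is saturated and reported missing, as is
omega when Ks = 0.  Both the site and pairwise-difference tables are
precomputed per genetic code, making the estimator O(codons) per pair.

The per-family aggregation design is configurable because published
figures rarely state it: `within-family` (default; mean over all
within-family pairs), `vs-outgroup` (members against outgroup taxa) and
`consensus` (family majority-consensus sequences compared between
families).  Families with fewer than two members are excluded with a
warning; undefined pairs are excluded from means and counted.

## Substitution saturation

Transition/transversion proportions per taxon pair are plotted against a
Tamura–Nei (1993) closed-form distance.  TN93 replaces the GTR model a
full implementation would optimize numerically — a deliberate choice: the
diagnostic is the *shape* of the curves (transversions overtaking
transitions), not absolute x-values.  Sites with gaps or N are excluded
pairwise, and pairs with fewer than 10 comparable sites are dropped with
a warning.

Iss is the mean per-site Shannon entropy divided by the entropy expected
at full saturation.  The full-saturation expectation is computed
*exactly* for the alignment's n sequences as the expected plug-in entropy
of an n-draw multinomial sample from the alignment's base frequencies
(enumeration over all compositions of n into four counts).  This finite-n
correction is what makes an alignment of independently random sequences
score Iss ≈ 1 at any n; the naive population-entropy denominator would
bias Iss below 1 by the Miller–Madow term.  Simulation-calibrated
critical values (the significance verdict of Xia's test) are out of
scope; Iss is reported descriptively.

## Supermatrix preparation

The conserved-block filter follows Gblocks semantics: columns are
classified by the fraction of sequences sharing the majority residue
(strictly greater than 0.5 default / 0.85 for "highly conserved");
gap-policy-violating columns ("none" default: any gap) are removed
outright; maximal nonconserved runs longer than 8 are removed; surviving
blocks are trimmed until they start and end on highly conserved columns;
blocks shorter than 10 are dropped.  Filtering never edits or reorders
residues — the kept-column map is strictly increasing and supports
coordinate lift-over.  All thresholds are configurable; the defaults
mirror the filter's customary settings since published analyses rarely
print them.

Concatenation gap-fills missing taxa per gene and emits partitions per
gene and per (gene × codon position), the layout model-selection tools
expect.  NEXUS export writes one CHARSET per partition (codon partitions
as `start-end\3`).  Neighbor joining uses pairwise-deletion K2P or TN93
distances, breaks Q-criterion ties on the lowest index pair, and clamps
negative branch lengths to zero moving the deficit to the sibling edge,
so output is deterministic.  A codon-unit Needleman–Wunsch pairwise
aligner (gap penalty −4 per codon, substitution score = matching bases)
is provided for unaligned same-gene CDS pairs; multiple alignment is out
of scope and pre-aligned input is expected otherwise.

## The synthetic-data generator

The generator emulates the architecture of moth mitogenomes, not any one
species: 37 genes + control region in the canonical order with the
derived trnM-trnI-trnQ block (ancestral layout selectable), ~15.2 kb
total, target A+T default 80% (realized within ±0.5 by adjusting
non-coding positions), 9 configured overlaps totalling 48 bp — within the
published 7–13 / 27–72 bp ranges — including ATP8/ATP6 (7 bp, fixed:
its size is geometrically coupled to the two genes' stop/start codons),
trnC/trnW and the 25 bp trnL1/rrnL overlap, and per-gene start/stop plans
(CGA-starting COX1, TTG-starting ND1, truncated stops on COX1, COX2, ND4,
ND5).  PCGs are sampled codon-by-codon from sense codons with
AT-biased weights, a ×6 weight on TTA (yielding UUA RSCU ≈ 5 and the
UUA/AUU/UUU/AUA/AAU-dominated family spectrum) and a ×2 T-enrichment at
third positions (yielding the negative 3rd-position AT-skew of real
data).  Overlaps into a downstream PCG pre-fix the downstream start codon
inside the upstream gene and sample the remaining constrained codons
consistently, with whole-genome retry on the rare infeasible draw.

Known mismatches with real data, hence limits on what passing tests
show: first-codon-position skew is more negative than the near-zero
published values (positions 1 and 2 share one weight set); tRNAs/rRNAs
are random sequence without secondary structure; the control region has
no repeat structure; between-genome variation comes only from seeds, not
phylogeny.

Sequence evolution uses an HKY-like proposal kernel (kappa default 2,
base frequencies default A 0.40, C 0.12, G 0.08, T 0.40) with
proposal-rejection selection: proposals creating stops are rejected,
nonsynonymous proposals are accepted with probability omega, synonymous
always.  Branch lengths are expected *proposed* substitutions per site
before selective rejection, so synonymous divergence tracks branch length
while nonsynonymous divergence is thinned by omega.  This is exact enough
for rank-recovery designs and auditable, which is why it was chosen over
a full codon rate matrix.  Because NG86 assumes equal mutation rates, the
omega ≈ Ka/Ks correspondence is unbiased under the uniform-frequency
kernel and mildly inflated under AT-rich frequencies; rank order is
unaffected.  tRNA, rRNA and CR evolve under the neutral nucleotide kernel
only.

## Problem sizes in the test and acceptance runs

Desk-scale conditions were chosen once as the study design: the default
template (13 PCGs, ~11.2 kb coding), 6 families × 4 taxa with one family
at doubled branch lengths, 20 replicate simulations for rate-pattern
recovery, 100 randomized templates for the junction identity, 500 random
codon pairs for the NG86 oracle comparison (tolerance 1e-12), a 16 × 10
kb uniform-random alignment for the Iss saturation limit (±0.02 of 1), a
5-step × 10-replicate divergence ladder for Iss monotonicity, and ten
6-taxon simulations (3 kb, internal edges ≥ 0.02 substitutions/site) for
NJ topology recovery.

## Determinism

Every stochastic component takes an explicit seed (numpy `default_rng`
with derived substreams); the pipeline writes the seed into its manifest
and re-running a configuration is byte-identical, which the test suite
asserts on artifact hashes.
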