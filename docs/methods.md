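# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, and what its synthetic data can and cannot establish.

## Coordinates, names, strands

All public interfaces use 1-based inclusive coordinates on the circular
genome; a feature may wrap the origin (`end < start`), with length taken
modulo the genome length.  Annotation labels are normalised through a
synonym table ("ATPase 8" → ATP8, "D-loop" → CR, "COX1" → COI, ...); the
two-copy tRNAs keep an anticodon suffix (tRNA-Leu(UAA)/(UAG),
tRNA-Ser(UGA)/(GCU)).  Strand symbols +/− map to H/L.  Unmappable names
are kept verbatim with a warning, never dropped.

## Composition and partitions

Base counts are exact; ambiguity codes are excluded from numerators and
denominators, and a zero-denominator skew is reported as undefined rather
than zero.  Gene partitions are oriented to the coding strand (L-strand
genes reverse-complemented) so that, e.g., ND6 shows its own negative AT
skew rather than the mirror image of the genome-wide skew; the
whole-genome partition is the H strand as deposited and includes the
control region (flagged in the output metadata, since conventions differ).
Codon-position partitions use complete codons only, in frame from the
annotated start; overlapping nucleotides are counted once in the
whole-genome partition but independently in each gene's partition.

## Codon usage

Translation table 2 (vertebrate mitochondrial) throughout: ATA = Met,
TGA = Trp, AGA/AGG = stop.  Leu and Ser are treated as two synonymous
families each, matching how mitogenome RSCU is reported.  Start codons are
read from sequence when available, else from annotation.  Truncated stops
(T--, TA-) are assigned from the reading-frame remainder and contribute
nothing to usage counts; AGA/AGG stops are recognised but reported as
their own class because they are atypical in fish.  Codon-usage tables are
produced both per genome and pooled, since either convention appears in
the literature.

## Gene order and rearrangement

Circular orders are compared through strand-aware adjacency sets, which
are rotation-invariant, so the display anchor (tRNA-Phe) cannot create
artificial breakpoints; a brute-force minimisation over rotations is kept
as a test oracle.  The displaced-gene search tries removal sets in
increasing size (exhaustive to size 4, greedy beyond) and verifies cyclic
equality of the reduced orders.  An adjacent transposition is inherently
ambiguous — removing either neighbour reconciles the orders — so ties are
broken by a fixed convention: walking from a shared start gene, the gene
occupying the first disagreeing slot of the query order is named as
displaced.  For the parrotfish-vs-canonical comparison this names
tRNA-Met, the way the rearrangement is conventionally described.

Overlaps and spacers satisfy the circular identity
Σ lengths − Σ overlaps + Σ spacers = genome length on every genome;
features fully nested in another are reported as containments and
excluded from the adjacency walk.

## Pseudogene scan

Spacers ≥ 30 bp are aligned (Needleman–Wunsch, match +1, mismatch −1,
gap −1) against every tRNA of the same genome in both orientations, and
identity is matches over aligned columns.  Because global-alignment
identity between unrelated short sequences sits near 0.5 — and taking the
best of 22 tRNAs × 2 orientations pushes the null above it — a ψ label
requires both identity ≥ 0.5 and exceeding a seeded shuffle null that
mirrors the same best-of-all selection (default: the maximum over 30
shuffled copies).  The threshold and null settings are parameters.

## Substitution saturation

Per-site entropy is Shannon entropy (bits) over observed A/C/G/T; columns
with > 50% gaps/ambiguity are dropped.  Iss is mean site entropy divided
by the entropy expected under full saturation, where the expectation is
over multinomial draws of n_taxa bases from the alignment's global base
frequencies — enumerated exactly for n_taxa ≤ 12, otherwise seeded Monte
Carlo with 100 000 draws.  The verdict comes from a two-sided one-sample
t-test of the per-site entropy ratios against Iss.c: saturated when
Iss ≥ Iss.c with p < α (default 0.05), unsaturated when significantly
below, inconclusive otherwise (including degenerate variance).  For more
than 32 taxa, Iss is averaged over 30 seeded 32-taxon subsamples and
compared with the 32-taxon critical value; the seed is recorded in the
result.

The packaged Iss.c table is this package's own simulation calibration
(`scripts/calibrate_iss_critical.py`): Jukes–Cantor evolution on symmetric
(balanced) and asymmetric (pectinate) trees of 4/8/16/32 taxa at lengths
100–6400, 40 replicates per depth over an 18-point depth sweep;
neighbour-joining reconstruction; Iss.c is the mean Iss at the depth where
the fraction of true internal bipartitions recovered falls through 0.95,
then made monotone in length by pool-adjacent-violators smoothing.
Queries interpolate linearly on log-length (extrapolating beyond the
grid, which preserves monotonicity) and on log2 of the taxon count between
table rows.  The calibration's defining choices — NJ as the
reconstruction method, the 0.95 recovery threshold, JC as the generating
process — are conventions; critical values from other implementations of
the same idea will differ in detail, so verdicts near the boundary should
be read with that in mind.

## dN/dS and distances

Nei–Gojobori site counts give each codon position the fraction of its
single-base changes that are synonymous, with changes to stop codons
excluded from the denominator (the position still counts as one site);
N + S = 3 per codon.  Observed differences for multi-hit codon pairs are
averaged over all minimal mutational pathways that avoid stops; pairs with
no stop-free pathway, codons containing ambiguity, and stop codons are
dropped pairwise.  Proportions are Jukes–Cantor corrected and undefined at
p ≥ 0.75 (saturated).  Per-gene ω is the ratio of the mean pairwise dN to
the mean pairwise dS — not the mean of per-pair ratios, which are unstable
for short genes such as ATP8 — with excluded pairs counted in the output.
Whole-sequence distances are the p-distance and K2P with pairwise
deletion; log-domain violations yield NaN entries rather than errors.

## CSB scanning

Each consensus slides along the control region; the score is the fraction
of consensus positions matched, IUPAC-aware, with best-scoring placement
and leftmost tie-breaking.  Overlapping placements are resolved in favour
of the higher-scoring block; the displaced block takes its best
non-overlapping position if still above the threshold (default 0.8).
The packaged consensus set is synthetic: plain-FASTA stand-ins whose
compositions follow the teleost pattern (CSB-D T-rich, CSB-I AT-rich,
CSB-II C-rich), because authoritative consensus strings vary by lineage.
Users with lineage-specific consensi should supply their own FASTA; block
composition tables are therefore directional evidence, not reference
values.

## The synthetic-data generator

`make_genome` builds an annotated circular genome from a published
parrotfish feature-table geometry (gene lengths, spacers, overlaps,
truncated stops), with either the parrotfish gene order (tRNA-Met between
tRNA-Ile and tRNA-Gln, plus a degenerate tRNA-Met copy at 0.8 identity in
the 68-bp tRNA-Gln→ND2 spacer) or the canonical vertebrate order.
Protein-coding genes are drawn codon-wise from a 60-sense-codon joint
distribution solved by iterative proportional fitting so that the
position-averaged base marginals equal the composition target exactly
while third positions carry an AT-biased wobble tilt (weights
A:1.7, T:1.2, C:0.9, G:0.45, chosen so A leads — reproducing the CGA
preference within arginine); positions 1–2 compensate, and stop-codon
exclusion is folded into the fit.  The control region gets its own AT
target (default 0.63) with the background composition solved to keep the
genome-wide target exact.  Planted overlap motifs are frame-consistent
with both partners (the ATP8/ATP6 16-mer carries ATP8's TAG and ATP6's
CTG; ND4L/ND4 share ATGCTAA; the ND5/ND6 tetramer holds both stops across
strands).  Everything planted is echoed in a truth record for assertion.

`evolve_sequences` is a K2P simulator (closed-form branch transition
probabilities, optional gamma rate multipliers drawn once per site) on
star or balanced trees; `evolve_codons` exponentiates a 60-state codon
rate matrix in which nonsynonymous changes carry relative rate ω, so stop
codons can never appear.  `make_genome_family` composes them into a study
set: neutral divergence outside the control region, codon-model divergence
with a configurable ω on the PCGs, fast divergence in the CR with the
planted CSBs held slow (conserved blocks inside a hypervariable region, as
in real control regions).

What the generator does **not** emulate: indels (alignments are always
positional), secondary-structure constraints on tRNAs/rRNAs (tRNA bodies
are composition-matched random sequence), compositional heterogeneity
along branches, and — because K2P has uniform stationary frequencies —
long-branch descendants drift toward 50% AT, so composition targets are
statements about generated genomes, not about deeply diverged families.
Passing tests therefore demonstrate correctness of the statistics and
recoverability of planted structure, not robustness to alignment error or
non-stationary evolution in real data.

## Default parameters and problem sizes

| Parameter | Default | Why |
|---|---|---|
| genetic code | 2 | vertebrate mitochondria |
| AT content / AT skew / GC skew | 0.55 / +0.05 / −0.25 | centre of the range reported for fish mitogenomes |
| CR AT content | 0.63 | control regions are the AT-richest partition |
| ψ-spacer identity | 0.8 | degenerate but recognisable gene copy |
| CSB min score | 0.8 | two mismatches allowed on a ~20-mer |
| saturation α / topology | 0.05 / symmetric | conventional test level; topology exposed as a flag |
| ω aggregation | ratio of means | stable for short genes |
| family divergence (genes / CR) | 0.02 / 10× | shallow radiation with hypervariable CR |

Test and acceptance runs use deliberately desk-scale sizes — 16–17 kb
genomes, 6–12 taxa, 500-codon alignments, 20 replicates for recovery
medians, 5000-site saturation constructions — chosen so the full suite
completes in about a minute while keeping sampling error well inside the
asserted tolerances (e.g. binomial sd ≈ 0.004 for AT content at 16 kb).
Multiple-testing correction is deliberately not applied across the
per-partition saturation tests; the summary notes this.
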