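# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, and what the synthetic-data generators do and do not
emulate.

## Coordinates and the gene table

All coordinates are 1-based inclusive on the heavy (H) strand, matching how
mitogenome feature tables are printed; 0-based half-open indices appear only
at internal slicing boundaries. Origin-spanning features are rejected in
this version — none occur in the packaged *O. pama* table, whose control
region ends exactly at the genome's last base. The feature table is a small
TSV dialect (`#genome_length` pragma plus `name/start/end/strand/class`
rows) rather than a GenBank parser; a GenBank importer is a natural
extension point. Gene names normalise to a 39-name canonical vocabulary
(13 PCGs, 22 tRNAs with leucine/serine isotypes `trnL1/trnL2/trnS1/trnS2`,
`rrnS`/`rrnL`, `OL`, `CR`); unmappable names survive verbatim with a
warning so exotic annotations are not silently dropped.

## Geometry

Adjacency (gap/overlap) is evaluated between coordinate-consecutive
features sorted by start, regardless of strand or class: light-strand
tRNAs, O_L and the CR all take part in the same ledger, which is the
convention that reproduces the published 10-gap/9-overlap census of the
*O. pama* table. Nested features are out of scope for the ledger (the
formula `overlap = end_a − start_b + 1` presumes consecutive features also
end in order); overlaps spanning three features would be reported pairwise.
PCG–PCG overlaps are summarised both as pairs and as the set of
participating genes, because the common phrasing "four overlaps between
seven PCGs" counts participants. Stop-codon classification derives the
trailing length from `len mod 3`; `T`/`TA` tails are incomplete stops
completed to `TAA`, complete stops are the mitochondrial set
{TAA, TAG, AGA, AGG}, and anything else is flagged `none` for review
rather than guessed.

## Composition

Skews follow `(A−T)/(A+T)` and `(G−C)/(G+C)` with NaN (never an exception)
on empty denominators. Regional composition is computed on the H-strand
sequence by default — including light-strand genes — because that is the
convention under which whole-genome and per-gene numbers add up; a
`coding_strand` switch re-complements L-strand genes for codon-oriented
work. Percentages are stored at full precision and rounded only in
outputs.

## Codon usage

The genetic code is NCBI translation table 2 (vertebrate mitochondrial),
taken from Biopython: 60 sense codons, stops {TAA, TAG, AGA, AGG},
TGA → Trp, ATA → Met, six-codon leucine and serine families. Stop codons
never enter RSCU. Codons containing ambiguity codes are skipped, not
imputed; per-unit skip counts are reported and a unit whose skip fraction
exceeds 1% is flagged, turning the common practice of excluding
ambiguity-ridden taxa into an explicit, reported threshold.

## Divergence

Site classification uses complete-column deletion (a column counts only if
no sequence has a gap or ambiguity), so conserved% + variable% = 100 on
evaluated sites. K2P uses pairwise deletion, maximising data per pair.
Saturated distances (log argument ≤ 0) are flagged undefined and excluded
from family means — never clamped. Family-level uncertainty is a seeded
bootstrap over alignment columns (default 500 replicates); the standard
error is the standard deviation of replicate means, with the same column
resample shared by all pairs within a replicate. Published "±" values of
this kind rarely state their method; ours is fully specified and seedable.

## Selection (NG86)

Site counting: position *i* of a sense codon contributes
`s_i = (synonymous one-step changes) / (non-stop one-step changes)`
synonymous sites and `1 − s_i` nonsynonymous sites, so S + N = 3 per codon
exactly and mutations to stops are excluded from the denominator.
Difference counting averages over all orderings of the differing positions
with equal weights; pathways through stop codons are excluded and the
weights renormalised. When *every* pathway is blocked — possible under the
mitochondrial code (e.g. TGA ↔ AAA, whose two intermediates AGA and TAA
are both stops) — the exclusion is waived and steps touching a stop count
as nonsynonymous, so the pair still contributes. Proportions are
Jukes–Cantor corrected; the family-level ratio is formed from counts
averaged over pairs (robust to individually undefined pairs), with the
mean of defined pairwise ratios reported alongside. The method is original
NG86; modified-NG variants are out of scope but results carry a method
tag.

## Gene order

Content differences are multiset comparisons (duplicated = extra copies in
the query, lost = missing copies). Breakpoints are counted on the genes
single-copy in both genomes, over circular, strand-aware directed
adjacencies: a strand flip is a real rearrangement, and the last→first
adjacency is included. Multi-copy genes are excluded from breakpoint
counting (their adjacency identity is ill-defined) and appear only as
duplications. "Moved" genes are those whose (predecessor, successor)
context changed — note this marks the flipped gene's *neighbours* when
only an orientation changes, a direct consequence of the neighbour-context
definition.

## Control-region motifs

Hamming-budget scanning of IUPAC consensus strings; every offset is
tested, overlapping hits are all reported. Only the two literal,
sequence-explicit landmarks ship as defaults (GTGGG-box, TAATATA); ETAS
and CSB consensus strings vary by lineage and are figure-level annotations
in the literature, so they are user-configurable inputs rather than
invented built-ins. No positional weight matrices in this version.

## Trees and clustering

Neighbor joining follows the Saitou–Nei Q criterion with deterministic
tie-breaking by the lexicographically smallest leaf label in each cluster,
so label permutations of the input matrix yield the same tree. Negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge. On additive matrices the tree reproduces the input path lengths to
machine precision (checked to 1e-9 in tests, against scikit-bio's NJ as an
independent cross-check). Bootstrap support resamples alignment columns,
rebuilds the K2P matrix and tree per replicate, and reports the percentage
of retained replicates containing each internal bipartition of the
full-data tree; replicates with saturated distances are skipped and
counted. A maximum-likelihood search is deliberately out of scope: NJ on
the same K2P distances is the distance-based stand-in, and topology
concordance — not likelihoods — is the test surface.

RSCU clustering is Euclidean agglomerative clustering via scipy's linkage
(single/complete/average/ward, with Ward in the Ward.D2 sense — stated
explicitly because R's two Ward variants differ). The agglomerative
coefficient is `mean_i (1 − h_first(i)/h_final)`, defined as 0 when the
final height is 0. Merge heights are non-decreasing for all four linkages
on Euclidean inputs.

## Synthetic data

`simulate_genome` emits the canonical 37-gene + OL + CR layout with the
observed junction sizes by default (gaps 1–7 bp, overlaps 1–10 bp), an
AC-biased genome-wide composition matching the published *O. pama* base
frequencies, an AT-rich CR (~64% A+T) carrying the TAATATA flank and a
GTGGG-box, and PCGs that start with ATG, are free of internal stops on
their coding strand, and end with their configured complete or incomplete
stops. Three compensations keep the genome-wide composition within about
one percentage point of target at 16 kb scale: codon-sampling frequencies
are tilted by fixed-point iteration so the post-stop-rejection marginal
hits the target; light-strand PCGs sample from the complemented target
(their bases are written complemented); and the unannotated background
absorbs the CR's A+T excess. Overlapping PCGs constrain each other's
reading frames: start/stop codons are pinned as hard constraints
(conflicting pins raise an infeasibility error) and the free positions of
any violating codon are re-drawn until all PCGs validate simultaneously —
with the default layout this converges in a handful of sweeps.

`evolve_sequences` runs a K2P (K80) substitution process along a guide
tree using the closed-form transition probabilities per branch; codon mode
is event-based with an accept/reject selection filter: stop-creating
events are rejected outright, and to keep the nonsynonymous:synonymous
flux ratio at omega on both sides of 1, nonsynonymous events are accepted
with probability min(1, omega) and synonymous events with
min(1, 1/omega). Branch lengths in codon mode are therefore expected
*proposed* substitutions per site. This filter is deliberately simpler
than a Goldman–Yang rate matrix; it is sufficient for regime-recovery
tests (NG86 recovers purifying/positive calls at omega = 0.1/2 in 20/20
seeded runs at 400 codons). No indels are simulated, keeping alignment
construction out of scope — the pipeline consumes alignments, it does not
build them.

`planted_rscu_matrix` starts from the no-bias baseline (RSCU = 1
everywhere), shifts one preferred codon per family per cluster by the
effect size, renormalises family sums to the degeneracy, and optionally
adds renormalised Gaussian noise. Zero effect and zero noise reproduce the
baseline exactly; excessive effects are clipped and renormalised with a
warning.

## What passing tests do and do not show

The simulators have single-rate sites, no indels, no rate heterogeneity
among lineages, and iid base sampling outside the PCG constraints, so
passing recovery tests demonstrates estimator correctness under the stated
models — not robustness to alignment error, rate variation or
compositional heterogeneity in real data. Published per-locus figures for
the 31-species family survey (conserved percentages, per-locus K2P means,
the Ka/Ks range, clustering coefficients) require the real accession set
and identical alignments; here they are documentation, and the oracle
equivalences, closed forms and seeded recoveries above are the test
surface.

## Problem sizes

Test and acceptance runs use 100 kb pairs for nucleotide-distance
recovery, 400-codon 4-taxon families (20 seeds per omega) for selection
recovery, 8-leaf trees (100 instances) for NJ exactness, and 10–12-species
planted RSCU matrices for clustering — sizes chosen so every stochastic
check has comfortable statistical power while the whole suite stays fast.
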