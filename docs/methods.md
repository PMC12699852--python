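# Methods

This note records the models, conventions and numerical choices behind
`strscape`, and what the synthetic-data tests do and do not establish
about real genomes.

## STR definition and detection

An STR is a maximal perfect tandem run: a primitive unit of 1–9 bp
repeated at least three complete times, spanning at least 10 bp. Both
thresholds apply jointly (`min_copies=3` AND `min_length=10`), so e.g. a
9 bp trinucleotide run fails on length and a 12 bp pentanucleotide run
fails on copies. A maximal run may end in a partial trailing copy; the
`copies` field counts complete units only, while `length` includes the
partial tail. Detection scans each period p = 1..9 for maximal runs of
`seq[i] == seq[i+p]` (vectorized over the sequence), which finds every
maximal periodic interval at that period in O(9n). A run is reported once,
at its primitive period: if the p-length unit is itself periodic the same
interval is found — and kept — at the shorter period instead. By the
Fine–Wilf periodicity theorem a run of ≥ 3 copies cannot be maximal at
two distinct primitive periods, so primitivity of the unit is a complete
de-duplication rule.

Case is folded to upper; any character outside {A, C, G, T} is a hard
terminator — runs never span it, and each maximal ACGT segment is scanned
independently. Coordinates are 0-based half-open everywhere in memory;
GFF3 (1-based inclusive) and VCF (1-based POS) are converted at the I/O
layer only.

Units are canonicalized to motif classes closed under cyclic shift and
reverse complement; the representative is the lexicographic minimum
(A < C < G < T) over all 2·|u| images. Exhaustive enumeration gives 2
mononucleotide, 4 primitive dinucleotide and 10 primitive trinucleotide
classes, which the tests verify.

## The shuffled null and the enrichment score

The null genome preserves the multiset of overlapping dinucleotides — the
composition signal that, through CpG depletion and AT skew, already
explains much repeat-free structure — while destroying tandem order. We
use the Euler-path construction: the sequence is an Eulerian path on the
4-vertex multigraph of dinucleotide edges; a uniformly random
last-exit-edge arborescence into the final vertex is drawn by rejection,
remaining out-edges are permuted, and the path is re-walked. This samples
uniformly among all sequences with the same dinucleotide counts and the
same first/last characters. Genomes are shuffled in 5 Mb chunks, each
independently; dinucleotides spanning chunk junctions are not preserved.
Non-ACGT characters are frozen in place and each flanking ACGT segment is
shuffled separately, so assembly gaps are neither created nor destroyed.
One master seed spawns per-record, per-chunk child generators (record id
hashed with CRC32), so output is independent of processing order.

Enrichment is FE(O, E) = (O − E)/(O + E) on merged STR base pairs, with
FE ≜ 0 at O = E = 0 (a repeat-free genome whose shuffle is also
repeat-free is neither enriched nor depleted). FE is bounded in [−1, 1]
and antisymmetric under swapping O and E. Group comparisons use a
two-sided independent t-test — equal-variance by default, with a Welch
flag, since nothing in the score requires either — plus Hedges' g
(pooled SD, small-sample factor J = 1 − 3/(4(nₐ+n_b) − 9)) and
Benjamini–Hochberg adjustment across tests.

## Densities and two-stage averaging

Density is merged STR bp per kB: overlapping records are unioned first,
so a poly-A run inside a longer AT run is not double-counted.
Compartment densities intersect the STR union with the merged compartment
(gene/exon/CDS features treated as flat intervals; parent–child GFF3
structure is deliberately ignored because the union makes it irrelevant).
Genome size includes non-ACGT characters. Species densities F(S) are
unweighted means over assemblies; rank densities F(R) are unweighted
means over species — duplicating assemblies of one species provably
leaves F(R) unchanged, and a property test asserts it. Species with zero
STRs contribute 0 rather than being dropped. Motif-class prevalence uses
the same two-stage scheme on within-species bp proportions; species with
no STRs of the period are excluded from that period's mean. AT-content
summaries default to the median over records, with the per-species
median available by aggregating upstream.

## Topography

For each gene, offsets −500..+500 are oriented along transcription: on
the plus strand the TSS is the gene start and offset +1 points into the
gene; on the minus strand the TSS is the last base and offsets run
leftward. Windows truncated by sequence edges carry a validity mask; the
relative-enrichment denominator (window mean) is computed over valid
offsets only, so truncation neither inflates nor dilutes the curve. The
profile counts (gene, STR-base) incidences, so overlapping genes
contribute independently. Nucleotide occurrence matrices complement
repeat bases on minus-strand windows before counting, and the 4×1001
probability matrix is the Dirichlet posterior mean
(nᵢ + αᵢ)/Σ(nⱼ + αⱼ) per column with a Laplace default α = 1 — chosen so
an unobserved column is uniform rather than undefined.

Confidence bands resample whole species (inner band) or whole families
(outer band) with replacement, N = 1,000 replicates, and take pointwise
2.5/97.5 percentiles of the replicate mean curves. The percentile
bootstrap is known to undercover slightly at small unit counts (~91%
observed at 40 i.i.d. units); calibration checks therefore run at 100
units, where measured coverage matches the nominal 95%.

## Chromosome bins

Bins are fixed 100 kb windows with a shorter final bin
(N = ⌈C/bin_size⌉); densities use actual bin lengths. The standalone
`assign_bin` exposes the equal-partition formula 1 + ⌊Nx/C⌋. Two
crediting modes exist for repeats spanning bin boundaries: `span` credits
the full repeat length to every bin it touches (the all-intermediate-bins
convention), and `overlap` (default) credits each bin only its
overlapping bases. Only `overlap` conserves total STR bp and makes the
length-weighted mean fold enrichment exactly 1; `span` is retained
because binned-profile conventions differ between tools and the
double-counting variant is sometimes wanted for comparability. Fold
enrichment divides each bin's density by the assembly-wide density.

## Variant overlap

Variants are assumed normalized and left-aligned upstream. Classes are
mutually exclusive: 1 bp ref and alt → substitution; longer alt →
insertion; longer ref → deletion; |Δlength| > 50 bp dropped; same-length
multi-base records are outside the three classes and skipped with a
warning. Overlap uses the POS anchor base as the variant's locus (an
option extends deletions to their ref span). Controls are drawn one per
STR, of identical length, uniformly from the stratum territory — merged
CDS for STRs with ≥ 30% CDS overlap, the CDS complement otherwise —
excluding the STR union; placement is weighted by the free space in each
territory segment so it is uniform over admissible starts. Fold
enrichment is n_obs/(n_ctrl + 1) — the +1 pseudocount on the control
count guards against empty control overlaps — and significance is a
one-tailed (greater) Fisher exact test on
[[n_obs, N − n_obs], [n_ctrl, N − n_ctrl]], BH-adjusted across
species × class. Regressions are OLS with Cook's distance from the
standard leverage/residual formula (via statsmodels) and Spearman rank
correlations; species with zero STR density are excluded.

## Synthetic data: what it emulates, and what it does not

Genomes are i.i.d. nucleotides at a target GC (or first-order Markov
chains for controlled dinucleotide structure). Planted arrays are flanked
by a buffer base differing from both the unit's first and last character,
so the truth coordinates are exactly the detector's maximal run and
recall can be asserted at exact coordinates; chance background repeats
are expected and handled by oracle-equality rather than zero-count
assertions. Variant anchors are drawn by weighted sampling without
replacement with relative in-STR weight ρ; the closed-form overlap
proportion ρf/(ρf + 1 − f) holds when draws barely deplete the in-STR
mass, so simulations keep n well below the in-STR position count
(genomes ≥ 1 Mb for n ≤ 5,000). Taxonomies allow arbitrary imbalance in
species-per-rank and assemblies-per-species.

Passing these tests shows the machinery is correct on sequences whose
only structure is what we planted. Real genomes add transposable
elements, satellite higher-order repeats, CpG islands, heterogeneous
mutation processes and phylogenetic correlation, none of which the
generators model — so the tests validate the arithmetic and the
conventions, not biological conclusions drawn from any particular
dataset.

## Problem sizes

Default test and acceptance runs use desk-scale conditions chosen once:
oracle comparisons on 200 sequences of 1–2 kb; shuffle conservation on
100 × 10 kb chunks; planted-truth recovery on a 1 Mb genome with 100
arrays; enrichment end-to-end on 20 × 60 kb STR-rich genomes plus a
50-genome shuffle-vs-shuffle null and a 1,000-repetition t-test
calibration; bootstrap calibration at 100 species × 1,000 replicates;
variant generative recovery at n = 1,000 variants × 20 seeds per ρ; and
regression recovery at 87 species × 200 runs.
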