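# Methods

## Scope and data model

The package analyses a single circular chloroplast genome and data derived
from it. Coordinates are 1-based and inclusive everywhere, matching the
arithmetic of the bundled primer table (amplicon length
= reverse start − forward start + 1). Sequences are restricted to
A/C/G/T/N; aligned inputs with gap columns are passed as plain
(name, sequence) pairs rather than validated records. The genetic code is
NCBI translation table 11 (plastid/bacterial) throughout.

The three packaged TSV tables (primer panel, mutation sites, genotype
matrix) are treated as data, transcribed verbatim up to glyph
normalization: markdown emphasis and intraword spaces are stripped from
gene labels, the typographic '∼' becomes '~', and en/em dashes in genotype
cells normalize to the ASCII reference symbol '-'. Five panel loci
(rpoC1_23167, IGS_23593, IGS_50999, ycf1_98314, ycf1_101148) have no
corresponding mutation-table row; the tables are kept as printed and the
discrepancy is surfaced by the loaders' documentation, not reconciled.

## Composition and codon usage

GC content excludes N from numerator and denominator. AT skew is
(A−T)/(A+T) and is undefined on AT-free input. Windowed skew defaults to
window 500 bp, step 200 bp, circular (windows wrap the origin); both
parameters are exposed because no canonical choice exists.

RSCU is count / family-mean-count within each synonymous family. Stop
codons and the single-codon families (ATG, TGG) are excluded by default —
they carry no synonymous choice — with flags to include them. A family
with zero total usage maps to RSCU 0 for all members and is flagged on the
profile. Cross-species matrices hold raw RSCU values (no row scaling) and
are clustered by average-linkage UPGMA on Euclidean row distances.

UPGMA is delegated to `scipy.cluster.hierarchy.linkage(method="average")`.
Labels are sorted lexicographically before agglomeration so ties resolve
deterministically, and heights are reported as merge distance / 2 (the
ultrametric convention: leaf-to-node path length equals half the
cophenetic distance). Input must be symmetric within 1e-9 with a zero
diagonal. Both species and codon axes can be clustered; each call returns
its own dendrogram.

## Ka/Ks (NG86)

Sites: for each codon position, the synonymous fraction is computed over
the non-stop single-base changes only, and every position carries weight
1, so each codon contributes exactly 3 sites (S + N = 3L). This follows
the original worked example of the counting method (Leu TTA → s = 2/3,
n = 7/3). Differences: averaged over all orderings of mismatched
positions, discarding pathways through stop codons; when every pathway is
blocked, all pathways are used as a fallback (never triggered for sense
codon pairs at distance ≤ 3 — verified exhaustively in the tests, which
compare both counts against an independent enumeration oracle for all
61 × 61 codon pairs).

Proportions pS = Sd/S̄ and pN = Nd/N̄ use site counts averaged over the two
sequences and are corrected with JC69, d = −(3/4)·ln(1 − 4p/3). Each rate
is corrected independently: a proportion at or beyond the 3/4 ceiling
leaves only its own rate (and hence the ratio) undefined, and the result
carries a `saturated` flag rather than a silent NaN. The ratio is also
undefined when Ks = 0. Codon columns containing a gap, an ambiguous base
or a stop codon are pairwise-deleted before counting.

Classification uses a neutral band of ±δ around 1 (default δ = 0.1,
configurable); an undefined ratio maps to "undetermined". The choice of a
counting estimator (rather than the LWL-family estimator of the seqinr R
package, or ML codon models) is deliberate: its two primitives are exactly
checkable by brute-force enumeration, which anchors the whole module to an
independent oracle. No numeric claim is made about any published Ka/Ks
bar heights, whose inputs (external genome sets and alignments) are not
distributed here.

## SNP discovery

Rates are pooled-read alternate fractions, not individual fractions — the
printed rates (e.g. 0.01) are not multiples of 1/33, so pooled-read
semantics is the only consistent reading. Calling emits, per site with
coverage ≥ `min_coverage` (default 10), every non-reference base with
fraction ≥ `min_rate` (default 0.01), rounded to two decimals; multiple
passing alternates collapse into one dual-allele record ordered by
descending rate. Annotation assigns genic hits (tRNA genes included) the
gene name and everything else the ordered spacer "left~right"; linear
genomes use START/END sentinels at the boundaries while circular genomes
wrap. Summaries bin each SNP once by its maximum alternate rate; indels
are excluded from per-gene counts and rate bins and keep their printed
rates verbatim (the packaged indels all print 0). The packaged-table
recount (71 SNPs / 4 indels, 17 in ycf1, max 48% in ycf2) disagrees with
three derived statements in the source narrative (counts below 15%,
in the 30–50% band, and genic totals); the package reports the recount.

## Genotyping

Profile comparison is strict symbol equality across all loci: '-' is an
informative value and 'N' is a literal distinct symbol. This is the only
policy that jointly reproduces all three headline counts from the packaged
matrix (32 variant-bearing, 23 distinguished, four duplicate groups);
treating 'N' as a wildcard merges near-reference profiles and breaks all
three. 'N' also counts as a non-reference call when tallying
variant-bearing individuals. The distinguished count includes the single
reference-matching individual (its all-'-' profile is unique), consistent
with 33 − 10 grouped = 23. The panel's exact discrimination fraction is
23/33 ≈ 69.7%; the package reports the exact fraction. Missing cells are
invalid in this version — the packaged matrix has none.

Greedy panel selection adds, at each step, the locus with the largest gain
in distinguished individuals (leftmost column on ties) and stops at the
cap or at zero gain. Greedy selection is not guaranteed optimal; the tests
compare it against exhaustive search on small matrices and check
monotonicity on random sub-panels. GC percentages use half-up decimal
rounding to two places, matching the printed primer values (40.91%).

## Trees

Topologies are unrooted; a degree-2 root is suppressed on parsing. RF is
the size of the symmetric difference of non-trivial bipartition sets,
normalized by 2(n−3) — the maximum over unrooted binary trees, also
applied (conservatively) to multifurcating input, and stated in the result
object. Neighbour joining is the Saitou–Nei algorithm with a
deterministic lowest-index tie-break; it rejects negative off-diagonal
distances and exactly inverts additive matrices. p-distances use pairwise
deletion of sites with N or a gap. The congruence experiment builds NJ
trees from a genome alignment and a gene alignment of the same taxa and
reports their mutual normalized RF. NJ on p-distances deliberately stands
in for maximum-likelihood inference at desk scale; the published
real-data congruence value (normalized RF 0.15 between plastome and ycf1
trees) depends on external genome sets and ML runs and is therefore not a
quantity this package recomputes.

## Synthetic data

Defaults mirror the study conditions: genome 121,530 bp at GC 0.385 with
71 genes (lengths 300–1500 bp, multiples of 3), 33 individuals, mean
pooled depth 200×, ambiguous-call rate 0.006 (the rate observed in the
packaged genotype matrix: 3 of 495 cells), divergence 0.05
substitutions/site (typical congeneric chloroplast divergence), and
exponential branch lengths with mean 0.05 for tree simulation.

The plastome generator embeds ATG + sense-codon interiors + TAA genes in
i.i.d. background; because excluding the AT-rich stop codons biases GC
upward, the per-base GC used for codon sampling is solved by bisection so
the sense-codon mixture hits the requested GC. The population generator
draws individuals per site independently by default; a linked mode
(single uniform variate per individual) produces the nested haplotype
blocks of a non-recombining chromosome. Pooled counts are
Binomial(Poisson(depth), realized individual fraction), so recovery tests
use the two-stage standard error sqrt(f(1−f)(1/n + 1/depth)).

CDS divergence is a proposal/acceptance walk: uniform single-base codon
proposals, synonymous acceptance min(1, 1/ω), nonsynonymous acceptance
min(1, ω) (ω = 0 gives a strictly synonymous walk), stop-creating
proposals always rejected, stopping after divergence × length accepted
substitutions. Tree alignments evolve sites under JC69 down a random
binary topology; the "gene" is the contiguous leading slice of the
alignment, so gene_fraction = 1 reproduces the genome alignment exactly.

What the simulations do not model: read errors and quality scores, indel
evolution, transition/transversion bias (JC69 only; hooks for K2P-style
extensions are left), rate heterogeneity across sites, and population
structure. Passing tests therefore demonstrate estimator correctness under
the stated models, not robustness to real-data artefacts such as
alignment error or sequencing bias.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise the
asymptotics that matter: 5,000-codon pairs for Ka/Ks recovery (binomial
error on the ratio ≈ 5% there), 12 taxa × 20,000 sites for congruence,
40-kb genomes with 15 genes for the calling round trip, and exhaustive
enumeration wherever the space is finite (61 codons, tree pairs with
n ≤ 8). All generators take explicit integer seeds and are bit-reproducible
for a fixed package version.
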