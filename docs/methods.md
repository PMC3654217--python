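# Methods

## The problem

Shotgun metagenomes of high-temperature chemotrophic springs are dominated
by a few archaeal populations with no close reference genomes. The analyses
here separate those populations and characterize their functional potential
using only signals intrinsic to the sequence: per-read G+C content and
homology-based LCA placement; nucleotide word frequencies of assembled
contigs; CRISPR repeat–spacer loci linking hosts to co-occurring viruses;
protein-family abundance profiles; and curated marker-gene inventories.
Every stage is exercised against synthetic communities with planted ground
truth, so correctness claims are recovery statements, not visual judgments.

## Synthetic community model

**Population genomes.** Each genome is an order-k Markov chain (k = 0–3,
default 2). Every context's next-base distribution starts from the
G+C-tilted composition (P(A)=P(T)=(1−gc)/2, P(G)=P(C)=gc/2), is perturbed
multiplicatively by exp(0.35·z) with z drawn once from the population's
`signature_seed`, then renormalized *within* the {G,C} and {A,T} pairs so
each context emits G or C with probability exactly `gc_target`. Realized
G+C is therefore Binomial(L, gc)/L: at 100 kb its standard deviation is
~0.0016, so the ±0.015 control band holds with enormous margin, while the
within-pair and A/T-vs-G/C context structure gives each population a
separable tetranucleotide signature even at identical G+C. The perturbation
scale 0.35 was chosen once as a realistic degree of codon/word bias between
unrelated genomes; it is not adjusted per analysis.

**CRISPR planting.** An array is `n_units` identical direct-repeat copies
separated by distinct random spacers (pairwise < 60% identical by
construction). A link (viral id, m) copies one spacer into the viral
element with exactly m substitutions at distinct positions, never
substituting a base to itself, so the planted Hamming distance is exact and
verifiable by direct window scanning. Protospacer placements never overlap,
including across host genomes sharing one viral pool. Decoy spacers are
random sequence; at spacer lengths ≥ 20 the probability of a chance ≤3-
mismatch window anywhere in the viral pool is < 1e-10 and is treated as
zero.

**Reads and contigs.** Reads have truncated-normal lengths (clipped to
200–2000 bp, emulating Sanger-scale ~800 bp shotgun reads), uniform
positions and strands. Contigs tile the genome with lengths from a
(min, max, shape) law; a segment that would split a planted array is
extended to cover it, and a trailing remainder shorter than the minimum is
merged into the previous contig. Real assemblies are not tilings — they
have coverage gaps, chimeras and errors — so passing recovery tests shows
the analyses are correct on clean population structure, not that they are
robust to assembly artifacts (out of scope here).

**Annotations.** Gene density is 1 per kbp; each gene's category is drawn
from the site's category profile and its family uniformly within the
category. This reproduces the multinomial sampling structure of
family-assignment pipelines without modelling HMM search itself.

**Determinism.** All randomness flows from one root seed through labelled
`SeedSequence` spawn keys (`derive_rng(seed, "reads", site, population)`),
so each stage is independently reproducible and full reruns are
byte-identical.

**The packaged study community** (`simulate.default_community`) has four
1-Mb populations at G+C 38%, 48%, 53.5% and 62.5% — the population modes
resolved in the motivating hot-spring systems — two sites with contrasting
mixtures and category profiles (2,000 reads each, 5–20 kb contigs), three
viral elements, and four CRISPR arrays planting 20 spacer–virus links at
≤1 mismatch plus 8 at 2–3 mismatches.

## Analysis choices

**G+C.** Numerator counts G, C and S; denominator counts A, C, G, T, S, W.
Other ambiguity codes and N are excluded: S and W are the only codes that
are unambiguous with respect to G+C.

**LCA assignment.** Defaults min_score = 35 bits, top_percent = 10,
min_support = 5 follow common MEGAN practice; all are configurable, and no
fidelity claim is attached to them. Reads at under-supported nodes are
promoted to the nearest sufficiently supported ancestor rather than
discarded, preserving the total-read series of the G+C histograms.

**Composition vectors.** k = 4 with canonical-strand pooling (136
dimensions): pooling a word with its reverse complement makes the vector
invariant to contig orientation, which is arbitrary in an assembly. Windows
containing ambiguity codes are skipped. Minimum contig length defaults to
5,000 bp; shorter contigs have too noisy a word spectrum.

**PCA.** sklearn's exact SVD solver behind one shared wrapper; component
signs are fixed by making each component's largest-magnitude loading
positive, so results are bit-reproducible. Zero-variance input yields
zero scores and fractions rather than an error.

**Binning.** K-means (fixed seed, 10 restarts) on the first D principal
components (smallest D with ≥80% cumulative variance, min 2) plus contig
G+C, every feature standardized to unit variance so compositional and G+C
signal weigh in together — without this, populations at nearly identical
G+C (e.g. 47.8% vs 48.2%) are not separable. Cluster count is chosen by
mean silhouette over 2–12. This automated pipeline stands in for the manual
curation such studies perform; screening then drops contigs whose G+C
deviates > 0.05 from the bin's length-weighted mean or whose taxon label
conflicts with the bin majority. Dropped contigs are flagged, never
reassigned.

**CRISPR detector.** Seed length 13 (long enough that chance repeats at
array-compatible spacings are ~absent in Mb-scale sequence, short enough to
seed every 21-bp repeat); unit boundaries extend while columns are
unanimous across units. Acceptance: ≥3 units, repeat 21–48 bp, units within
2 mismatches of consensus, spacers 0.6–2.5× the repeat length and
consecutive spacers < 60% identical. These are CRISPRFinder-style
conventions, all exposed as `CrisprParams`. Unanimous extension can
overshoot the true repeat boundary only when every unit's flanking base
agrees by chance (probability (1/4)^(n−1) per column), which is why
recovery is quoted on arrays with ≥4 units.

**Spacer matching** is an exact full-length gapless Hamming scan on both
strands — a deterministic, strictly-defined replacement for heuristic
word-search alignment. It admits a brute-force per-position oracle, and the
test suite demands exact set equality against it. Ambiguity codes in the
scaffold mismatch everything; matches overlapping the spacer's own source
array are masked by default. "Instances" in the repeat census are total
repeat units per exact strand-canonicalized consensus per sample; fuzzy
repeat grouping is deliberately not implemented.

**Viral grouping.** Pairwise identity is estimated from exact shared
16-mers chained on the dominant diagonal, with matches counted over the
anchored span; single-linkage at ≥0.92 identity. This is accurate for the
near-duplicate scaffolds the grouping is meant to find and returns 0 (no
shared word) for unrelated sequence; it is not a general aligner.

**Family profiling.** Relative abundance uses total annotated genes at the
site as the denominator (a total-family-hits denominator is available via
`denominator="family_hits"`). Row standardization uses the population
(ddof = 0) standard deviation, so standardized rows have unit variance
exactly and the operation is idempotent. Two clustering presets are shipped
because two recipes circulate for this analysis — Pearson distance with
average linkage, and Euclidean distance with complete linkage — rather than
privileging one; both use deterministic smallest-index tie-breaking and are
verified against an independent agglomeration. Two-way clustering is the
product of clustering each axis.

**White's t test** is implemented as its permutation variant: pooled
two-sample t statistic, null by label permutation (all distinct splits
enumerated when ≤10,000, otherwise sampled), two-sided
p = (b+1)/(B+1). The original's small-sample pooling heuristics are not
replicated. With 6 vs 6 sites the 924 enumerable splits give a minimum
attainable p of 3/925 ≈ 0.0032 and an exact rejection rate of 45/924 ≈
0.0487 at α = 0.05 under the null. ANOVA computes F from between/within
sums of squares directly (verified against scipy's f_oneway), with F = 0,
p = 1 for rows with no between-group variation. Multiple testing uses
Benjamini–Hochberg throughout (the choice is this package's; nothing is
claimed about the original workflow).

**Marker inventory.** The E-value screen is strictly `E < 1e-10`.
"Individual phylogenetic assessment" of candidates is operationalized as
rule i, a reciprocal-best-hit family check; per-gene trees are out of
scope. Rule ii passes vacuously when no gene-neighborhood table is
supplied. Query coverage below 0.7 demotes a surviving hit to `partial`;
the threshold is a default, not a fidelity claim.

## Problem sizes

The packaged community uses 1-Mb genomes, 2,000 reads/site and ~80 contigs
per population per site; detector performance is measured on 40 planted
arrays and 1 Mb of array-free sequence; matcher oracle equivalence on 500
random instances; permutation-test calibration on 1,000 null rows at 6 vs 6
sites with enumerated splits. These sizes make every recovery statistic
statistically meaningful (binomial error well inside each quoted band)
while the whole suite runs in seconds to minutes.

## Known limitations

- Genomes are stationary Markov chains: no repeats beyond planted arrays,
  no mobile elements, no strand-specific skew. Binning on real assemblies
  is harder than on this model.
- Reads are error-free; the LCA stage consumes hit tables and is agnostic
  to the aligner, but no aligner noise model is provided.
- The CRISPR detector assumes near-identical repeat copies (≤2 mismatches
  to consensus) and cannot find heavily degenerate arrays.
- The viral grouping identity estimate is ungapped; indel-rich divergence
  is underestimated.
- Coverage-based binning and reference-genome read recruitment are
  deliberately out of scope.
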