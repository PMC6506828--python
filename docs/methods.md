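# Methods

## Scope and data model

looplink re-implements, as a tested pipeline, the analysis chain that
connects RNA-polymerase-II-mediated chromatin loops, SOX2 and
enhancer-mark occupancy, and expression change after Sox2 deletion in
neural stem cells. Inputs are plain-text: tag-pair TSV (one PET per
row), BED6 peak sets, BED12/TSV gene models, bedGraph bin counts, and
TPM replicate tables. All coordinates are 0-based half-open throughout;
BED shares that convention, so no reader or writer shifts coordinates.
Out of scope by design: read alignment, peak calling, multi-state
chromatin HMMs, and RSEM quantification — the pipeline starts from
their outputs.

## Loop calling

*Linker classes.* Half-linker barcodes AA/BB mark intra-molecular
ligation; AB/BA are chimeric artifacts and discarded. Absent linkers
(single bridge-linker chemistry) are non-chimeric by construction.

*Classification and dedup.* Self-ligation means both tags on one
chromosome within 8,000 bp (inclusive); intra-chromosomal means
distance > 8 kb. Duplicates are PETs whose two ends both lie within
2 bp of a retained PET; a greedy scan in (chrom, pos_a, pos_b) order
keeps the lexicographically smallest member, which makes the result
independent of input order. The rule is deliberately non-transitive: a
duplicate whose offset from its group representative exceeds the
tolerance survives, which affects well under 10% of planted duplicates
in the generator's regime.

*Clustering.* Two intra-chromosomal PETs join one cluster iff their
left ends are within the 1-kb extension AND their right ends are —
single linkage, transitively closed (connected components over that
relation). "Within 1 kb" is measured between tag coordinates, the
stricter of the readings the wording allows. Cluster anchors span
member tags, [min, max+1) per side; singletons are noise.

*Significance.* p = P(X ≥ c) under Hypergeom(T, n_A, n_B) with T the
deduplicated intra-chromosomal PET count and n_A, n_B tag ends (both
PET sides) overlapping each anchor; the formulation is symmetric in the
anchors. Counts use the cluster-derived anchor span without extension.
BH step-up gives q; loops pass at c ≥ min_ipet (3 in-situ, 2 tr1),
q < 0.05, and p < 0.05. The distance-conditional (non-central) variant
of the test is out of scope; the plain hypergeometric is conservative
on distance-uniform backgrounds (it double-counts pairable tags) and
anti-conservative at short range under heavy-tailed ligation noise —
a known limitation.

*Noise.* `shuffle_noise` re-pairs left and right tags uniformly within
each chromosome, drops re-paired pairs inside the self-ligation span,
re-clusters, and reports mean simulated PET-2+ cluster count over the
real count. On input whose tags are already exchangeable (both ends
uniform) the ratio is ~1 by construction; on planted data it is ≪ 1.
The planted-over-10×-background regime used in the tests sits near
0.07–0.11 across generator seeds: the residual simulated clusters come
from re-paired tags that still fall in anchor-tag clumps.

## Annotation

Promoter windows are TSS ± 2,500 bp, endpoint inclusive (implemented as
overlap with [tss−w, tss+w+1)); the histone-mark layer separately uses
a 1,000-bp promoter distance, because both constants genuinely coexist
in the analysis. Anchor priority is P > G > I at ≥ 1 bp overlap per
tier. Overlapping anchors merge into nodes (≥ 1 bp, transitive);
book-ended intervals do not merge. A node's promoter status is decided
by the merged interval's TSS distance, not by its members. Interaction
types follow from the two anchor classes (G and I collapse to nonP).
Interaction-set overlap between samples matches anchor midpoints within
± window after sorting each interaction's anchors.

## Mark layer

Peaks shorter than 2 kb are extended symmetrically around their
midpoint and merged (idempotent). Distal regions are typed active
(both marks), poised (H3K4me1 only), k27_only, or none. 200-bp bins
are enriched when the Poisson upper tail at the genome-wide mean rate
(over unmasked bins) is < 1e-4. WT/MUT differential bins use a 2×2
chi-square on [[r_wt, R_wt−r_wt], [r_mut, R_mut−r_mut]] without
continuity correction (Yates available by flag), differential at
p < 1e-4; expected cells < 1 trigger a warning, not an error.

The unmappable mask is the union of zero-read 3,000-bp windows at
500-bp stride, merged with gap/blacklist intervals. Random-sampling
enrichment draws 1,000 null sets matched element-for-element in length,
placed uniformly over positions where the whole element fits in
unmasked genome (chromosomes are thereby weighted by placeable length).
The add-one estimator (1 + #null ≥ obs)/(n+1) never returns 0; an
observation above every null reports p = 1/1001. The overlap statistic
is the element count by default; total overlapping bases are available
by flag and are what the calibration test uses, because the element
count is heavily tied at small query sizes and ties make the empirical
p conservative rather than uniform.

## Expression

The differential test is a label-permutation test on log₂(TPM+1),
exact over all C(r₁+r₂, r₁) splits when that is feasible, sampled with
a fixed seed otherwise; BH gives q. Two pooling modes:

- `per-gene` (the plain difference of condition means against the
  gene's own permutations) is exact but floor-limited — at 3v3 the
  smallest two-sided p is 2/20 = 0.1, so no gene can reach q < 0.05.
- `across-genes` (default): a variance-regularized t statistic
  (pooled SD plus the median SD as a stabilizer, in the SAM tradition)
  whose null pools the label-mixing splits of every gene; the identity
  labelling and its mirror are excluded from the null because they
  carry the real signal. This reaches p ≈ 1/(18·n_genes) at 3v3 and is
  empirically calibrated (null q < 0.05 rate ~0, p ≤ 0.05 rate ≈ 0.05).

This permutation test is this package's own differential-expression
method; it does not emulate any particular external DE tool, and a
precomputed q column can be supplied instead.

Grouping uses mean TPM > 5 in either condition; group 1 requires a
linear WT/MUT fold > 1.5 *and* q < 0.05 (the downregulated direction),
group 2 is the remainder at q < 0.2, group 3 the rest. Three TPM floors
are intentional and distinct: > 0 for distribution summaries, > 1 for
log-fold ratios, > 5 for grouping and co-association.

The paired Wilcoxon signed-rank test drops zero differences, reports
the signed rank sum W⁺−W⁻, and computes the exact two-sided tail by
dynamic programming over doubled (hence integer, tie-exact) ranks for
n ≤ 25; beyond that a normal approximation with variance Σrᵢ² (which
absorbs ties) is used.

## Co-association

For group n, category m, overlap k among N eligible genes, the
two-sided Fisher exact p on [[k, n−k], [m−k, N−n−m+k]] is signed:
−log₁₀p when k exceeds nm/N, +log₁₀p otherwise; |score| > 2 is the
significance convention. Two-sided was chosen because the signed score
reports depletion as well as enrichment; one-sided is available.
Categories are set-valued per gene and tested marginally. The
"non-SOX2 P-E" category is exclusive — genes whose promoter–enhancer
interactions involve no SOX2-bound enhancer — mirroring the contrast
between genes wired to SOX2-bound versus SOX2-free enhancers.
"SOX2 promoter target" means a SOX2 peak in the gene's promoter
window. No multiple-testing correction is applied across cells; raw
signed scores are reported.

## Synthetic data generator

The generator encodes the study conditions as defaults: 87.5% of loops
promoter-mediated, split evenly P-P / P-nonP; 38.5% of distal anchors
SOX2-bound; SOX2-bound distal anchors active (dual-marked) with
probability 0.97, versus 0.70 active / 0.15 poised / 0.15 single-or-no
mark for the rest; planted loop intensity 8 iPETs (Poisson); MUT
expression of SOX2-enhancer-connected genes at 0.15× WT; per-enhancer
WT boost 1.5×; replicate CV 0.2 with 3 replicates per condition; base
expression lognormal with ln-scale mean 3.4 and σ 1.2 (median ≈ 30
TPM). The standard test genome is 4 × 25 Mb with 2,000 genes — large
enough that 1,200 planted loops fit without anchor collisions, small
enough that the whole suite runs in well under a minute per stage.

Two modelling choices go beyond the planted effect itself:

- *Background downregulation.* 8% of genes without SOX2-bound
  enhancers are mildly downregulated (0.5×) in MUT. A perturbation of
  this kind has genome-wide indirect effects, and the significant-
  decrease group is much larger than its SOX2-P-E overlap; a generator
  in which only SOX2-connected genes move would make every disjoint
  category look strongly depleted, which is not the structure the
  co-association analysis describes.
- *Background PET distance law.* No background-noise model is given by
  the protocol; intra-chromosomal background distances default to a
  truncated power law (exponent 1, minimum 8,001 bp) as a stand-in for
  heavy-tailed ligation noise, with a `uniform` alternative (both tags
  independent) that is exchangeable under tag re-pairing and therefore
  the right null for the noise-ratio self-consistency check.

Enhancers are placed ≥ 3.5 kb from every TSS so a called distal anchor
can never fall inside a promoter window, and ≥ 4 kb apart so distinct
planted loops cannot merge during clustering. Strands are generated but
ignored downstream. What the generator does *not* emulate: sequence
content and mappability structure, distance-dependent contact decay of
real polymer physics, anchor-width heterogeneity, shared anchors
between many loops, and replicate-level batch effects — so passing
tests demonstrate the pipeline's correctness and calibration on known
structure, not performance on real libraries.

## Numerical and degenerate-input choices

- loops-per-million rounds half away from zero (matches all printed
  normalizations).
- Hypergeometric and Fisher tails come from scipy; both are
  oracle-tested against exact rational enumeration (T ≤ 60 exhaustive;
  all 2×2 tables with N ≤ 18 plus a sample to N = 40).
- p = 1 cases: zero iPET count, all-zero paired differences, empty
  groups (k = n = 0), saturating enrichment targets.
- `shuffle_noise` raises when the input has no PET-2+ clusters
  (undefined denominator); `loops_per_million` raises on a zero
  denominator; anchor annotation raises on unknown chromosomes.
- The null-calibration check for the cluster model evaluates the
  hypergeometric p over pre-specified random window pairs on re-paired
  PETs. p-values of clusters *selected* for c ≥ 2 cannot be uniform —
  selection conditions on the coincidence being tested — so model
  calibration is the property checked.
- Determinism: every sampler takes a seed; the pipeline fans one
  global seed out per stage via CRC-derived sub-seeds (< 2³¹), so any
  stage re-run in isolation reproduces its outputs byte for byte.

## Problem sizes used in tests and the acceptance script

Loop recovery: 50 planted loops (intensity 10) over 5,000 background
PETs on the 100-Mb genome. Type proportions: 1,200 loops. Expression
and co-association: 400 loops, 2,000 genes. Noise self-consistency:
50,000 uniform intra-chromosomal PETs on 2 × 2 Mb. Calibration: 200
replicates of 99-set enrichment nulls; ~4,000 random window pairs for
the cluster null. These sizes give comfortable Monte-Carlo margins for
every asserted band while keeping each stage in the seconds range.

## Known limitations

Inter-chromosomal clusters are not called (intra-chromosomal analysis
only). The hypergeometric model ignores contact-distance decay. The
permutation DE test needs ≥ 2 replicates per condition and, in
per-gene mode, cannot reach small p at 3v3. Anchor tag counts are not
extended beyond the cluster span before counting. The generator plants
at most one enhancer per loop side and no shared enhancers between
genes.
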