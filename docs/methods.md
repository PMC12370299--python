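# Methods

This note documents the models, conventions and numerical choices behind
`translocscape`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and matrix conventions

All in-memory intervals are 0-based half-open (BED convention); VCF positions
are 1-based and converted at the I/O boundary.  A `BinnedMatrix` stores a
symmetric count matrix, its genome-ordered bin table and a boolean per-bin
mask.  Masked bins behave as NA in every computation, but the underlying
counts are retained: masking decisions are therefore made on the stored
counts, which makes `mask_low_coverage_bins` idempotent and reversible.  The
"total interaction count" of a matrix counts each unordered bin pair once
(upper triangle including the diagonal).

## Interchromosomal landscape

Bins whose genome-wide row total (including cis) falls below 60 000 are
masked; this flags telomeric/centromeric-like low-mappability bins.  Masking
is applied to raw counts before depth normalisation (a flag order is not
imposed by the library; the CLI masks first).  Matrices are scaled to a fixed
total (default 150 M) and merged across samples by the element-wise median
(mean of central values for even sample numbers); an entry is NA whenever any
input is NA, which is the conservative choice for masked regions.

Trans frequency per chromosome pair is the summed unmasked trans count
divided by the product of the chromosomes' total bin numbers (counts per
Mb²).  Log₂ fold changes are NA when either frequency is NA or either is
zero — a zero numerator would otherwise produce an unbounded value that
dominates every ranking.  "Common extreme" pairs are those strictly above the
(1−q) quantile (or strictly below the q quantile) of both fold-change tables;
ties at the threshold are excluded, so a constant table selects nothing.  The
enrichment test is a 2×2 chi-square (selected vs not × focal-chromosome vs
not) without continuity correction — counts in this setting are large — with
a flag to enable the Yates correction.

Segment assignment uses per-chromosome breakpoint bounds with a small gap
(1 kb in the generator): a bin entirely below the lower bound is "up",
entirely above the upper bound "down", and a bin spanning the gap is excluded
from both segments.

## Allele-specific Hi-C

Heterozygous SNPs are retained when (a) heterozygous in both array
replicates, (b) heterozygous in pooled Hi-C genotype calls with genotype
quality ≥ 20, or (c) implied by differing homozygous genotypes of the sorted
derivative and wild-type chromosomes (each with GQ ≥ 20).  Positions with
contradictory ref/alt between sources are dropped with a warning.  A SNP's
derivative allele is forced by a homozygous derivative genotype and left
unassigned otherwise.

Read pairs vote per covered, assigned SNP; unanimous votes classify the pair,
disagreement yields "conflict", and a base matching neither allele is treated
as no evidence.  Pairs with both mates in mapped segments and a concordant
classification contribute one count per direction (two increments), so the
count tables read as "interactions from segment X to each chromosome"; how to
weight multi-SNP pairs is not canonically defined, and counting once per
pair-direction is the simplest consistent rule.  "none"/"conflict" tallies
are reported in a QC summary.  The short-chromosome test compares the
fraction of each allele's trans contacts that target a configured short set
with a 2×2 chi-square (no continuity correction), excluding contacts to the
segment's own chromosome.

## Diploid deconvolution and 3D geometry

Normal genomes: cis counts are halved between alleles a/b, trans counts
quartered over the four allele combinations; totals are conserved exactly.
Tumor genomes with one translocated homologue per partner chromosome: the
wild-type allele receives the full normal-reference counts, the derivative
the sample excess clamped at zero (the clamped-entry count is logged; the
data give no guidance for negative excess), so wildtype + derivative =
max(sample, reference) entrywise.  Trans entries among the two partner
chromosomes and their derivatives are set NA, since bulk counts there mix
derivative-cis and wild-type-trans signal that cannot be split.  Trans counts
between a partner and a non-partner chromosome are split between the
non-partner's two alleles evenly after the wild-type/derivative split.

Bead-model geometry: a territory's radial position is the Euclidean norm of
its bead center of mass (rotation-invariant, linear in coordinate scale).
The nuclear center is the origin of the CMM coordinate frame; the radius
(default 5 length units) is configuration, not read from the file.  CMM files
carry no genomic coordinates, so bead order plus a required sidecar bin
table defines the bin mapping; a recolor-by-chromosome utility edits the RGB
fields for visualisation.

Compartment tracks: each Mb bin's score is the median of its ten 100-kb
scores per sample, then the median across samples; labels are A (> 0), B
(< 0) and "undetermined" at exactly zero, where the sign rule is silent.
Eigenvector selection picks the candidate with the highest |Pearson r| to GC
content when that correlation reaches 0.6; if a competitor is within 0.05 of
the best |r| and their explained-variance ratio is below 1.5, the case is
flagged for manual inspection instead of guessed.

## Viewpoint profiling

4C fragments strictly closer than 10 kb to the viewpoint are removed
("within" read as strict), the rest summed into 250-kb bins from the region
start; retained totals are conserved.  Profiles use raw retained counts —
per-fragment normalisation belongs to upstream capture pipelines — with a
flag-free path for pre-scaled inputs (values are treated as given).

The insulation score is the mean count in the diamond [b−w, b) × [b, b+w)
(window default 5 bins), reported as log₂ of the ratio to the mean of all
diamond means.  This makes a uniform matrix score exactly zero and a
contact-depleted boundary negative; the score is only defined where the full
diamond fits.  Insulation differences default to sample − control (negative
= stronger insulation in the sample); the opposite convention is available
by argument since figure sign conventions vary.

Matrices are compared across cell lines after scaling each to the minimum
shared-region total.  Breakpoints are called by scanning every boundary k of
the cross-partner per-bin count vector and maximising
mean(upstream)/(mean(downstream) + ε) with ε = 1 (robust to all-zero tails);
a best ratio below 2 is reported as "no drop detected".

## Gene-level statistics

The patient-style selection takes protein-coding genes with log₂FC > 1,
FDR < 0.1 and expression in ≥ 3 of 5 case samples (thresholds strict; the
downregulated analog mirrors them).  The engineered-mixture selection uses
fold change > 1.1 and FDR < 0.1 — with ~10% of cells translocated, a 2-fold
within-cell effect dilutes to a population fold change of
f·FC + (1−f) = 1.1, which is what the mixture model computes.

Permutation enrichment assigns genes to the 3-Mb bin containing their TSS
(counted once), draws |upregulated| genes uniformly without replacement per
permutation (default 10 000), and estimates p = (#{random count > observed}
+ 1)/n.  The strict ">" with "+1" numerator is implemented exactly as
stated; a "≥" variant is available for sensitivity analysis.  Note the
estimator is slightly liberal for very discrete nulls (few genes per bin):
the calibration suite therefore uses gene-dense segments (60 Mb, 1200 genes,
200 upregulated, 20 bins), where the null p-value distribution is close to
uniform; at sparser gene counts, p-values near the nominal level should be
read with a grain of salt.

Distance correlations default to Spearman (no linearity assumption across a
50-Mb arm); Pearson is available by flag.  Promoter activity is any
qualifying chromatin-state interval overlapping the half-open window
[TSS − 1500, TSS + 1500).  Reported percentages round to one decimal.  The
allele→cell conversion doubles the translocated-allele fraction (one
junction per two control alleles in heterozygous cells), clipping fractions
above 0.5.

## Single-cell classification

Droplet QC removes cells with mitochondrial content > 20%, detected genes
< 500 or > 6000, or reads < 1000 or > 30 000; the bounds are exclusive as
printed, so boundary cells are kept.  Full-length QC requires ≥ 50 000
mapped reads.  CCND1 positivity is ≥ 1 transcript.  Doublet detection is out
of scope; a pre-computed `is_doublet` column is honoured when present.

Phasing pools allele reads of imprinted markers across non-translocated
cells; a marker anchors its parent to the haplotype carrying ≥ 90% of its
reads (the threshold for "biased representation" is a package choice,
configurable), markers below 10 pooled reads are dropped, and all remaining
markers must agree on a bijective mapping.  Translocated cells require ≥ 5
allele-specific CCND1 reads on one haplotype and zero on the other; cells
with CCND1 expression but insufficient allele evidence stay "unclassified"
and are excluded from pools.  Pseudo-bulk ratios report genes with ≥ 10
allele reads in the control pool and in at least one translocated pool.

## The synthetic generator

The toy genome has four chromosomes of 20/15/10/8 Mb at 1-Mb bins — small
enough that every stage runs in seconds.  Mean radial positions increase
linearly with chromosome length from 0.3 to 0.8 of the nuclear radius,
following the observation that short, gene-dense chromosomes sit centrally.
Cis contact means decay as c₀·(s+1)^(−α) with separation s in bins
(c₀ = 300, α = 1); trans means are t₀/(0.1 + |Δradial|) (t₀ = 3), giving a
trans/cis ratio of a few percent as in real Hi-C.  Counts are Poisson draws
around these means — the simplest count-noise model, chosen because the
consumed data formats carry no replicate structure to estimate
overdispersion from.  The translocation adds derivative-cis decay contacts
(at half scale, one homologue of two) across the junction to the tumor
matrix; the ultra-long-range loop multiplies the decay mean at its anchor
pair in **both** conditions, because such loops pre-exist in normal cells —
this is what lets the translocated enhancer exploit them.

Allelic reads anchor one mate at a SNP in the first partner's "up" segment
and send the other mate to a non-partner chromosome, short with probability
0.40 (wild-type allele) or 0.60 (derivative allele); the 0.4/0.6 gap is the
configured effect size for the short-chromosome test.  A base-flip error
rate (default 0) converts directly into the misclassification rate.  Bead
models place each territory's center of mass at its radial position exactly
(plus N(0, 0.03·R) jitter), with a centered random walk for bead shape;
derivative territories are displaced by the configured shift so the
parameter is recoverable as a mean difference.  The cell mixture marks a
fraction (default 0.11) of cells as translocated; these express CCND1
(guaranteed ≥ 1 transcript and ≥ 5 allele reads on the translocated
haplotype, i.e. noiseless) and upregulate genes in the configured bins, with
the extra reads in cis.  Two synthetic imprinted markers are fully
monoallelic and anchor the haplotype-to-parent phase.

What the generator does **not** emulate: sequence content and mappability
(no FASTQ, no alignment bias), polymer-physics contact structure (TADs,
compartment checkerboards), overdispersed counts, ambient RNA and doublets,
allele-specific mapping bias, or dropout structure in single-cell counts.
Passing tests therefore demonstrate the correctness of the statistics and
rules under their stated assumptions, not robustness to those artefacts.

## Problem sizes

The test and acceptance suites use the toy genome (53 bins), 10 000 read
pairs, 100 bead models, 500–3000 cells, and permutation runs of 4000–20 000
draws over segments of up to 1200 genes; the full suite completes in well
under a minute of compute for the unit tests plus about half a minute for
the acceptance properties.
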