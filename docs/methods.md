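# Methods

## The even-genomic-mass expectation model

A mock community assembled with equal DNA mass per species does not yield
equal 16S amplicon abundances: longer genomes contribute fewer genome copies
per nanogram, and genomes differ in rRNA operon count. The model chains the
genome molecular weight (607.4 g/mol per double-stranded base pair), the
single-genome mass via Avogadro's number, the per-species mass of the mix
(concentration × volume / species count), the resulting genome copy number
(kept real-valued — rounding to whole genomes would bias the downstream
ratios), and finally the expected 16S copy count (genome copies × per-genome
16S copies). Relative abundances are those counts renormalized. Because
every mass term cancels, the relative abundances reduce to
`copies_i / length_i` renormalized and are provably invariant to
concentration, volume and the base-pair weight constant; the intermediate
quantities are still reported because they are meaningful bench-side
numbers. Genus-level expectations sum the species values, the only
aggregation consistent with pooled 16S copy counts.

Assumptions: haploid chromosomes only (no plasmid-borne rRNA operons), a
GC-independent mean base-pair mass, and perfectly even mass pooling. These
are the same idealizations the certificate of an even mix asserts.

## Read stratification

Only primary alignments participate anywhere; secondary and supplementary
records are dropped at ingestion of the classification step. Internal
coordinates are 0-based half-open, converted from SAM exactly once. A read
overlaps a 16S gene when its aligned reference blocks cover at least
`min_overlap_bp` bases of the gene interval (default 1 — the field reports
no threshold, so any overlap counts; the knob is exposed). Deletions consume
reference and count toward overlap and coverage, matching reference-space
pileup semantics; insertions and clips do not.

Pair logic: a pair is on-target only when both mates land on the same gene
or on byte-identical copies of it *within the same genome* (identical-copy
groups are computed per genome from the extracted, strand-oriented gene
sequences; identical sequences shared across genomes do not merge, so such
pairs remain ambiguous). One mate on a 16S gene with the other off-target
or unmapped also counts as ambiguous rather than on-target: only concordant
evidence is credited to a gene. A mapped pair touching no 16S gene is
off-target; a pair with no mapped primary alignment is unmapped. The four
categories are exhaustive and mutually exclusive, so counts always conserve
the number of templates. Species relative abundances are computed over
on-target templates only, counting pairs once (a `--count-mates` style
doubling would only rescale, not reorder).

## ASV evaluation

Hits are filtered at identity ≥ 97 % and query coverage ≥ 90 %; among
survivors the best bitscore wins, ties broken by identity, then by
lexicographic genome id, making the choice deterministic. The bundled
aligner scans each genome (both strands) with banded infix edit-distance
alignment (edlib, band = 30 % of the query length — placements worse than
that can never reach the filters) and then trims the alignment to its
maximal-scoring local segment under BLASTN-like affine scores (match +2,
mismatch −3, gap open 5, gap extend 2, via a maximum-subarray pass over
per-column scores). Identity, query coverage, subject span and score are
computed on the trimmed segment. This is a seed-free, deterministic stand-in
for a word-seeded local aligner: at these thresholds the filter, not the
aligner's exact scoring, decides the outcome, and a quadratic Smith–Waterman
oracle is kept in the test suite to confirm agreement on short instances.
Precomputed tabular (outfmt-6) hits can be supplied instead, in which case
query coverage is reconstructed from the query span and length.

Labelling at a rank (genus or species): an ASV whose best hit overlaps an
annotated 16S gene is TP if its call matches the genome's known lineage
(after symmetric alias mapping between reference taxonomies — the bundled
table covers the Clostridium sensu stricto 1 / Clostridium,
Actinomyces / Schaalia and Escherichia-Shigella / Escherichia
discrepancies and is user-extensible), FP if the call is present but wrong,
FN if blank at that rank. A best hit outside every 16S region is TN — an
unusual but deliberate definition: such ASVs are real genomic signal that
the amplicon assay should not have produced, and crediting them as TN keeps
accuracy sensitive to off-target amplification. ASVs with no surviving hit
are reported separately as unaligned background noise rather than forced
into the matrix. Metrics can be read-weighted (each ASV weighted by its
total read count) or unit-weighted. ROC/AUC uses TP as the positive class
against FP and FN among on-gene ASVs, scored by the classifier confidence;
AUC equals the tie-corrected Mann–Whitney normalization. Without
confidences only the trivial single-threshold point is emitted.

## Concordance and diversity

Expected-vs-observed agreement uses Pearson's r with its exact t-based
two-sided p-value and an OLS fit reporting slope, intercept and adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2). Both axes are percentages; taxa missing
on either side enter as zeros (undetected taxa are evidence, not missing
data). Constant observations yield R² = 0 by convention rather than NaN.

Alpha diversity: single-draw seeded rarefaction without replacement (the
result sums exactly to the requested depth; shallower samples are dropped
with a warning), inverse Simpson `1/Σp²`, and Pielou's evenness
`H/ln S` over observed features (undefined below two features). Beta
diversity treats counts as compositions: pseudocount (default 1, exposed)
added before closure, CLR transform, Euclidean distance in CLR space
(the Aitchison distance), classical PCoA by eigendecomposition of the
double-centered −D²/2 (axes with positive eigenvalues only; explained
fractions over the positive spectrum), and one-way PERMANOVA with the
pseudo-F from the distance-partition identity, R² = SS_between/SS_total,
and p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) over seeded label
permutations (999 by default). Pairwise PERMANOVA runs each group pair
separately, as strategy comparisons are reported. All of these are
first-principles numpy implementations; scikit-bio serves only as an
independent cross-check in the test suite.

## The synthetic-data generator

The generator emulates the *structure* of a 20-strain even-mass mock:
20 species across 18 genera (two congeneric pairs), variable genome lengths
and 16S copy numbers (1–10), all 16S genes descending from one shared
ancestral 1,550-bp sequence with 5 % per-site inter-species divergence, and
a configurable fraction (default 0.5) of a genome's copies byte-identical,
the rest mutated at ≥ 1 site. Genome lengths default to 80–340 kb — a ~20×
scale-down from Mb-scale bacterial genomes that preserves the length and
copy-number variability the expectation model keys on while keeping
desk-scale runs fast. Reads (2×250 bp pairs from fragments inside genes, or
full-length reads of 1,000–1,600 bp) are emitted with a *truth* SAM
recording the generating locus, so stratification is testable without an
aligner; off-target templates come from intergenic loci and an optional
unmapped fraction is random sequence. ASVs carry substitution noise and
per-rank call errors; an error is blank or a wrong label according to
`call_blank_fraction` (default 0.5). When all errors are blanks, recall
TP/(TP+FN) has expectation exactly 1 − ε, which is the configuration the
recall-recovery check uses; with mixed errors the expectation is
(1 − ε)/(1 − ε/2) because wrong labels leave the recall denominator.
Confidences are Beta-distributed with a higher mean for correct calls.
Count tables are Dirichlet-multinomial around group means derived from the
expected profile, with a log-scale separation parameter (0 = exchangeable
groups, the PERMANOVA null).

What the simulator does *not* model — chimeras, platform quality profiles,
PCR amplification bias, co-extracted contaminants, real aligner ambiguity
between near-identical operons — bounds what green tests mean: they verify
the statistics and the bookkeeping, not robustness to every artifact of
real sequencing runs. In particular, simulated truth placements never
produce ambiguous pairs; that category is exercised by constructed cases.

## Numerical and scale choices

Normalized abundances are checked to 1e−9; PCoA reconstruction to 1e−8.
Ties in best-hit selection and ROC thresholds are resolved
deterministically (documented above). Degenerate inputs return None with a
warning where a metric's denominator vanishes (precision/recall on empty
classes, Pielou below two features) and raise where the request is
incoherent (rarefaction beyond the sample total, PERMANOVA with a singleton
group, zero-variance correlation). The acceptance script runs the full
loop at reduced problem sizes chosen for a single CPU: 10,000 read pairs
for stratification recovery, 2,000 ASVs against ten 20–40 kb genomes for
the recall check, and 2,000 null replicates at 199 permutations for
PERMANOVA calibration (the α = 0.05 rejection grid is exact at 10/200).
All randomness flows from numpy Generators seeded by the caller; identical
seeds give byte-identical outputs.
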