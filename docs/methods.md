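# Methods

## Signal quantification

Reads are intervals on a 0-based, half-open coordinate system; each
read is assigned to exactly one bin by its 5′ start position. Single-
point assignment makes the per-bin counts partition the window count
exactly, which is what turns the window-level normalization

H_i^k = h_i^k · 10⁹ / (h_k · L)

into the identity *window value = mean of the bin values* (the bins
tile the window and share the depth factor). The 10⁹ scale keeps the
numbers on the same footing as RPKM. The window is ±`flank_bp` around
the TSS (default 5 000 bp) in `bin_bp` bins (default 100 bp → 100
bins). Bins are labelled −50…−1, 1…50 in transcription direction: for a
minus-strand gene the genomic bin order is reversed, so "upstream"
always means upstream of transcription. Replicate tracks are each
normalized by their own depth and then averaged arithmetically.

Windows that run off the chromosome start are clipped (zero counts,
logged warning). Chromosome-name dialect mismatches ("chr1" vs "1")
raise instead of being silently renamed.

### Per-bin difference scan

For each mark and bin, signals are compared across genes between the
two conditions with an unpaired Welch t-test (a paired variant is a
flag: the conditions are different cell populations measured on the
same genes, and either reading is defensible). P-values are
Benjamini–Hochberg adjusted across the 100 bins within each mark;
`adjust="none"` reproduces the raw-p reading. A bin with zero variance
in both conditions gets p = 1 by convention. Default significance
threshold: adjusted p < 0.01.

## Expression and DEG labels

RPKM = count · 10⁹ / (exon_bp · library_size). Labels follow strict
inequalities: *up* iff adjusted p < 0.01 and log2 FC > 1, *down* iff
adjusted p < 0.01 and log2 FC < −1, else *neither*. The built-in
`simple` caller is an exact binomial test of the cancer count against
the pooled two-library expectation with BH adjustment — a deliberately
small, dependency-free stand-in adequate for synthetic data; external
DEG tables (e.g. from a dispersion-modelling caller) slot in through
`method="external"`. Fold changes use a pseudocount of one read in both
conditions when either raw count is zero; a gene with zero counts in
both conditions is *neither* with log2 FC = 0.

## Ratio features

Feature = (cancer + ε)/(normal + ε) per mark and bin (per-bin mode) or
per mark on window-level signals (region mode). ε defaults to half the
smallest nonzero normalized signal in the tensor pair — small enough
not to distort informative ratios, large enough to keep zero bins
finite. Raw ratios are the default classifier input; log2 ratios are a
flag. Rows are the up- and down-labelled genes in sorted gene order.
With ε = 0 swapping the conditions maps every ratio r to 1/r; region-
mode ratios equal the ratio of bin means by the identity above.

## Classifier and evaluation

Random forest (500 trees, √p features per split by default — the
canonical defaults of the reference implementation; no class weights),
stratified 2/3 train / 1/3 test splits, 10 repeats. Sn and Sp come from
hard labels at probability 0.5; the AUC is the trapezoidal area under
the probability-score ROC on the test set. A sensitivity/specificity
pair alone does not determine a curve, so the single-point estimate
(Sn+Sp)/2 is reported alongside the probability AUC rather than in its
place. Per-repeat split and forest seeds derive from one master seed
and are independent of the feature matrix, so evaluations of different
feature subsets under the same seed share splits (common random
numbers); this removes split noise from subset comparisons and makes
the full-subset entry of a scan bitwise-equal to a direct evaluation.
Stratification uses first-occurrence group codes, not label strings, so
relabeling up↔down leaves the splits themselves unchanged (and swaps
Sn with Sp exactly). A split that loses a class (possible only
unstratified) is re-drawn with an incremented seed and logged.

## Subset scan

All 2^m − 1 non-empty mark subsets, ordered by (size, lexicographic),
each evaluated on its region-mode columns with shared splits. The
near-optimal pool for size k is the set of k-mark subsets whose mean
AUC is at least `threshold` (default 0.95) times the full-model mean
AUC, read literally on mean AUCs; the frequency table counts each
mark's appearances in that pool. m is a parameter: desk-scale tests
run m = 4–6 exhaustively in seconds; the full m = 11 enumeration is
2 047 models.

## Per-bin importance

For each bin, the m same-bin ratios feed (a) a classifier whose AUC
profiles that genomic position and (b) a regression forest on 0/1-
encoded labels from which %IncMSE is computed: out-of-bag predictions
are aggregated over the trees for which each gene is out of bag, one
feature's column is permuted, and the importance is
100 · (MSE_perm − MSE_oob)/MSE_oob, averaged over 5 independent
permutations (deterministic per seed). A regression forest is used
because %IncMSE is a regression-forest statistic; labels are encoded
0/1. Importance magnitudes are not comparable across bins, so they are
converted to within-bin ranks (rank 1 = largest; ties go to the
lexicographically smaller mark name). The rank-1 mark per bin forms the
table's `argmax_hm` column. No conditional-importance correction for
correlated features is applied; with strongly co-varying marks,
permutation importance splits credit among them (tests assert exactly
this masking behaviour).

## Correlation, clustering, network

Spearman rho (mid-ranks, average ties) between each (mark, bin) ratio
column and the per-gene expression ratio, separately within up- and
down-DEGs; pairwise mark–mark Spearman on region-level ratios (a raw-
signal flag exists because the published analysis is ambiguous on this
point); agglomerative clustering of the rho rows with Euclidean
distance (complete linkage by default — the metric is fixed by the
source analysis, the linkage is not, so it is a parameter); and an
edge list of mark pairs with rho strictly greater than 0.6, one row per
unordered pair, consumable by any graph tool. A constant vector has no
rank correlation: NaN with a warning, and clustering refuses matrices
with missing entries.

## Synthetic data

The generator emulates what the analysis assumes about real data: per
gene a log2 expression fold-change F ~ N(0, fc_sd = 1.5); normal counts
Poisson around a log-normal baseline (mean 100 reads); cancer counts
Poisson(mu · 2^F). Read tracks have baseline 0.05 reads/bp per gene
window (≈5 reads per 100-bp bin — promoter-proximal ChIP enrichment at
typical depths), depths 10⁷ (normal) and 8·10⁶ (cancer) so the
normalization must genuinely correct a depth difference, and uniform
read starts within bins. For a *driver* mark, a gene in the mark's
regulon (Bernoulli, `responsiveness` = 0.5 per gene and mark) changes
its cancer-condition intensity by 2^(s·effect_size·F + η) in the
mark's effect bins (s = +1 active, −1 repressive; η ~ N(0, 0.5) is
gene-level response noise; effect_size default 1, 0 = null). Regulon
membership and response noise keep any single mark an imperfect
predictor — single-driver AUC ≈ 0.75–0.85, three drivers ≈ 0.95 —
mirroring the regime reported for real chromatin data, where combining
marks measurably helps; a deterministic coupling instead drives every
driver-containing subset to AUC 1.0 and makes "best subset" a
tie-break artefact.

RNA count tables carry matched effective library sizes (10⁶ per
condition) rather than panel column sums: every gene in the panel may
be differentially expressed, so total-count libraries would carry the
composition bias that size-factor normalization removes in real
pipelines, and the built-in binomial caller has no size-factor step.

What the generator does *not* emulate: nucleosome-scale peak shapes,
fragment-length effects, overdispersed (negative-binomial) counts,
mappability or GC structure, gene-density effects, or correlated
regulons between marks. Passing tests therefore demonstrate that the
pipeline recovers planted structure under idealized Poisson noise, not
that it would achieve the same accuracy on real ChIP-seq.

## Problem sizes and determinism

Stochastic end-to-end checks run at desk scale, chosen once: null
calibration at 500 genes, 11 marks, 10 repeats with default forests,
averaged over 5 replicate datasets (a single dataset's mean AUC carries
chance-correlation noise of sd ≈ 0.04, so one draw is a poor estimate
of the pipeline's calibration);
driver recovery at 300 genes, 6 marks (63-subset exhaustive scan), 6
repeats and 50-tree forests over 20 generated datasets; per-bin
importance demonstrations on ±1 kb schemes (20 bins). Every stochastic
component (generator, splits, forests, permutations) is seeded from a
single master seed via `SeedSequence`; same seed, same bytes.

## Known limitations

* The binomial DEG caller ignores biological overdispersion; it is a
  stand-in, not a reimplementation of dispersion-modelling callers.
* %IncMSE here aggregates OOB predictions forest-wide before permuting;
  the classical per-tree averaged variant differs by a normalization
  but orders features the same way on the cases tested.
* Permutation importance shares credit among correlated features; the
  within-bin ranks inherit that behaviour.
* The paper-scale numbers (AUC 0.92 for a best three-mark model on real
  leukemia vs lymphoblastoid data) depend on real ENCODE tracks and are
  out of scope here; the package asserts structural and synthetic-
  recovery properties instead.
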