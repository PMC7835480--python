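# histmod-dex

Histone-modification (HM) signal changes around transcription start
sites as predictors of differential gene expression between a normal
and a cancer (chronic myelogenous leukemia-like) condition.

Chromatin marks such as H3K79me2, H3K36me3 and H3K27ac change together
with gene expression when a cell turns malignant. Given per-condition
ChIP-seq read tracks for a panel of marks, a gene annotation and
RNA-seq counts, this package quantifies each mark's signal in 100 bins
of 100 bp spanning ±5 kb around every TSS, labels genes as up-/down-
regulated, and asks which marks — and which positions relative to the
TSS — carry the information that separates up- from down-regulated
genes.

## The model

For gene *i* and mark *k*, the depth- and length-normalized signal over
a window of length *L* is

```
H_i^k = h_i^k · 10^9 / (h_k · L)
```

with *h_i^k* the read count in the window and *h_k* the track's
sequencing depth; the per-bin variant replaces *L* by the bin length
*L_j*. Because reads are assigned to exactly one bin by their 5′ start,
the window value is identically the mean of the 100 bin values.

Genes with BH-adjusted p < 0.01 and log2 fold-change > 1 (< −1) are
up-DEGs (down-DEGs). The feature for mark *k* (and optionally bin *j*)
is the cancer/normal signal ratio. A random forest is trained on a
stratified 2/3 split of the up/down genes and scored on the held-out
third, repeated 10 times; from the test-set confusion counts

```
Sn = 1 − N_D^U / N^U        Sp = 1 − N_U^D / N^D
```

and the ROC AUC of the forest's class probabilities is the headline
metric (the single-point estimate (Sn+Sp)/2 is reported alongside).
On top of this classifier sit

* an exhaustive subset scan over all 2^m − 1 mark combinations (2047
  models for the full 11-mark panel) with a best-AUC-per-size curve and
  the frequency of each mark among near-optimal models (mean AUC ≥ 95%
  of the full model's);
* per-bin models whose %IncMSE permutation importance ranks the marks
  within each bin (rank 1 = most important);
* Spearman correlation of signal changes with expression changes,
  mark–mark correlation heat-map input, Euclidean-distance hierarchical
  clustering, and the >0.6-correlation network edge list.

A synthetic-data generator plants known structure (driver marks whose
regulon's signal co-varies with expression change, active vs repressive
sign, depth differences, Poisson noise), so every stage can be tested
against ground truth.

## Worked example

```python
from histmod_dex import (SyntheticConfig, generate, quantify, call_degs,
                         build_ratios, evaluate, scan)
from histmod_dex.synthetic_data import small_panel_config

cfg = small_panel_config(n_genes=300, n_hms=6, n_drivers=3, seed=0)
ds = generate(cfg)                                   # tracks, counts, truth
tensors = quantify(ds.anchors, ds.tracks, cfg.scheme)
degs = call_degs(ds.counts, ds.anchors)              # up/down/neither
matrix = build_ratios(tensors["normal"], tensors["cancer"], degs,
                      mode="region")
res = evaluate(matrix, repeats=6, seed=0, n_estimators=50)
print(f"full-model AUC {res.auc_mean:.3f}")
sc = scan(matrix, repeats=6, seed=0, sizes_of_interest=(3,),
          n_estimators=50)
print("best 3-mark subset:", sc.best_subset(3))
```

prints

```
full-model AUC 0.971
best 3-mark subset: ('H3K27ac', 'H3K36me3', 'H3K79me2')
```

i.e. the exhaustive 63-subset scan identifies exactly the three marks
the generator planted as drivers, and the full 6-mark model separates
up- from down-regulated genes with AUC ≈ 0.97 on held-out genes.

The same stages are exposed on the command line:

```sh
histmod-dex simulate --n-genes 300 --seed 0 --out data/
histmod-dex quantify --annotation data/annotation.refflat \
    --track H3K79me2=normal=data/H3K79me2.normal.bed ... --out sig/
histmod-dex degs --counts data/counts.tsv --annotation data/annotation.refflat --out deg.tsv
histmod-dex ratios --signal-dir sig/ --degs deg.tsv --mode region --out matrix.tsv
histmod-dex classify --matrix matrix.tsv --repeats 10 --seed 17
histmod-dex scan --matrix matrix.tsv --sizes 3,4 --threshold 0.95 --out scan/
```

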