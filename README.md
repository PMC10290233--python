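# speck

Unsupervised estimation of **relative cell-surface receptor abundance** from
single-cell RNA-sequencing (scRNA-seq) count matrices.

Many single-cell analyses — cell typing, phenotyping, cell–cell signaling —
hinge on the abundance of surface proteins, but direct protein measurements
(CITE-seq antibody-derived tags, ADT) are rare and limited to available
antibodies. The naive proxy, the receptor's own transcript, is crippled by
the sparsity of scRNA-seq data. `speck` implements a reduced-rank
reconstruction with per-gene clustered thresholding that produces
cell-level estimates which track ADT measurements substantially better than
the raw transcript.

## Method

Given an *m* × *n* count matrix *X* (cells × genes):

1. **Log-normalize** — `X[i,j] ← ln(1 + X[i,j] · 10⁴ / Σⱼ X[i,j])`.
2. **Randomized SVD** — a rank-100 (or smaller) decomposition
   *X ≈ U Σ Vᵀ* of the non-centered matrix.
3. **Rank selection** — from the principal-component standard deviations
   `σᵢ/√(m−1)`, round the absolute consecutive differences to 2 decimals
   and run-length encode them; among runs with value ≥ 0.01 spanning ≥ 2
   difference pairs, the smallest-valued run marks the scree elbow and sets
   the target rank *k*.
4. **Reduced-rank reconstruction** — *X̂ = U[:, :k] Σ[:k] V[:, :k]ᵀ*.
5. **Clustered thresholding** — each gene's reconstructed column is
   partitioned by **optimal 1D k-means** (exact dynamic programming, no
   initialization dependence) with the cluster number chosen in 1..4 by a
   Gaussian-mixture BIC. If more than one cluster is found, every cell in
   the least-valued cluster is set to exactly 0; otherwise the column is
   kept as is. This exploits the characteristic bimodality of surface
   protein expression: a receptor is "off" in some cell populations and
   "on" in others.

Evaluation utilities quantify agreement with CITE-seq ADT data (centered
log-ratio normalization, per-receptor Spearman/Pearson/Kendall
correlations, and the proportion of receptors on which each method is
best), and a seeded synthetic generator produces paired scRNA-seq/ADT data
with known ground truth.

## Worked example

```python
import speck

# paired synthetic data: 2000 cells x 300 genes, 10 bimodal receptor genes,
# 4 cell types, intrinsic rank 8, paired noisy ADT readout
counts, adt, truth = speck.simulate_joint(seed=42)

result = speck.speck(counts, seed=42)
print(result.rank_used)                              # 17
print(int(result.per_gene_info.thresholded.sum()))   # 119  (of 300 genes)

# benchmark against the ADT ground truth
adt_clr = speck.clr_normalize(adt)
fmap = speck.FeatureMap.from_pairs(zip(adt.antibody_names, truth.receptor_genes))
est = speck.correlate(result, adt_clr, fmap, method_name="speck")
rna = speck.correlate(speck.log_normalize(counts), adt_clr, fmap,
                      method_name="rna_transcript")
print(round(est.correlations.median(), 3))           # 0.738
print(round(rna.correlations.median(), 3))           # 0.59
print(speck.proportion_best([est, rna]))             # speck 0.7, rna_transcript 0.3
```

The selected rank (17) sits near the planted dimensionality (8 cell-type
factors plus receptor structure). The median per-receptor Spearman
correlation with ADT rises from 0.59 (log-normalized transcript) to 0.74
(thresholded reconstruction), and the estimate is best for 7 of the 10
receptors.

The same pipeline is available from the shell:

```sh
speck simulate --out-dir data --cells 2000 --genes 300 --seed 42
speck run --input data/counts --output estimates.csv --seed 42 --report report.json
speck evaluate --estimates estimates.csv --adt data/adt.csv \
      --map data/antibody_map.tsv --out correlations.tsv
```

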