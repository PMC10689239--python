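# engramap

Single-cell analysis of fear-memory engrams in the mouse amygdala: iterative
cell-type clustering, spatial correlation mapping, and activity (IEG) scoring
of cued-fear-conditioning (CFC) responses — reimplemented as a tested,
reusable Python pipeline with a ground-truth synthetic data generator.

## Who this is for

Neuroscientists and computational biologists who want to apply (or scrutinize)
the engram-detection statistics used in amygdala scRNA-seq studies:
percentile-based activation calling over an immediate-early-gene (IEG) panel,
in-silico trapping differential expression, gene-module correlation scores,
and Pearson mapping of cell-type profiles onto Visium spots or in-situ
"energy" voxel atlases. Because the original raw data is large and external,
every stage here is validated against seeded synthetic datasets with planted
ground truth.

## The statistics at the core

**IEG score.** For the activity panel *G* = {Arc, Bdnf, Btg2, Fos, Fosl2,
Homer1, Npas4, Nr4a1}, let θ_g be the 90th-percentile expression of gene *g*
over all neurons (pooled timepoints). A cell is IEG-high if its expression
exceeds θ_g for any panel gene. Per cluster, F[g,t] is the fraction of
IEG-high cells for gene *g* at timepoint *t* ∈ {HC, 2h, 8h, 24h, recall};
S[t] = Σ_g F[g,t]; and

    IEG score = max over t ∈ {2h, 8h, 24h, recall} of ( S[t] − S[HC] ).

Trapping DE uses the 95th percentile and compares IEG-high against IEG-low
cells of the same type by d = mean log₂(x+1) difference; the 99th percentile
drives observed/expected enrichment against the chance rate.

**Correlation score.** For a gene module within one (cluster, timepoint)
group of *n* cells, the pairwise Pearson matrix is aggregated by mean Fisher
*z* to r̄, converted to a two-sided *p* through
t = r̄·√((n−2)/(1−r̄²)), and score = −log₁₀(p). The per-cluster score is
max(CFC timepoints) − max(HC controls, batch A or B).

**Taxonomy.** Cells are L1-normalized to 20,000, highly variable genes are
ranked by residual above a log₂CV–log₂mean fit (53 IEGs, 6 sex genes and
non-neuronal markers excluded), PCA → per-batch centering → Barnes–Hut t-SNE
(correlation distance, θ = 0.5, learning rate n/12, exaggeration 20) →
DBSCAN, with Ward/correlation dendrograms and branch markers ranked by the
difference in fraction-positive cells between branches.

## Worked example

Run the full pipeline on a synthetic experiment (6 neuron types in 3 classes,
5 timepoints in 2 batches, one planted engram type, one planted coexpression
module):

```bash
cat > demo.yaml <<'YAML'
outdir: demo_out
seed: 0
qc:
  min_genes_neurons: 150   # synthetic universe has 600 genes, not ~20k
YAML
engramap report --config demo.yaml
```

On this dataset the clustering pass recovers the three neurotransmitter
classes as clusters, and `demo_out/ieg_scores.tsv` contains:

```
      HC     2h     8h    24h  recall  ieg_score  low_confidence
0  0.703  1.888  0.833  1.494   0.636      1.184           False
1  0.595  0.570  0.747  0.759   0.675      0.165           False
2  0.712  0.597  0.696  0.883   0.610      0.172           False
```

Cluster 0 is the GABAergic cluster that contains the planted engram type
(activation probability 0.3 at 2 h and 24 h, panel genes scaled 5×): its
summed activated fraction S rises from 0.70 in home cage to 1.89 at 2 h, an
IEG score of 1.18, while the two glutamatergic clusters stay near the null
level (≈ 0.17). `demo_out/` also holds the cluster table and t-SNE
coordinates, dendrogram (Newick), branch markers, spatial correlation
matrices, module correlation scores, photometry z-matrix, and a reproducible
run manifest.

The same stages are available individually (`engramap simulate`, `qc`,
`cluster`, `spatial`, `engram`, `corr`, `photometry`) and as library
functions (`engramap.taxonomy`, `engramap.engram`, …).

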