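# Methods

This note documents the models, parameter choices and numerical decisions
behind `engramap`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator (`engramap.simulate`) emulates a cued-fear-conditioning (CFC)
single-cell experiment with known ground truth.

**Counts.** UMI counts follow a gamma–Poisson (negative binomial) law: for
cell *c* and gene *g*, counts ~ Poisson(L_c · p_{t(c),g} · γ), with γ ~
Gamma(1/φ, φ) and the overdispersion φ (default 0.3) shared across genes —
the standard UMI noise model, chosen for simple parameter recovery. Library
sizes L_c are log-normal (default mean 5,000 UMI, σ = 0.25, matching the
>3,000-UMI regime healthy neurons reach) so that QC thresholds have a
nontrivial effect.

**Design.** Default: three neuron classes (GABA, VGLUT1, VGLUT2) × 4 types,
five timepoints (HC, 2 h, 8 h, 24 h, recall) in two batches — batch A carries
HC/8 h/24 h, batch B carries HC/2 h/recall, so home-cage controls exist in
both batches, as in the emulated design. Batch effects are gene-wise
log-normal factors (σ = 0.15). Doublets (default 2%) are Poisson samples of
the summed rates of two cells from *different* classes, so the
marker-ratio < 2 doublet rule is actually exercised.

**Markers.** Each type gets `markers_per_type` marker genes elevated
`marker_fold`× (default 8) over a sparse shared baseline calibrated to ~0.4
expected UMI per off-type cell (so markers are detected in well under half of
all cells, as real markers are; a broad baseline would trip the
feature-selection detection gate, which no real marker set does).
Neurotransmitter-class markers (Gad2, Slc17a7, Slc17a6) get a fixed high
in-class level (~6 UMI) and near-zero off-class level: the doublet ratio rule
assumes the class markers are comparably strong, which they are in tissue.
Because rate units are renormalized per cell, these calibrations are settled
by a two-pass fixed-point sweep.

**Engrams.** An `EngramSpec` plants an activated state: cells of one type at
given timepoints are activated with the specified probability, scaling the
eight panel IEGs by `panel_fold` and, optionally, a signature gene set by
2^log2FC (the coregulated program trapping DE recovers). Signature genes get
a fixed ~2-UMI baseline, since the learning-related genes they emulate are
moderately expressed and near-zero "signature" genes would be erased by the
top-DEG mean-UMI > 1 filter rather than by any property under test.

**Modules.** A `ModuleSpec` plants coexpression: in active (type, timepoint)
groups, all module genes share a per-cell multiplicative factor
exp(loading·z), z ~ N(0,1) — multiplicative through one log-normal latent
factor so rates stay positive. The default loading 0.45 was calibrated once,
by direct measurement, to give a mean pairwise Pearson r ≈ 0.3 among module
genes in 50-cell groups, the regime the recovery experiments specify.

**Spatial targets.** Spots are Poisson samples of Dirichlet mixtures of type
mean profiles; the mixture concentrates (α = 12 vs 0.25) on the types
assigned to the spot's region, arranged as vertical strips of a grid. Voxel
atlases give each gene a gamma background energy plus marker elevation in its
type's region, and append four deliberately invalid genes violating exactly
one quality rule each (coverage ≤ 30 voxels, peak energy ≤ 5, mean ≤ 0.2,
all-zero).

**Photometry.** The 465 nm channel = exponential bleaching × (1 + shared
motion artifact) + post-event exponential transients (τ = 2.5 s) + Gaussian
noise; the 405 nm control lacks the transients. `response_amp` is expressed
in z units: the transient amplitude is scaled by the analytically expected
baseline bin noise, including the control-channel noise that the affine
detrending fit propagates into ΔF/F (factor √(1 + (f₀/c₀)²)).

**What the generator does not emulate:** ambient RNA, realistic mouse gene
names or empirical expression distributions, cell-cycle or dissociation
stress programs, spatial platform artifacts, per-spot cell-count variation.
Passing tests therefore demonstrate correctness of the statistics and
recoverability under the stated noise model, not performance on tissue data.

## Pipeline parameters

| parameter | default | notes |
|---|---|---|
| QC thresholds (neurons) | ≥ 3,000 UMI and ≥ 2,500 genes | thresholds inclusive; our call. The gene threshold assumes a ~20k-gene transcriptome; synthetic runs scale it to universe/4 |
| QC thresholds (non-neuronal) | ≥ 2,000 UMI and ≥ 1,000 genes | second stream, with Gad2/Slc17a7/Slc17a6-expressing cells excluded |
| normalization | L1 to unit sum × 20,000 | "length 1" read as L1 (library-size normalization), so fraction-positive and percentile statistics behave as intended; L2 available via config |
| feature gates | expressed in ≥ 5 cells and < 50% of cells | spot matrices disable the upper gate (micro-bulk pools make most genes ubiquitous) |
| exclusion lists | 53 IEGs + 6 sex genes + 25 non-neuronal markers | config block, editable |
| t-SNE | correlation metric, θ = 0.5, lr = n/12, exaggeration 20; final visualization perplexity 100 / exaggeration 5 | init = first two PCs scaled to sd 1e-4 |
| perplexity heuristic | median per-cell bend of the sorted 500-NN correlation-distance curve, clipped to [5, n/4] | |
| DBSCAN | min_pts 10, eps from the k-distance-curve bend | exposed in config; outliers dropped for cells, kNN-reassigned (k = 5) for spots |
| cluster auto-merge | mean-profile Pearson r > 0.995 **within the selected feature space** | replaces manual visual merging; full-transcriptome correlations sit near 1 for any two clusters, so similarity is judged on the clustering features |
| activity panel | 8 IEGs; percentiles 90 (score), 95 (trapping), 99 (obs/exp) | percentiles with linear interpolation over all neurons, zeros included |
| activation rule | expression > θ_g, falling back to > 0 when θ_g = 0 | without the fallback a mostly-zero gene flags all or no cells |
| trap DE | d on log₂(x+1) normalized means; top 100 with mean UMI > 1; d > 0.5 frequency rule | log scale matches the difference-vs-average (MA-style) reading of the statistic |
| fold-change dynamics | conditional mean above θ vs HC, pseudocount ε = 0.1 | the source defines no formula; this is ours |
| module eligibility | genes in > 200 class cells; clusters with ≥ 20 cells per timepoint | strict/inclusive as written |
| correlation score | mean Fisher z → r̄ → t test → −log₁₀p, capped at 320 | see "Known limitations" |
| photometry | 405→465 affine fit, ΔF/F = (s−fit)/fit; 0.5 s bins, −5..+5 s window, 5 s baseline | bins aligned to event time; windows clipped, not padded |

## Numerical choices

- **Bend ("elbow") detection** is the max-perpendicular-distance-to-chord
  rule on the min–max-normalized curve (ties to the smallest index; constant
  series → 1). For the two heavy-tailed curves — the sorted CV-residual curve
  and the PCA explained-variance curve — the bend is located on the log of
  the curve (positive residuals only for features): on the raw scale the few
  extreme leading values own the chord and the bend lands absurdly early
  (~15 features, 3 PCs on data with 120 planted markers and 12 types).
- **Ward linkage on a correlation-distance matrix**: Ward's update formally
  assumes Euclidean geometry; we follow the source procedure verbatim and
  note the deviation. Leaf order is `scipy`'s optimal leaf ordering.
- **Batch correction** is per-batch mean-centering of each principal
  component (grand mean restored) — a contract-satisfying alignment whose
  hook (`correct_batches(backend=...)`) accepts any callable implementing an
  iterative-centroid method. Batches with < 3 cells pass through with a
  warning.
- **Majority vote** for class assignment: each cell votes for the class with
  the highest marker-set mean (normalized expression); all-zero cells do not
  vote; the cluster takes the modal vote. "Expressed" means raw count > 0
  wherever a binary notion is needed.
- The atlas ">5 energy" rule is read as **max-over-voxels energy > 5**
  (coverage and mean are separately constrained); all three atlas thresholds
  are strict inequalities.
- Spot/voxel correlations use library-normalized, untransformed expression
  (configurable); ρ heatmap export offers per-cluster min–max scaling.
- correlation_p is computed through the log survival function of the t
  distribution, so |r| → 1 underflows to the smallest positive double rather
  than 0.

## Validation experiments and problem sizes

`engramap.validation` fixes the study conditions: clustering recovery uses 12
types × ~300 cells × 2,000 genes in two batches (ARI vs planted truth);
engram recovery plants 4 of 12 types at activation 0.3 (2 h/24 h, panel fold
5) over 20 seeded runs; the null calibration uses 100 cells per
cluster-timepoint group with batch effects off — the null property is defined
for CFC and HC drawn from the *same* distribution, and with batch effects on,
single-batch timepoints genuinely differ from the pooled-batch home-cage
baseline (the reason batch-matched controls exist); trapping DE plants a
30-gene signature at log2FC 1.5; module recovery plants one 10-gene module
(pairwise r ≈ 0.3) in one of six types at 50 cells/group; spatial recovery
uses 8 types over 4 regions for both spot and voxel targets.

## Known limitations

- **Correlation-score power at small n.** Aggregating the pairwise matrix by
  mean Fisher z to a single r̄ tested at the group's cell count is a
  conservative reading of the (unstated) matrix→p conversion: at r̄ = 0.3 and
  n = 50 it yields p ≈ 0.034 (score ≈ 1.5), so planted modules in that regime
  score above 2 in only a minority of runs — the acceptance experiment
  reports this honestly. A pair-count-aware test would be far more powerful
  but is anticonservative under the dependence among pairs sharing a gene,
  and would light up unplanted clusters; we keep the conservative statistic.
- Mean-centering removes only location batch effects; scale or nonlinear
  batch structure needs an external backend via the hook.
- Doublet handling is cluster-level (the ratio rule), not per-cell.
- GO enrichment is out of scope: ranked gene lists are emitted for external
  tools.
- The fiber-photometry utilities process traces and events; across-animal
  statistics beyond a simple paired pre/post test are left to the user.
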