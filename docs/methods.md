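# Methods

## Scope and design

`hrdfuse` reconstructs, at desk scale, a two-stage multimodal HRD-detection
pipeline: label-free contrastive alignment of three patient modalities into
a shared latent space, followed by supervised gradient-boosting
classification on the fused embeddings, with a three-stage gene-panel
selector curating the transcriptomic input. Everything runs on one CPU in
minutes; the synthetic cohort generator replaces the clinical datasets and
GPU-scale foundation encoders, preserving the statistical structure each
stage depends on while making ground truth available for recovery tests.

## Synthetic cohort model

Each patient carries a latent factor z ~ N(0, I_k) (default k = 8) shared
by all modalities.

* **Label.** HRD-High is drawn from a logistic model on z₁ with weight 2
  and an intercept found by bisection so the expected prevalence equals
  `hrd_prevalence` (default 0.3, matching the imbalance typical of
  breast/ovarian cohorts). After labelling, z₁ is shifted by ±`de_effect`/2
  per class, so a single knob (`de_effect`, Cohen's d units, default 1.5)
  controls class separation in every modality.
* **Morphology.** A slide is a bag of 8–24 patch embeddings
  (`patch_embed_dim` = 22, the toy encoder's width):
  patchⱼ = Az + εⱼ, with A a frozen random linear map and ε ~ N(0, σ²_morph)
  (default σ = 1).
* **Expression.** Background genes: softplus(Bz) + N(0, 1) on a log scale
  (continuous Gaussian deliberately, since the pipeline consumes continuous
  inferred expression, not counts). Planted differentially expressed genes
  gain a mean shift of `de_effect`·σ in HRD-High. Synergy pairs are
  sign-product constructions: gene 1 takes value s·a + noise with s = ±1
  random, gene 2 takes ±s·a with the sign matched in HRD-High and flipped
  in HRD-Low — each gene is marginally symmetric in both classes (a
  marginal test behaves like a null test) while the pair's sign product
  predicts the label. This gives the genetic algorithm a target that no
  marginal filter can find.
* **Predictor emulation.** An image-based expression predictor is emulated
  per gene as x + N(0, σ_g²(1/r² − 1)), whose population Pearson
  correlation with x is exactly r (`predictor_fidelity`, default 0.6061,
  the reported median accuracy of such predictors). r = 1 is an exact copy;
  r = 0 is independent noise with the gene's own variance. Zero-variance
  columns are flagged and passed through with unit-scale noise.
* **Clinical covariates.** Aneuploidy score, genomic-event burden and the
  three signature exposures are softplus-transformed Gaussians positively
  shifted in HRD-High by `de_effect`/2; histology is an independent
  categorical; `timex` scores are a linear readout of z. All are plumbed
  through one-hot/z-score preprocessing exactly like real tables would be.

What the generator does **not** emulate: H&E pixel texture (tiling is
tested on synthetic block images only), batch effects, missingness beyond
complete-case scenarios, count noise, or inter-gene correlation structure
beyond the shared factor. Passing tests therefore demonstrate that the
*algorithms* recover planted structure under calibrated noise — not
clinical performance.

## Splitting, preprocessing, leakage

Stratified patient-disjoint splits use largest-remainder rounding of
per-class counts (deterministic and exactly proportion-preserving; the
rounding scheme is a package choice). Numeric features are z-scored with
the population-sd convention; categorical level sets are frozen on the
training split, and unseen levels at apply time encode to all-zeros with a
warning rather than erroring. Every stage that may only see training data
(preprocessing fit, gene-panel selection, classifier fit, grid search)
takes the split manifest and raises on any non-training sample;
`assert_no_leakage` additionally checks pairwise disjointness across
manifests. The alignment API accepts no labels at all — enforcement by
signature, tested by inspection.

## Tiling

Tissue is any pixel with HSV saturation above 0.08 (white/grey background
has near-zero saturation) after removal of connected components under
16 px. The patch grid is anchored at (0,0), half-open, row-major; partial
edge tiles are discarded; patches keep ≥ 50% tissue by default. These
thresholds are declared defaults, not inferred from any reference
configuration. No stain normalisation is applied anywhere. Magnification is
caller-declared metadata; no rescaling is performed. The toy encoder emits
per-channel mean (3) + per-channel sd (3) + a 16-bin grayscale histogram
(16) = 22 features — the histogram width was set so the encoder's contract
dimension is 22; any foundation model can replace it behind the
`PatchEncoder` protocol. Aggregation defaults to mean pooling; gated
attention (softmax weights summing to 1) is available and is
permutation-consistent with the bag rows.

## Gene-panel selection

Stage 1 uses a two-sided Mann–Whitney U per gene with Benjamini–Hochberg
FDR (rank test chosen for robustness to the generator's softplus
nonlinearity; Welch t is swappable in config); constant genes get p = 1 by
convention. Stage 2 keeps genes with predicted-vs-true Pearson r ≥ 0.4 — a
threshold deliberately below the 0.6061 median fidelity so a well-calibrated
predictor retains a majority of genes. Stage 3 is a genetic algorithm over
fixed-cardinality gene subsets: tournament selection (k = 3), uniform
crossover with random add/drop cardinality repair, per-gene swap mutation
(rate 0.15), elitism (2), and **random immigrants** (6 fresh random
chromosomes per generation). The immigrants matter: a pure synergy signal
is invisible until all of its genes co-occur in one chromosome, so the
fitness landscape is flat almost everywhere and a plain GA collapses onto
lucky noise subsets; a uniform exploration floor restores reliable
discovery. Fitness is the mean stratified 3-fold CV AUC of a depth-4
decision tree on the candidate subset — a deliberately small nonlinear
learner: it exposes XOR-like interactions exactly as well as a shallow
boosted ensemble at ~1/25 of the cost, which is what makes multi-replicate
validation practical; a 50-tree gradient-boosting fitness is available via
`GAConfig.fitness_classifier="gbm"`. Fold assignment is frozen per run so
fitness is comparable across generations, and per-chromosome fitness is
cached. Panel size is a fixed constraint (260 at full scale, 5–20 in
tests), making fitness comparable across chromosomes. The full selector
runs DE → fidelity → GA on training data only and the panel is frozen
thereafter.

## Contrastive alignment

Each modality encoder is a configurable MLP implemented directly in NumPy
(explicit forward/backward passes, Adam). The default head is **linear**
(no hidden layers) with weight decay 0.1: at desk-scale n (~160 training
patients) deeper heads memorise batch composition and held-out cross-modal
retrieval collapses to near chance, while a regularised linear head
recovers the planted factor reliably; hidden layers remain available via
`EncoderSpec.hidden_dims` for larger cohorts. Inputs are z-scored with
training statistics stored in the bundle.

The objective is the symmetric InfoNCE loss summed over the three modality
pairs (equal weights by default, configurable): rows are L2-normalised,
similarities are cosine/τ, and the loss averages the row-wise and
column-wise softmax cross-entropies with the matching patient as target.
The temperature is learnable through its log (initialised at 0.07, the
convention of CLIP-style systems), clipped to [1e-3, 10]; a fixed-τ mode
exists for tests. Batches are sampled without replacement per epoch with
the last short batch dropped (contrastive quality depends on batch size);
batch size defaults to 128 and is clamped to n. Training is deterministic
given the seed. Gradients of the loss through the normalisation and
softmaxes are hand-derived and verified against finite differences to
1e-7 in the test suite.

Fusion L2-normalises each available modality projection, averages, and
re-normalises — the natural choice in a space where the contrastive
objective pulls same-patient projections together, and it degrades
gracefully to image-only inference (morphology + inferred transcriptomics,
molecular absent). Antipodal projections whose average vanishes raise
rather than silently producing a zero vector. The default shared dimension
is 512.

## Classification

The gradient-boosting defaults are the tuned optimum configuration:
learning_rate 0.01, max_depth 7, max_features ⌈log₂ d⌉ (9 at d = 512),
min_samples_leaf 1, min_samples_split 5, 100 estimators, subsample 0.8.
Grid search enumerates the full Cartesian product of candidate lists under
stratified CV with a deterministic lexicographic tie-break; the shipped
default grid brackets each tuned value and is a package choice, not a
reproduction of any original candidate list. The untuned baseline suite
pins six model families (logistic regression, random forest, RBF SVC,
gradient boosting, k-NN, decision tree) at explicitly frozen defaults so
rows cannot drift across library versions.

AUC is computed by the mid-rank Mann–Whitney statistic — identical to
trapezoidal ROC integration (verified to 1e-12) and robust to the heavy
score ties tree ensembles produce. The classification threshold defaults to
0.5 and is declared, with a threshold sweep emitted alongside every
evaluation; ratio metrics with empty denominators report NaN rather than
an arbitrary value.

## Pipeline plumbing

One YAML config drives all stages; unknown keys are rejected at any level.
The global seed fans out per stage as sha256(stage-name : seed) mod 2³¹, so
stages are independently reproducible. Every stage echoes its effective
config and appends input/output SHA-256 hashes, seed and timestamp to an
append-only ledger; rerunning a stage with identical config reproduces
identical output hashes (pickled model checkpoints included, since every
library call is seeded).

## Problem sizes and numerical choices

Validation runs use cohorts of 120–500 patients, 60–2000 genes, latent
dimension 6–8, and alignment embed dims of 16–512 — sizes chosen so the
full suite exercises every claim in a few minutes while keeping each check
statistically meaningful (e.g. 200 null replicates for FDR control, 50
seeded GA runs for synergy recovery, 100 random instances for InfoNCE
oracle equivalence). Degenerate inputs are handled explicitly throughout:
empty bags and grids, constant genes/features, zero-variance predictor
columns, single-class labels, unseen categorical levels, antipodal fusion
inputs.

## Known limitations

* The morphology path validated here uses the toy colour-statistics
  encoder; conclusions about foundation-model embeddings require plugging
  one in behind the `PatchEncoder` contract.
* The generator's modalities are (softplus-)linear readouts of a single
  shared factor; real cross-modal structure is richer, so retrieval
  accuracies here do not forecast clinical retrieval.
* Grid-search candidate lists, the fidelity threshold, the per-patch
  tissue fraction and the GA panel-size constraint are declared package
  defaults wherever the original configuration is unstated.
* No GO/pathway enrichment, survival modelling, federated training, or
  vendor WSI container parsing.
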