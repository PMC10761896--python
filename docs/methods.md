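# Methods

## Problem setting

Highly multiplexed imaging (MIBI, CODEX) measures tens of protein markers
per pixel over tissue. After cell segmentation, each cell is summarized by
its mean counts per pixel per marker and its area; phenotyping assigns each
cell a type from a curated vocabulary. `phenomlp` treats this as supervised
classification of the per-cell feature vector `x ∈ R^(N+1)` (N markers +
area), deliberately ignoring the image neighborhood: the per-cell
expression summary is cheap, platform-agnostic and — with enough curated
labels — sufficient for pathologist-level calls on most phenotypes.

## Expression extraction and normalization

For each positive label of the segmentation mask, expression of marker m is
the sum of channel m over the cell's pixels divided by the pixel count
(area). Because this readout is linear in counts, the two batch
normalizations are applied to cell tables rather than to images; the
results are identical to image-level scaling.

- **Per-FOV** (within one stitched run): the per-cell mean of a reference
  nuclear channel (Histone H3 by convention) is computed per FOV; every
  marker column of a FOV is multiplied by `max_FOV(mean) / mean(FOV)`, so
  the brightest FOV is the fixed point (coefficient 1).
- **Across-run**: the same construction with the per-cell *median* per run.

The FOV statistic is the unweighted mean over cells of per-cell mean
intensities (cells count equally regardless of area); a pixel-weighted mean
would be a defensible alternative but changes coefficients only when cell
size correlates with brightness. Both operations are multiplicative per
group, hence idempotent and ratio-preserving within every cell. A group
whose reference statistic is zero cannot be normalized and is reported as
an error naming the group. FOV normalization is intended to run before run
normalization, mirroring acquisition order (tiles within a run, then runs).

## Classifier

Four fully connected hidden layers (default width 512) with ReLU and
dropout after each, then a softmax classification layer; the predicted
class is the argmax, ties broken toward the lowest class index for
determinism. Design points the architecture itself does not fix:

- **Feature scaling.** Per-feature standardization (train-set mean/SD, SD
  floored at 1e-8) is fitted on the training split only and stored with
  the weights. Raw count scales differ by orders of magnitude between
  markers and area; an MLP trains poorly without this.
- **Initialization.** Fan-in-scaled uniform weights (limit `sqrt(6/fan_in)`),
  zero biases, seeded.
- **Dropout.** Inverted (survivors scaled by 1/(1−p) at train time), so
  inference is exactly the plain forward pass.
- **Numerics.** Softmax subtracts the row maximum before exponentiation;
  cross-entropy floors the true-class probability at 1e-12.

The implementation is plain numpy (forward, analytic backprop, Adam). At
these model sizes — a few hundred thousand parameters, mini-batches of
128 — a deep-learning framework buys nothing on CPU, and the closed-form
gradient is verified against finite differences in the test suite.

## Training protocol

Mini-batches of 128, dropout p = 0.25, Adam at learning rate 1e-3 (the
optimizer and rate are configurable; several tests use 5e-3 on tiny tables
where convergence speed matters more than stability). Per epoch the
training set is reshuffled (seeded), and the validation loss is evaluated
with dropout off. Early stopping combines a minimum epoch count with a
patience window: training stops once `epoch ≥ min_epochs` and the
validation loss has not improved for `patience` epochs, or at `max_epochs`
(defaults: min 10, patience 10; max 100 is sized for ~1M-cell tables and
should be raised to ~500 for small ones, since fewer optimizer steps fit
in one epoch). The returned parameters are those of the epoch with the
lowest validation loss; "improvement" is a strict decrease. The epoch
shuffle, dropout masks and weight initialization all derive from one user
seed via seed-sequence splitting, so a fit is bit-reproducible.

Cells labeled `UNASSIGNED` (the reserved name for unannotated/"Others"
cells) are excluded from training and evaluation by default; whether such
cells should ever be modeled as a class is exposed as a flag
(`include_unassigned`) rather than decided here, because curated studies
differ on it.

## Cross-validation designs

- **Cell-stratified k-fold**: per class, cells are shuffled and dealt
  round-robin, so per-fold per-class counts differ by at most one. This
  design lets cells of one patient appear on both sides and is known to
  flatter metrics; the plan records its mode so downstream reports can
  flag it.
- **Case-grouped k-fold**: whole cases (patients) are assigned to folds,
  largest-first to the currently lightest fold by total cell count, with
  seeded tie-breaking. Balancing targets cell counts, not case counts,
  because cells-per-case is typically very skewed and balanced test sizes
  stabilize the metrics. Control cases (e.g. reactive lymph node) can be
  pinned: they join the training side of every fold and are never tested.
- **Train/validation split**: stratified 80/20 within the non-test side of
  each fold, used for early stopping and model selection.

## Evaluation

Confusion matrices (rows true, columns predicted) with row percentages;
per-class precision, recall and F1 with zero-denominator cases reported as
0 *and flagged*, keeping macro averages defined while preserving
auditability; macro averages are unweighted over classes. Average precision
is the step-wise area under the precision–recall sweep,
`AP = Σ (R_n − R_{n−1}) P_n` over distinct-score threshold groups, without
interpolation — equal scores enter the sweep together. One-vs-rest softmax
probabilities serve as the scores. Across folds, metrics are aggregated as
mean ± sample SD (n−1; folds are a sample). Mean-expression matrices
(class × marker) built from ground-truth and from predicted labels are
compared by per-class Pearson correlation across markers plus an overall
correlation on the flattened matrices; zero-variance rows yield NaN with a
flag rather than an arbitrary number.

## Experiment drivers

`run_crossval` fits per fold and aggregates. `run_data_efficiency`
subsamples each fold's training side per fraction (stratified, seeded by
fold seed + fraction index so curves are reproducible); a subsample missing
a class is skipped and recorded. `run_transfer` restricts both tables to
the shared marker intersection in training-table order — missing markers
are never imputed — fits with an internal 80/20 validation split and
evaluates the second table. All drivers enforce that no `cell_id` occurs in
both the fitted and the evaluated data of a condition (the transfer driver
exempts the degenerate self-transfer case, which is useful as an in-domain
baseline).

## Synthetic data

The generator produces cell tables with the statistical structure the
classifier assumes, so every invariant is testable offline:

- **Signatures.** Log-space class signatures: each class has a disjoint set
  of enriched markers (default 2) at `high_level` 2.0 versus background
  0.0, i.e. ~7.4× enrichment on the natural scale — comparable to the
  contrast between a lineage marker and background staining. Marker 1 is a
  designated reference channel (`HistoneH3`) expressed at the same level
  (1.5) in every class, giving the normalizations a meaningful target.
- **Structure.** Cells draw a class from the abundance vector, a case and
  FOV uniformly (default 8 cases × 3 FOVs, cases dealt round-robin to 2
  runs so run normalization is exercisable); per-case and per-FOV batch
  shifts are centered normals in log space (SD 0.2 / 0.1), per-cell noise
  is lognormal (SD 0.3), and optional lateral spillover replaces each
  cell's expression by `(1−r)·x + r·x_neighbor` with a random same-FOV
  neighbor (default r = 0.05). Areas are truncated normal (120 ± 40 px,
  ≥ 1). A fraction of labels can be masked to `UNASSIGNED` while the truth
  is returned separately.

What the generator does **not** emulate: spatial coordinates and true
neighborhood structure (spillover partners are random within a FOV, not
adjacent), segmentation errors, channel crosstalk, zero-inflation from
antibody dropout, and the heavy-tailed class imbalance of real cohorts
(configurable but uniform by default). Tests passing on this data therefore
demonstrate correctness of the pipeline's mechanics and learnability under
a faithful noise family — not performance on any real tissue.

## Problem sizes in tests and the acceptance script

The reference evaluation conditions are a 10,000-cell, 5-class, 20-marker
table with noise SD 0.3 and generator-default batch effects. Tests and the
acceptance script train with hidden width 64 (the architecture default of
512 is unnecessary at 21 input features and makes no difference to the
checks, which are about protocol correctness); the data-efficiency
comparison evaluates the 5% and 100% endpoints over three seeds. The
acceptance script derives every seed from `--seed` and finishes in about a
minute on one CPU.

## Known limitations

- Per-cell expression features discard spatial context; phenotypes defined
  by morphology or neighborhood (e.g. some stromal distinctions) are out of
  reach by design.
- The run-normalization approach assumes the reference channel is equally
  expressed across phenotype compositions of runs; strong composition
  shifts between runs bias the coefficients.
- No class weighting or ensembling: severely imbalanced vocabularies may
  need the stratified subsampler or abundance-aware simulation to probe
  behavior before use.
- Checkpoints store raw weight arrays; models are not portable across
  incompatible marker panels (by intent — transfer requires an explicit
  marker intersection).
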