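# phenomlp

Cell phenotyping for highly multiplexed spatial proteomics (MIBI, CODEX and
similar platforms). Given segmented multi-channel images — or a precomputed
per-cell expression table — `phenomlp` assigns each cell one of K
user-defined phenotypes (B cell, macrophage, tumor, ...) with a compact
feed-forward neural network, and evaluates the result with the
cross-validation and precision–recall protocols this kind of study demands.

It is aimed at computational pathology and tissue-imaging groups who have a
segmentation and a curated (even partial) set of phenotype annotations and
want a fast, reproducible classifier rather than another round of manual
cluster annotation.

## The model

Each cell is described by `x ∈ R^(N+1)`: its mean counts per pixel for the
N markers plus its area in pixels, standardized per feature on the training
set. A four-hidden-layer network maps this to a distribution over the K
phenotypes:

    h_i = ReLU(W_i h_{i-1} + b_i),  i = 1..4,  h_0 = x
    y   = argmax_k softmax(W_c h_4 + b_c)_k

Hidden layers have width 512 by default; dropout (p = 0.25, inverted) acts
on each hidden activation during training only. Training minimizes
categorical cross-entropy in mini-batches of 128 with Adam, with early
stopping governed by a minimum epoch count and a patience window on the
validation loss; the parameters from the epoch with the lowest validation
loss are kept.

Around the classifier, the package implements the full study workflow:

- **preprocess** — per-cell expression extraction from TIFF channel stacks
  and integer segmentation masks (summed counts / area), plus
  reference-channel (Histone H3) normalization across FOVs within a run
  (means toward the brightest FOV) and across runs (per-cell medians toward
  the highest run median).
- **splits** — stratified cell-level k-fold, case-grouped k-fold in which
  every patient's cells stay on one side of each fold (with control cases
  pinned to training), and stratified 80/20 train/validation splits.
- **evaluation** — confusion matrices with row percentages, per-class and
  macro precision/recall/F1, step-wise average precision, across-fold
  mean ± sample SD, and mean-expression concordance between ground-truth
  and predicted groupings.
- **experiments** — drivers for k-fold cross-validation, data-efficiency
  curves over training-set fractions, and cross-dataset transfer on shared
  markers, all with structural leakage checks.
- **synthetic** — a generator of cell tables with known phenotype
  signatures, batch effects, spillover and class imbalance, so the whole
  pipeline is testable without any external download.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/04_crossval_and_data_efficiency.py
5-fold macro F1: 1.000 +/- 0.000
  training fraction 0.05: macro F1 0.771
  training fraction 0.25: macro F1 1.000
  training fraction    1: macro F1 1.000
```

On a 4,000-cell synthetic table with five well-separated phenotypes the
cross-validated macro F1 is essentially perfect, and the learning curve
shows the characteristic diminishing return: 5% of the training data
already gives 0.77 macro F1 and a quarter of it is indistinguishable from
the full set.

The same workflow is available from the shell:

```sh
phenomlp simulate --out data/
phenomlp train --table data/cells.csv --classes class_1,class_2,class_3,class_4,class_5 --out model/
phenomlp predict --table data/cells.csv --checkpoint model/model.npz --out preds.csv
phenomlp evaluate --predictions preds.csv --truth data/truth.csv \
    --classes class_1,class_2,class_3,class_4,class_5 --out report.json
```

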