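"""Train the phenotype classifier and read the evaluation report.

A 4,000-cell synthetic table is split 80/20 for train/validation and a
held-out test slice; the four-hidden-layer MLP is fitted with dropout and
early stopping, then scored with the confusion matrix, per-class
precision/recall/F1 and average precision.
"""

import numpy as np

from phenomlp import (
    SyntheticSpec,
    TrainConfig,
    evaluate,
    fit,
    predict,
    simulate_cells,
    train_val_split,
)

spec = SyntheticSpec(n_cells=4000, seed=3)
table, _ = simulate_cells(spec)
vocab = spec.vocab

rest, test = train_val_split(table, fraction=0.8, seed=0)
train, val = train_val_split(rest, fraction=0.8, seed=0)

config = TrainConfig(hidden_dim=64, max_epochs=30, min_epochs=10,
                     patience=10, seed=0)
params, history = fit(train, val, vocab, config)
print(f"stopped at epoch {history.stopped_epoch}, "
      f"best epoch {history.best_epoch} "
      f"(validation loss {min(history.val_loss):.4f})")

idx, probs = predict(test.features(), params, return_probs=True)
report = evaluate(test.labels, [vocab.classes[i] for i in idx], probs, vocab)
print(f"\ntest cells: {report.n_cells}")
print(f"macro precision/recall/F1: {report.metrics.macro_precision:.3f} / "
      f"{report.metrics.macro_recall:.3f} / {report.metrics.macro_f1:.3f}")
for i, cls in enumerate(vocab):
    print(f"  {cls}: F1 {report.metrics.f1[i]:.3f}, "
          f"AP {report.average_precision[cls]:.3f}")
# F1 balances precision and recall per phenotype; average precision
# summarizes the full precision-recall sweep of the softmax scores.
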