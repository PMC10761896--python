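"""Simulate a synthetic cell table and summarize its annotation coverage.

The generator draws 5,000 cells from five phenotypes, each defined by two
enriched markers over a 20-marker panel, with per-case/per-FOV batch
effects and lognormal noise; 5% of cells are masked to UNASSIGNED the way
unannotatable cells are in curated datasets.
"""

from phenomlp import SyntheticSpec, simulate_cells, summarize

spec = SyntheticSpec(n_cells=5000, unassigned_fraction=0.05, seed=7)
table, truth = simulate_cells(spec)

s = summarize(table, spec.vocab)
print(f"cells: {s.total_cells}, markers: {table.n_markers}")
for cls, n in s.class_counts.items():
    print(f"  {cls}: {n} cells")
print(f"annotated: {s.n_labeled}/{s.total_cells} ({s.labeled_percent}%)")
# The percentage is the fraction of cells carrying a curated phenotype;
# the remainder are UNASSIGNED and excluded from training by default.
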