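import numpy as np
import pytest

from phenomlp import CellTable, ClassVocabulary, SyntheticSpec, simulate_cells


@pytest.fixture
def vocab_ab() -> ClassVocabulary:
    return ClassVocabulary(("A", "B"))


@pytest.fixture
def small_table() -> CellTable:
    """10 hand-built cells over 3 markers, two cases, two FOVs."""
    rng = np.random.default_rng(7)
    n = 10
    return CellTable.from_arrays(
        markers=["HistoneH3", "CD20", "CD68"],
        cell_id=[f"c{i}" for i in range(n)],
        case_id=["case1"] * 5 + ["case2"] * 5,
        fov_id=["f1"] * 3 + ["f2"] * 2 + ["f3"] * 5,
        run_id=["r1"] * 5 + ["r2"] * 5,
        area=rng.integers(50, 200, size=n),
        expression=rng.gamma(2.0, 1.0, size=(n, 3)),
        label=["A", "A", "B", "B", "A", "UNASSIGNED", "B", "A", "B", "A"],
    )


@pytest.fixture(scope="session")
def easy_table():
    """Well-separated 3-class table used for quick parameter-recovery runs."""
    spec = SyntheticSpec(
        n_classes=3, n_markers=8, n_cells=1500, noise_log_sd=0.2,
        spillover_rate=0.0, case_batch_log_sd=0.0, fov_batch_log_sd=0.0, seed=11,
    )
    table, truth = simulate_cells(spec)
    return spec, table, truth
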