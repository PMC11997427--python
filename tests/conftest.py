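import numpy as np
import pytest

from pavscan import PAVMatrix, SimulationConfig


@pytest.fixture
def small_config():
    """A fast two-population cohort used across modules."""
    return SimulationConfig(
        seed=7,
        n_genes=40,
        n_chromosomes=3,
        chromosome_length=500_000,
        group_sizes={"cultivated": 12, "wild": 10},
        n_selected=6,
        n_snps=300,
        n_tissues=5,
        n_specific_genes=8,
    )


@pytest.fixture
def toy_pav():
    """5 genes x 4 samples with hand-checkable frequencies."""
    calls = np.array(
        [
            [1, 1, 1, 1],  # frequency 1.0
            [1, 1, 1, 0],  # 0.75
            [1, 0, 0, 0],  # 0.25
            [0, 0, 0, 0],  # 0.0
            [1, 1, 0, 0],  # 0.5
        ],
        dtype=np.int8,
    )
    return PAVMatrix(
        gene_ids=[f"g{i}" for i in range(1, 6)],
        sample_ids=["s1", "s2", "s3", "s4"],
        calls=calls,
        populations={"s1": "cultivated", "s2": "cultivated", "s3": "wild", "s4": "wild"},
    )
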