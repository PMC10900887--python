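import numpy as np
import pytest

from rarebench import DatasetSpec, OtuTable, generate_dataset


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 samples × 4 OTUs with hand-checkable counts."""
    return OtuTable(
        ("s1", "s2", "s3"),
        ("Otu1", "Otu2", "Otu3", "Otu4"),
        np.array([[5, 3, 2, 0], [1, 0, 3, 0], [2, 2, 2, 2]]),
    )


@pytest.fixture(scope="session")
def small_table() -> OtuTable:
    """12 samples × 300 OTUs, ~12-fold depth spread; reused across tests."""
    spec = DatasetSpec(
        name="small",
        n_samples=12,
        n_otus=300,
        depth_log_mean=np.log(3000.0),
        depth_log_sd=0.8,
        min_depth=500,
        max_depth=20000,
        abundance_log_sd=2.0,
        seed=7,
    )
    return generate_dataset(spec)
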