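import numpy as np
import pandas as pd
import pytest

from metabomark import FeatureTable, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def two_group_config() -> SyntheticConfig:
    """Two-group study at the reference design size: 11 vs 11 children,
    ten planted markers at fold change 16, 10% technical RSD."""
    return SyntheticConfig(
        n_features=100,
        groups=(("HC", 11), ("PA", 11)),
        n_differential=10,
        fold_changes=(16.0,) * 10,
        technical_rsd_percent=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_group_dataset(two_group_config):
    return generate_dataset(two_group_config)


@pytest.fixture()
def tiny_table() -> FeatureTable:
    """Hand-sized table: 4 biological samples in 2 groups + 3 QC injections."""
    values = pd.DataFrame(
        {
            "f1": [1.0, 2.0, 3.0, 4.0, 2.4, 2.5, 2.6],
            "f2": [10.0, 10.0, 10.0, 10.0, 1.0, 2.0, 3.0],
            "f3": [np.nan, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        },
        index=["a1", "a2", "b1", "b2", "qc1", "qc2", "qc3"],
    )
    groups = pd.Series(["A", "A", "B", "B", "QC", "QC", "QC"], index=values.index)
    is_qc = pd.Series([False] * 4 + [True] * 3, index=values.index)
    return FeatureTable(values, groups, is_qc)
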