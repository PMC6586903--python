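import numpy as np
import pandas as pd
import pytest

from refframes import FeatureTable, build_design_matrix, simulate_count_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    counts = np.array([
        [10, 5, 0, 20],
        [8, 2, 4, 16],
        [12, 6, 3, 9],
        [7, 7, 7, 7],
    ])
    return FeatureTable(counts, ("s1", "s2", "s3", "s4"),
                        ("taxA", "taxB", "taxC", "taxD"))


@pytest.fixture
def paired_experiment():
    """Small paired two-group draw shared by ranking/ratio tests."""
    return simulate_count_experiment(n_per_group=12, D=8, depth=2000, seed=7)


@pytest.fixture
def paired_design(paired_experiment):
    exp = paired_experiment
    return build_design_matrix(exp.metadata, [("group", "categorical")],
                               sample_ids=exp.table.sample_ids)


@pytest.fixture
def two_group_metadata():
    return pd.DataFrame(
        {"group": ["pre", "pre", "post", "post"], "ph": [6.5, 7.0, 7.5, 8.0]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
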