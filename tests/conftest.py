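import numpy as np
import pandas as pd
import pytest

from eqtg import FeatureTable, Hyperparameters, LabeledGeneSet, SimConfig
from eqtg.evaluation import CVConfig
from eqtg.simulate import simulate_feature_table, simulate_raw_inputs


@pytest.fixture(scope="session")
def small_sim():
    """Small labeled table with planted signal: 40 positives / 400 pool,
    10 features of which 3 informative, one correlated block."""
    cfg = SimConfig(
        n_genes=440, n_positives=40, n_features=10, n_informative=3,
        effect_size=2.0, n_correlated_blocks=1, block_size=3, block_corr=0.85,
        seed=101,
    )
    return simulate_feature_table(cfg)


@pytest.fixture(scope="session")
def raw_inputs(tmp_path_factory):
    """Toy PPI / expression / annotation files plus their ground truth."""
    out = tmp_path_factory.mktemp("raw")
    return simulate_raw_inputs(out, n_genes=30, seed=3)


@pytest.fixture
def tiny_cv_config():
    return CVConfig(
        n_positive_splits=2, n_negative_samplings=2,
        hp=Hyperparameters(n_trees=25, pos_neg_ratio=3), master_seed=42,
    )


@pytest.fixture
def toy_table():
    """Hand-built 6-gene x 3-feature table, no missing values."""
    frame = pd.DataFrame(
        {
            "f1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "f2": [0.5, 0.1, 0.9, 0.2, 0.8, 0.3],
            "f3": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
        },
        index=[f"g{i}" for i in range(6)],
    )
    return FeatureTable(frame)
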