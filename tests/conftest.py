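import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dnbkit import SyntheticConfig, generate_dataset
from dnbkit.datasets import ConditionSlice


@pytest.fixture(scope="session")
def planted():
    """Default-condition synthetic dataset with a planted DNB module."""
    config = SyntheticConfig(seed=11)
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def null_dataset():
    """No planted structure at all: pure baseline noise."""
    config = SyntheticConfig(
        n_genes=200, n_dnb=10, sd_ratio=1.0, target_abs_corr=0.0,
        n_deg_clusters=0, seed=7,
    )
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


def make_slice(values: np.ndarray, group="case", week=5, gene_ids=None) -> ConditionSlice:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(values.shape[0])]
    cols = [f"{group}_w{week}_r{k}" for k in range(values.shape[1])]
    return ConditionSlice(pd.DataFrame(values, index=gene_ids, columns=cols), group, week)
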