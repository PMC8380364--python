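import numpy as np
import pandas as pd
import pytest

import microlmp as m


@pytest.fixture(scope="session")
def fixture_dataset():
    """Reduced reference cohort shared by read-only tests (150 samples)."""
    cfg = m.SimulationConfig.default_fixture(seed=11)
    cfg.n_samples = 150
    table, taxonomy, metadata, truth = m.simulate_dataset(cfg)
    return cfg, table, taxonomy, metadata, truth


@pytest.fixture(scope="session")
def adjusted_metadata(fixture_dataset):
    _, _, _, metadata, _ = fixture_dataset
    return m.adjust_phenotype(metadata)


@pytest.fixture
def tiny_table():
    data = pd.DataFrame(
        [[2, 2, 0], [0, 5, 5], [1, 1, 2]],
        index=["s1", "s2", "s3"],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    return m.OtuTable(data, kind="counts")
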