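import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nwdose import AnalysisConfig, CountMatrix, build_field_design, build_lab_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def lab_design():
    return build_lab_design()


@pytest.fixture(scope="session")
def small_field_design():
    """Six cultivars in duplicate: 48 samples, cheap enough for GLM loops."""
    return build_field_design([f"cv{i:02d}" for i in range(1, 7)], replicates=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(values, gene_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values, dtype=np.int64)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
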