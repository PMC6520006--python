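import numpy as np
import pandas as pd
import pytest

from agevar import (ExpressionMatrix, SampleMetadata, SimulationConfig,
                    simulate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """300 genes x 147 samples with planted DE and DV (linear trend)."""
    cfg = SimulationConfig(n_genes=300, n_samples=147, frac_de=0.3,
                           frac_dv=0.3, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_null_dataset():
    """400 null genes (no DE, no DV, no batch/covariate effects)."""
    cfg = SimulationConfig(n_genes=400, n_samples=147, frac_de=0.0,
                           frac_dv=0.0, batch_scale=0.0,
                           covariate_scale=0.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(pd.DataFrame(
        [[2.0, 1.0], [4.0, 5.0], [6.0, 9.0]],
        index=["g1", "g2", "g3"], columns=["a", "b"]))


@pytest.fixture
def tiny_meta():
    return SampleMetadata(pd.DataFrame(
        {"age": [25.0, 70.0], "sex": ["F", "M"]}, index=["a", "b"]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
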