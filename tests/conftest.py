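import numpy as np
import pandas as pd
import pytest

from spongenet import ExpressionMatrix, SynthParams, simulate_sponge_dataset


@pytest.fixture
def small_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p1", "p2"],
            "condition": ["normal", "normal", "cancer", "cancer"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


@pytest.fixture
def small_matrix(small_samples) -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, "lncRNA", small_samples)


@pytest.fixture(scope="session")
def default_sponge_dataset():
    """One default-parameter sponge dataset shared across tests."""
    return simulate_sponge_dataset(SynthParams(random_seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
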