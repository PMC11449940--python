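import numpy as np
import pytest

from pulseaf import PipelineConfig, train_pipeline


@pytest.fixture(scope="session")
def default_model():
    """Ensemble trained once on the default synthetic cohort (seed 0)."""
    return train_pipeline(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def toy_table():
    """Fixed 40-row, 2-feature toy classification table.

    Two interleaved Gaussian blobs with a few overlapping rows so boosting
    needs several rounds; deterministic by construction.
    """
    rng = np.random.default_rng(42)
    X0 = rng.normal([0.0, 0.0], 0.8, size=(20, 2))
    X1 = rng.normal([1.5, 1.0], 0.8, size=(20, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
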