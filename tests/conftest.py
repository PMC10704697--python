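import numpy as np
import pytest

import solubgcn as sg

#: Small reduced block dimensions used where full Table-style dims are not
#: the point of the test — keeps fits fast while exercising all six blocks.
SMALL_DIMS = {"ESM": 4, "BLOSUM": 4, "AAPHY7": 2, "PSSM": 3, "HMM": 5, "SPIDER3": 3}


def fast_estimator(**overrides) -> sg.HybridGCNRegressor:
    """A quick-to-train estimator configuration for unit tests."""
    params = dict(
        gcn_hidden=12,
        attention_hidden=8,
        dropout=0.0,
        max_epochs=8,
        patience=5,
        batch_size=8,
        validation_fraction=0.2,
        random_state=0,
    )
    params.update(overrides)
    return sg.HybridGCNRegressor(**params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small full-dimension synthetic dataset plus its ground truth."""
    config = sg.SimConfig(n_proteins=16, length_range=(8, 14), seed=3)
    records, ground_truth = sg.simulate_dataset(config)
    return records, ground_truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """A reduced-dimension dataset for fit/predict round trips."""
    config = sg.SimConfig(
        n_proteins=20,
        length_range=(6, 10),
        block_dims=dict(SMALL_DIMS),
        informative_blocks=("ESM", "HMM"),
        informative_channels_per_block=2,
        seed=7,
    )
    records, ground_truth = sg.simulate_dataset(config)
    return records, ground_truth


@pytest.fixture(scope="session")
def fitted_tiny_model(tiny_dataset):
    records, _ = tiny_dataset
    est = fast_estimator()
    est.fit(records)
    return est
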