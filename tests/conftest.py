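import numpy as np
import pytest

from amescp import LabeledFingerprintDataset, SyntheticConfig, generate


@pytest.fixture
def tiny_dataset() -> LabeledFingerprintDataset:
    """Six compounds, four bits, both classes present."""
    return LabeledFingerprintDataset(
        compound_ids=np.array([f"c{i}" for i in range(6)], dtype=object),
        features=np.array(
            [
                [1, 1, 0, 0],
                [1, 0, 1, 0],
                [1, 1, 1, 0],
                [0, 0, 0, 1],
                [0, 1, 0, 1],
                [0, 0, 1, 1],
            ]
        ),
        labels=np.array(["M", "M", "M", "NM", "NM", "NM"], dtype=object),
    )


@pytest.fixture
def separable_dataset() -> LabeledFingerprintDataset:
    """Twenty compounds whose first bit determines the class exactly."""
    rng = np.random.default_rng(11)
    X = rng.integers(0, 2, size=(20, 6)).astype(np.uint8)
    labels = np.array(["M"] * 10 + ["NM"] * 10, dtype=object)
    X[:, 0] = (labels == "M").astype(np.uint8)
    return LabeledFingerprintDataset(
        compound_ids=np.array([f"s{i}" for i in range(20)], dtype=object),
        features=X,
        labels=labels,
    )


@pytest.fixture(scope="session")
def small_synthetic() -> LabeledFingerprintDataset:
    """Desk-scale synthetic dataset for pipeline tests (150 compounds, 60 bits)."""
    return generate(
        SyntheticConfig(
            n_compounds=150,
            n_mutagenic=100,
            n_features=60,
            n_activating=10,
            n_deactivating=5,
            seed=20,
        )
    )
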