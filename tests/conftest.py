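import numpy as np
import pytest

from protamine_ml import (
    LabeledDataset,
    SimulationConfig,
    featurize_dataset,
    simulate_dataset,
)
from protamine_ml.seqio import STANDARD_AA


def random_valid_sequences(n: int, rng: np.random.Generator, min_len: int = 12,
                           max_len: int = 80) -> list[str]:
    """Uniformly random sequences over the standard alphabet, all long enough
    for lag 10."""
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(STANDARD_AA), size=length)))
    return out


@pytest.fixture(scope="session")
def benchmark_records():
    """Separable arginine-rich vs background benchmark, n=200 per class."""
    return simulate_dataset(SimulationConfig(n_pos=200, n_neg=200, seed=11))


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark_records):
    dataset, skips = featurize_dataset(benchmark_records)
    assert not skips
    return dataset


@pytest.fixture(scope="session")
def imbalanced_dataset():
    """Random two-class 30-feature table with the curated-data class sizes
    (221 minority / 431 majority)."""
    rng = np.random.default_rng(42)
    features = rng.random((652, 30)) * 0.2
    labels = np.array([1] * 221 + [0] * 431)
    return LabeledDataset(
        features=features,
        labels=labels,
        provenance=np.full(652, "real", dtype=object),
    )
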