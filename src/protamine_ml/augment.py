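"""Class balancing by SMOTE and by a tabular GAN, with distributional QC.

Both balancers grow the minority class to the majority size and tag every
synthetic row with its provenance; original rows are never modified.  SMOTE
interpolates between minority points and their nearest minority neighbours
(so it never extrapolates outside the minority's per-feature range); the
GAN learns the minority distribution and samples fresh rows from it, which
typically show greater dispersion.  Note that synthetic rows need not sum
to 1 like genuine PseAAC vectors — they live in the feature space, not the
sequence space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .dataset import LabeledDataset
from .gan import GANConfig, TrainedGenerator, gan_sample, gan_train

__all__ = [
    "SmoteConfig",
    "GANConfig",
    "smote_oversample",
    "gan_train",
    "gan_sample",
    "balance_with_gan",
    "pca_compare",
]


@dataclass(frozen=True)
class SmoteConfig:
    """``k_neighbors`` minority nearest neighbours per synthetic sample;
    the (only) strategy is balance-to-majority."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _minority_majority(dataset: LabeledDataset) -> tuple[int, int, int, int]:
    counts = dataset.class_counts()
    if len(counts) != 2:
        raise ValueError("balancing requires exactly two classes")
    minority = dataset.minority_label()
    majority = 1 - minority
    return minority, majority, counts[minority], counts[majority]


def smote_oversample(
    dataset: LabeledDataset, config: SmoteConfig | None = None
) -> LabeledDataset:
    """Grow the minority class to the majority size by SMOTE interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``,
    ``x`` a uniformly chosen minority row and ``x_nn`` one of its
    ``k_neighbors`` Euclidean nearest minority neighbours.  An already
    balanced dataset is returned unchanged.  Deterministic given the seed.
    """
    config = config or SmoteConfig()
    minority, _, n_min, n_maj = _minority_majority(dataset)
    deficit = n_maj - n_min
    if deficit == 0:
        return dataset
    if n_min <= config.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors {config.k_neighbors}"
        )
    rng = np.random.default_rng(config.seed)
    minority_rows = dataset.features[dataset.labels == minority]
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(minority_rows)
    # drop each point's self-neighbour (column 0)
    neighbour_idx = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=deficit)
    pick = rng.integers(0, config.k_neighbors, size=deficit)
    gap = rng.random(deficit)
    x = minority_rows[base]
    x_nn = minority_rows[neighbour_idx[base, pick]]
    synthetic = x + gap[:, None] * (x_nn - x)
    return dataset.append(synthetic, minority, "smote", "smote")


def balance_with_gan(
    dataset: LabeledDataset,
    config: GANConfig | None = None,
    sample_seed: int | None = None,
) -> tuple[LabeledDataset, TrainedGenerator | None]:
    """Balance the dataset by training the GAN on minority rows only.

    Trains on the minority class, samples ``majority - minority`` rows, and
    merges them with provenance ``gan``.  Returns the balanced dataset and
    the trained generator (``None`` when the input was already balanced).
    """
    minority, _, n_min, n_maj = _minority_majority(dataset)
    deficit = n_maj - n_min
    if deficit == 0:
        return dataset, None
    config = config or GANConfig(out_dim=dataset.n_features)
    minority_rows = dataset.features[dataset.labels == minority]
    generator = gan_train(minority_rows, config)
    synthetic = gan_sample(generator, deficit, seed=sample_seed)
    return dataset.append(synthetic, minority, "gan", "gan"), generator


def pca_compare(
    real_features: np.ndarray, synthetic_features: np.ndarray
) -> dict:
    """Project real and synthetic rows onto shared principal components.

    The two principal axes are fitted on the pooled matrix, so real and
    synthetic clouds are directly comparable in one plane.  Returns the 2-D
    coordinates, a real/synthetic tag per row, and the explained-variance
    fractions of the two components.
    """
    real = np.asarray(real_features, dtype=float)
    synthetic = np.asarray(synthetic_features, dtype=float)
    if real.ndim != 2 or synthetic.ndim != 2 or real.shape[1] != synthetic.shape[1]:
        raise ValueError("real and synthetic matrices must share feature width")
    pooled = np.vstack([real, synthetic])
    if pooled.shape[0] < 2:
        raise ValueError("pca_compare requires at least two rows")
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(pooled)
    source = np.array(
        ["real"] * real.shape[0] + ["synthetic"] * synthetic.shape[0], dtype=object
    )
    return {
        "coordinates": coords,
        "source": source,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


def pca_compare_to_csv(result: dict, path) -> None:
    """Write QC coordinates as CSV with columns pc1, pc2, source."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "pc1": result["coordinates"][:, 0],
            "pc2": result["coordinates"][:, 1],
            "source": result["source"],
        }
    )
    frame.to_csv(path, index=False)
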