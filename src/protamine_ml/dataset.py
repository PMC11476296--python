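"""Labelled feature-table container shared by the featurization, balancing
and modeling stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROVENANCE_VALUES = ("real", "smote", "gan")


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-row provenance.

    ``provenance`` records whether each row came from a real sequence or was
    synthesised by SMOTE or the GAN; all rows entering the pipeline from
    featurization are ``real``.
    """

    features: np.ndarray  # (n, d) float
    labels: np.ndarray  # (n,) int in {0, 1}
    provenance: np.ndarray  # (n,) str
    ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.features.shape[0]
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("features, labels and provenance row counts differ")
        if not self.ids:
            self.ids = [f"row_{i + 1}" for i in range(n)]
        if not self.feature_names:
            self.feature_names = [
                f"x{j + 1}" for j in range(self.features.shape[1])
            ]
        bad = set(np.unique(self.provenance)) - set(PROVENANCE_VALUES)
        if bad:
            raise ValueError(f"unknown provenance values: {sorted(bad)}")

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def minority_label(self) -> int:
        counts = self.class_counts()
        if len(counts) != 2:
            raise ValueError("dataset must contain exactly two classes")
        return min(counts, key=lambda k: (counts[k], k))

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        index = np.asarray(index)
        return LabeledDataset(
            features=self.features[index],
            labels=self.labels[index],
            provenance=self.provenance[index],
            ids=[self.ids[i] for i in index],
            feature_names=list(self.feature_names),
        )

    def append(
        self,
        features: np.ndarray,
        label: int,
        provenance: str,
        id_prefix: str,
    ) -> "LabeledDataset":
        """Return a new dataset with synthetic rows appended."""
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.n_features:
            raise ValueError("appended rows have the wrong feature width")
        n_new = features.shape[0]
        return LabeledDataset(
            features=np.vstack([self.features, features]),
            labels=np.concatenate([self.labels, np.full(n_new, label, dtype=int)]),
            provenance=np.concatenate(
                [self.provenance, np.full(n_new, provenance, dtype=object)]
            ),
            ids=self.ids + [f"{id_prefix}_{i + 1}" for i in range(n_new)],
            feature_names=list(self.feature_names),
        )

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame.insert(0, "id", self.ids)
        frame["label"] = self.labels
        frame["provenance"] = self.provenance
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledDataset":
        feature_cols = [
            c for c in frame.columns if c not in ("id", "label", "provenance")
        ]
        provenance = (
            frame["provenance"].to_numpy(dtype=object)
            if "provenance" in frame
            else np.full(len(frame), "real", dtype=object)
        )
        ids = (
            [str(v) for v in frame["id"]]
            if "id" in frame
            else []
        )
        return cls(
            features=frame[feature_cols].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(dtype=int),
            provenance=provenance,
            ids=ids,
            feature_names=feature_cols,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path))
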