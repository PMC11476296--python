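"""Splitting, cross-validation, the eight-classifier harness, and prediction.

The evaluation protocol holds out 20% of the data as an independent test
set, runs stratified 10-fold cross-validation on the remaining 80%, and
reports the full metric bundle per algorithm.  Two leakage regimes are
provided: ``leaky`` augments the whole dataset before splitting (synthetic
neighbours of test points can then reach the training side, inflating
metrics), while ``safe`` splits first and augments only inside training
folds.  Both are first-class and labelled in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .augment import GANConfig, SmoteConfig, balance_with_gan, smote_oversample
from .dataset import LabeledDataset
from .metrics import MetricReport, compute_metrics, confusion, roc_auc
from .pseaac import PseAACParams, featurize_dataset
from .seqio import ProteinRecord

AUGMENTATIONS = ("none", "smote", "gan")


@dataclass(frozen=True)
class SplitSpec:
    """80/20 independent split; ties go to the training side.

    ``leakage_mode``: ``leaky`` = augment-then-split, ``safe`` =
    split-then-augment-train-only.
    """

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    leakage_mode: str = "leaky"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.leakage_mode not in ("leaky", "safe"):
            raise ValueError("leakage_mode must be leaky or safe")


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm from the registry plus optional hyperparameter overrides.

    Hyperparameters default to the backend's defaults and are echoed into
    reports; ``seed`` feeds every stochastic backend.
    """

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm.upper() not in MODEL_REGISTRY:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {sorted(MODEL_REGISTRY)}"
            )

    def build(self):
        return MODEL_REGISTRY[self.algorithm.upper()](self.seed, self.hyperparameters)


def _lightgbm(seed: int, overrides: dict):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=seed, verbosity=-1, **overrides)


def _xgboost(seed: int, overrides: dict):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=seed, **overrides)


MODEL_REGISTRY: dict[str, Callable] = {
    "LIGHTGBM": _lightgbm,
    "MLP": lambda seed, kw: MLPClassifier(random_state=seed, **kw),
    "RF": lambda seed, kw: RandomForestClassifier(random_state=seed, **kw),
    "XGBOOST": _xgboost,
    "KNN": lambda seed, kw: KNeighborsClassifier(**kw),
    "LR": lambda seed, kw: LogisticRegression(random_state=seed, **kw),
    "NB": lambda seed, kw: GaussianNB(**kw),
    "RBF-SVM": lambda seed, kw: SVC(
        kernel="rbf", probability=True, random_state=seed, **kw
    ),
}


@dataclass
class TrainedModel:
    """Fitted classifier with its decision threshold (default 0.5)."""

    estimator: object
    algorithm: str
    threshold: float = 0.5
    n_features: int = 0

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Probability-like score in [0, 1] for the positive class.

        Uses the backend's predict_proba where available, otherwise
        min-max-scaled decision values.
        """
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {features.shape}"
            )
        if np.isnan(features).any():
            raise ValueError("features contain NaN")
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(features)[:, 1]
        raw = self.estimator.decision_function(features)
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)


@dataclass(frozen=True)
class PredictionResult:
    label: str  # YES | NO
    score: float


@dataclass
class CVReport:
    """Per-fold metric reports plus their unweighted mean."""

    folds: list[MetricReport]
    summary: dict


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint train/test split with ``ceil(train_fraction * n)`` training
    rows, stratified by label when requested."""
    n = len(dataset)
    if n < 10:
        raise ValueError("split requires at least 10 rows")
    n_train = int(np.ceil(spec.train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=n_train,
        random_state=spec.seed,
        shuffle=True,
        stratify=dataset.labels if spec.stratified else None,
    )
    train, test = dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))
    if spec.stratified:
        for side, name in ((train, "train"), (test, "test")):
            if len(np.unique(side.labels)) < 2:
                raise ValueError(f"a class is absent from the {name} split")
    return train, test


def _evaluate(model: TrainedModel, data: LabeledDataset) -> MetricReport:
    scores = model.scores(data.features)
    y_pred = (scores >= model.threshold).astype(int)
    report = compute_metrics(confusion(data.labels, y_pred))
    if len(np.unique(data.labels)) == 2:
        report.auc, _ = roc_auc(scores, data.labels)
    return report


def train_model(train: LabeledDataset, model_spec: ModelSpec) -> TrainedModel:
    """Fit one registry algorithm on a training dataset."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    estimator = model_spec.build()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimator.fit(train.features, train.labels)
    except Exception as exc:  # surface the algorithm id with backend failures
        raise RuntimeError(f"{model_spec.algorithm}: {exc}") from exc
    return TrainedModel(
        estimator=estimator,
        algorithm=model_spec.algorithm.upper(),
        n_features=train.n_features,
    )


def predict(model: TrainedModel, features: np.ndarray) -> list[PredictionResult]:
    """YES/NO call per row; YES iff score >= threshold (ties go to YES)."""
    scores = model.scores(np.asarray(features, dtype=float))
    return [
        PredictionResult(label="YES" if s >= model.threshold else "NO", score=float(s))
        for s in scores
    ]


def make_folds(
    train: LabeledDataset,
    n_folds: int = 10,
    seed: int = 0,
    fold_transform: Callable[[LabeledDataset], LabeledDataset] | None = None,
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Stratified folds as (fit, held-out) dataset pairs.

    ``fold_transform`` (e.g. a balancer, for leakage-safe augmentation) is
    applied to the fit side only.
    """
    counts = train.class_counts()
    if min(counts.values()) < n_folds:
        raise ValueError(f"need >= {n_folds} rows per class for {n_folds}-fold CV")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pairs = []
    for fit_idx, val_idx in splitter.split(train.features, train.labels):
        fit = train.subset(fit_idx)
        if fold_transform is not None:
            fit = fold_transform(fit)
        pairs.append((fit, train.subset(val_idx)))
    return pairs


def evaluate_folds(
    fold_pairs: Sequence[tuple[LabeledDataset, LabeledDataset]],
    model_spec: ModelSpec,
) -> CVReport:
    reports = []
    for fit, val in fold_pairs:
        if len(np.unique(val.labels)) < 2:
            raise ValueError("a CV fold lacks one of the classes")
        reports.append(_evaluate(train_model(fit, model_spec), val))
    keys = ("acc", "recall", "precision", "f1", "kappa", "mcc", "auc", "fpr")
    summary = {
        key: float(np.mean([getattr(r, key) for r in reports])) for key in keys
    }
    return CVReport(folds=reports, summary=summary)


def cross_validate(
    train: LabeledDataset,
    model_spec: ModelSpec,
    folds: int = 10,
    seed: int = 0,
    fold_transform: Callable[[LabeledDataset], LabeledDataset] | None = None,
) -> CVReport:
    """Stratified k-fold CV; the summary is the unweighted fold mean."""
    return evaluate_folds(make_folds(train, folds, seed, fold_transform), model_spec)


def _balancer(
    method: str, smote_config: SmoteConfig, gan_config: GANConfig | None
) -> Callable[[LabeledDataset], LabeledDataset]:
    if method == "none":
        return lambda ds: ds
    if method == "smote":
        return lambda ds: smote_oversample(ds, smote_config)
    if method == "gan":

        def balance(ds: LabeledDataset) -> LabeledDataset:
            config = gan_config or GANConfig(out_dim=ds.n_features)
            if config.out_dim != ds.n_features:
                config = replace(config, out_dim=ds.n_features)
            return balance_with_gan(ds, config)[0]

        return balance
    raise ValueError(f"unknown augmentation {method!r}")


def run_experiment(
    records: Sequence[ProteinRecord],
    augmentations: Sequence[str] = AUGMENTATIONS,
    model_specs: Sequence[ModelSpec] | None = None,
    split_spec: SplitSpec | None = None,
    pseaac_params: PseAACParams | None = None,
    smote_config: SmoteConfig | None = None,
    gan_config: GANConfig | None = None,
    cv_folds: int = 10,
) -> dict:
    """Full harness: featurize, balance, split, cross-validate, test.

    Returns a JSON-ready report with one block per (augmentation,
    algorithm): the CV summary over ``cv_folds`` stratified folds and the
    independent-test metrics, plus a full config echo.  In ``leaky`` mode
    each augmentation is applied to the whole dataset before the split; in
    ``safe`` mode the split comes first and balancing happens inside
    training folds (and on the final training set) only.
    """
    split_spec = split_spec or SplitSpec()
    pseaac_params = pseaac_params or PseAACParams()
    smote_config = smote_config or SmoteConfig(seed=split_spec.seed)
    if model_specs is None:
        model_specs = [
            ModelSpec(name, seed=split_spec.seed) for name in MODEL_REGISTRY
        ]
    dataset, skips = featurize_dataset(records, pseaac_params)
    report: dict = {
        "config": {
            "leakage_mode": split_spec.leakage_mode,
            "train_fraction": split_spec.train_fraction,
            "stratified": split_spec.stratified,
            "seed": split_spec.seed,
            "cv_folds": cv_folds,
            "lambda": pseaac_params.lam,
            "weight": pseaac_params.weight,
            "smote_k_neighbors": smote_config.k_neighbors,
            "gan": vars(gan_config) if gan_config is not None else "default",
            "algorithms": [m.algorithm.upper() for m in model_specs],
            "n_records": len(records),
            "n_skipped": len(skips),
        },
        "results": {},
    }
    for method in augmentations:
        balance = _balancer(method, smote_config, gan_config)
        if split_spec.leakage_mode == "leaky":
            train, test = split_dataset(balance(dataset), split_spec)
            fold_pairs = make_folds(train, cv_folds, split_spec.seed)
            final_train = train
        else:
            train, test = split_dataset(dataset, split_spec)
            fold_pairs = make_folds(
                train, cv_folds, split_spec.seed, fold_transform=balance
            )
            final_train = balance(train)
        block: dict = {}
        for spec in model_specs:
            cv = evaluate_folds(fold_pairs, spec)
            model = train_model(final_train, spec)
            block[spec.algorithm.upper()] = {
                "cv": cv.summary,
                "cv_folds": [r.to_dict() for r in cv.folds],
                "test": _evaluate(model, test).to_dict(),
            }
        report["results"][method] = block
    return report


def report_to_frame(report: dict):
    """Flatten an experiment report to one row per (augmentation, algorithm,
    phase) for CSV export."""
    import pandas as pd

    rows = []
    for method, block in report["results"].items():
        for algorithm, entry in block.items():
            for phase in ("cv", "test"):
                row = {
                    "leakage_mode": report["config"]["leakage_mode"],
                    "augmentation": method,
                    "algorithm": algorithm,
                    "phase": phase,
                }
                row.update(
                    {k: v for k, v in entry[phase].items() if k != "flags"}
                )
                rows.append(row)
    return pd.DataFrame(rows)
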