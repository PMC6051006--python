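"""Linear-SVM screening of encephalopathy vs normal from band energies.

The published protocol holds 100 epochs per group out for training and tests
on the remainder; the positive class is encephalopathy throughout, so
sensitivity is the detected fraction of encephalopathy test epochs.  A test
score of exactly zero on the decision boundary counts as positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .epoch import BANDS
from .errors import InvalidInputError
from .features import validate_feature_table

__all__ = [
    "SplitSpec",
    "ConfusionMatrix",
    "PerformanceMetrics",
    "DEFAULT_SUBSETS",
    "split",
    "train_linear_svm",
    "evaluate",
    "run_feature_set_comparison",
]

logger = logging.getLogger(__name__)

POSITIVE_GROUP = "encephalopathy"
NEGATIVE_GROUP = "normal"

#: The four published feature subsets.
DEFAULT_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("delta", "theta", "alpha", "beta"),
    "delta": ("delta",),
    "alpha": ("alpha",),
    "beta": ("beta",),
}


@dataclass(frozen=True)
class SplitSpec:
    """Seeded per-group train/test split (train counts fixed per group)."""

    n_train_per_group: dict[str, int] = field(
        default_factory=lambda: {POSITIVE_GROUP: 100, NEGATIVE_GROUP: 100}
    )
    seed: int = 0


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity/specificity/accuracy in percent."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "PerformanceMetrics":
        if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0 or cm.total == 0:
            raise InvalidInputError("metrics undefined: empty class in test set")
        return cls(
            sensitivity_pct=100.0 * cm.tp / (cm.tp + cm.fn),
            specificity_pct=100.0 * cm.tn / (cm.tn + cm.fp),
            accuracy_pct=100.0 * (cm.tp + cm.tn) / cm.total,
        )


def split(
    features: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform without-replacement split, per group."""
    validate_feature_table(features)
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    for group in sorted(spec.n_train_per_group):
        n_train = spec.n_train_per_group[group]
        idx = features.index[features["group"] == group].to_numpy()
        if idx.size < n_train:
            raise InvalidInputError(
                f"group {group!r} has {idx.size} epochs, needs >= {n_train} for training"
            )
        if idx.size == n_train:
            warnings.warn(
                f"group {group!r}: all epochs used for training, empty test set",
                stacklevel=2,
            )
        train_idx.append(rng.choice(idx, size=n_train, replace=False))
    chosen = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    train = features.loc[np.sort(chosen)]
    test = features.drop(index=chosen).sort_index()
    return train, test


def _design(table: pd.DataFrame, feature_subset: tuple[str, ...]) -> np.ndarray:
    bad = set(feature_subset) - set(BANDS)
    if bad or not feature_subset:
        raise InvalidInputError(f"feature subset must be nonempty, from {BANDS}")
    return table[[f"{b}_pct" for b in feature_subset]].to_numpy()


def train_linear_svm(
    train: pd.DataFrame, feature_subset: tuple[str, ...], c: float = 1.0
) -> SVC:
    """Soft-margin linear SVM on the selected band columns (no scaling)."""
    labels = (train["group"] == POSITIVE_GROUP).to_numpy(dtype=int)
    if labels.min() == labels.max():
        raise InvalidInputError("training set must contain both classes")
    model = SVC(kernel="linear", C=c)
    model.fit(_design(train, feature_subset), labels)
    # remember the columns the model was fitted on
    model.feature_subset_ = tuple(feature_subset)
    return model


def evaluate(model: SVC, test: pd.DataFrame) -> tuple[ConfusionMatrix, PerformanceMetrics]:
    """Confusion counts and metrics with encephalopathy as positive class."""
    if len(test) == 0:
        raise InvalidInputError("test table is empty")
    if test["group"].isna().any() or (test["group"] == "unknown").any():
        raise InvalidInputError("test table contains unlabeled rows")
    scores = model.decision_function(_design(test, model.feature_subset_))
    predicted = scores >= 0.0  # boundary ties count as positive
    actual = (test["group"] == POSITIVE_GROUP).to_numpy()
    cm = ConfusionMatrix(
        tp=int(np.sum(predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
    )
    return cm, PerformanceMetrics.from_confusion(cm)


def run_feature_set_comparison(
    features: pd.DataFrame,
    spec: SplitSpec,
    subsets: dict[str, tuple[str, ...]] | None = None,
    c: float = 1.0,
) -> pd.DataFrame:
    """Train/evaluate one model per feature subset on a shared split."""
    if subsets is None:
        subsets = DEFAULT_SUBSETS
    train, test = split(features, spec)
    rows = []
    for name, subset in subsets.items():
        model = train_linear_svm(train, subset, c=c)
        cm, metrics = evaluate(model, test)
        rows.append(
            {
                "subset": name,
                "TP": cm.tp,
                "TN": cm.tn,
                "FP": cm.fp,
                "FN": cm.fn,
                "sensitivity_pct": metrics.sensitivity_pct,
                "specificity_pct": metrics.specificity_pct,
                "accuracy_pct": metrics.accuracy_pct,
            }
        )
    return pd.DataFrame(rows)
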