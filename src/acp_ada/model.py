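"""Classifiers: the boosted-random-forest predictor plus comparison models.

The main predictor is AdaBoost with a Random Forest base learner at the
benchmark hyperparameters (learning rate 0.04, 406 boosting rounds, seed
121; base forest: 300 trees, min_samples_split 10, min_samples_leaf 1,
sqrt feature subsampling, no bootstrap, seed 120). Six standard
classifiers (MLP, SVM, RF, KN, ET, GB) are exposed behind the same
interface for the with/without-augmentation comparison; they run at
library defaults with a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .encoders import FeatureMatrix

CLASSIFIER_NAMES = ("ADA", "RF", "ET", "GB", "MLP", "SVM", "KN")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the boosted predictor and the comparison zoo."""

    classifier: str = "ADA"
    learning_rate: float = 0.04
    n_estimators_boost: int = 406
    seed_boost: int = 121
    rf_n_estimators: int = 300
    rf_min_samples_split: int = 10
    rf_min_samples_leaf: int = 1
    rf_max_features: str = "sqrt"
    rf_bootstrap: bool = False
    seed_base: int = 120

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_NAMES:
            raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_estimators_boost < 1 or self.rf_n_estimators < 1:
            raise ValueError("estimator counts must be >= 1")


def build_estimator(config: ModelConfig):
    """Instantiate the scikit-learn estimator for *config*."""
    if config.classifier == "ADA":
        base = RandomForestClassifier(
            n_estimators=config.rf_n_estimators,
            min_samples_split=config.rf_min_samples_split,
            min_samples_leaf=config.rf_min_samples_leaf,
            max_features=config.rf_max_features,
            bootstrap=config.rf_bootstrap,
            random_state=config.seed_base,
        )
        return AdaBoostClassifier(
            estimator=base,
            n_estimators=config.n_estimators_boost,
            learning_rate=config.learning_rate,
            random_state=config.seed_boost,
        )
    seed = config.seed_boost
    zoo = {
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "ET": lambda: ExtraTreesClassifier(random_state=seed),
        "GB": lambda: GradientBoostingClassifier(random_state=seed),
        "MLP": lambda: MLPClassifier(random_state=seed, max_iter=500),
        "SVM": lambda: SVC(probability=True, random_state=seed),
        "KN": lambda: KNeighborsClassifier(),
    }
    return zoo[config.classifier]()


@dataclass
class FittedModel:
    """A trained classifier plus the metadata needed to validate inputs
    at prediction time."""

    estimator: object
    config: ModelConfig
    n_features_in: int
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    selection_fingerprint: str = ""


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.X
    return np.asarray(features, dtype=float)


def train(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: ModelConfig = ModelConfig(),
    selection_fingerprint: str = "",
) -> FittedModel:
    """Fit the configured classifier; deterministic given the config seeds."""
    X = _as_array(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    est = build_estimator(config)
    est.fit(X, y)
    blocks = dict(features.blocks) if isinstance(features, FeatureMatrix) else {}
    return FittedModel(est, config, X.shape[1], blocks, selection_fingerprint)


def predict(
    model: FittedModel,
    features: FeatureMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and per-class probabilities (columns: class 0, class 1;
    rows sum to 1)."""
    X = _as_array(features)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"the model was trained on {model.n_features_in} "
            f"(encoder blocks {model.blocks or 'unknown'})"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty((0, 2))
    labels = model.estimator.predict(X).astype(int)
    proba = model.estimator.predict_proba(X)
    return labels, proba


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist the fitted estimator (joblib) plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "config": asdict(model.config),
        "n_features_in": model.n_features_in,
        "blocks": {k: list(v) for k, v in model.blocks.items()},
        "selection_fingerprint": model.selection_fingerprint,
        "sklearn_version": sklearn.__version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> FittedModel:
    return joblib.load(path)


__all__ = ["ModelConfig", "FittedModel", "CLASSIFIER_NAMES",
           "build_estimator", "train", "predict", "save_model", "load_model"]
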