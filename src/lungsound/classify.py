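"""Three-class SVM mapping feature vectors to crackle / wheeze / normal.

A one-vs-rest RBF support vector machine on standardized wavelet-packet
features. Classification is single-label and three-class: recordings
with mixed findings are excluded upstream, and ``indeterminate`` is a
human-rater-only value that the classifier never emits (and refuses in
training labels). Class imbalance is handled with inverse-frequency
class weights.

An optional hybrid mode appends the rule-based detector's crackle and
wheeze event counts as two extra features; it is off by default so the
default feature contract stays purely spectral.
"""

from __future__ import annotations

import dataclasses
import hashlib

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector

CLASS_ORDER = ("crackle", "wheeze", "normal")
VALID_LABELS = frozenset(CLASS_ORDER)

_BUNDLE_VERSION = 1


@dataclasses.dataclass
class Hyperparams:
    C: float = 1.0
    gamma: str | float = "auto"  # "auto" = 1 / n_features
    kernel: str = "rbf"


@dataclasses.dataclass
class ModelBundle:
    """Trained decision machinery plus the metadata needed to refuse misuse."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    class_order: tuple[str, ...]
    seed: int
    hyperparams: Hyperparams
    corpus_fingerprint: str
    version: int = _BUNDLE_VERSION


def corpus_fingerprint(labels: dict[str, str]) -> str:
    """Order-independent SHA-256 fingerprint of a labelled corpus."""
    h = hashlib.sha256()
    for rec_id in sorted(labels):
        h.update(f"{rec_id}\t{labels[rec_id]}\n".encode())
    return h.hexdigest()


def _design_matrix(
    features: list[FeatureVector], names: tuple[str, ...]
) -> np.ndarray:
    for fv in features:
        if fv.feature_names != names:
            raise ValueError(
                f"feature names for {fv.recording_id!r} do not match the "
                "training feature contract"
            )
    return np.vstack([fv.values for fv in features])


def train(
    features: list[FeatureVector],
    labels: dict[str, str],
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Fit the three-class SVM. Deterministic given the seed.

    Raises ``ValueError`` when any label is missing or outside
    {crackle, wheeze, normal}, or when fewer than two classes are present.
    """
    hp = hyperparams or Hyperparams()
    if not features:
        raise ValueError("no feature vectors supplied")
    y = []
    for fv in features:
        if fv.recording_id not in labels:
            raise ValueError(f"no label for recording {fv.recording_id!r}")
        label = labels[fv.recording_id]
        if label not in VALID_LABELS:
            raise ValueError(
                f"label {label!r} for {fv.recording_id!r} is not a classifier "
                f"class (expected one of {sorted(VALID_LABELS)})"
            )
        y.append(label)
    if len(set(y)) < 2:
        raise ValueError("training requires at least two classes")

    names = features[0].feature_names
    X = _design_matrix(features, names)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", OneVsRestClassifier(
            SVC(C=hp.C, gamma=hp.gamma, kernel=hp.kernel,
                class_weight="balanced", random_state=seed)
        )),
    ])
    pipe.fit(X, np.asarray(y))
    return ModelBundle(
        pipeline=pipe,
        feature_names=names,
        class_order=CLASS_ORDER,
        seed=seed,
        hyperparams=hp,
        corpus_fingerprint=corpus_fingerprint(
            {fv.recording_id: lab for fv, lab in zip(features, y)}
        ),
    )


def predict(model: ModelBundle, features: FeatureVector) -> str:
    """Predict one of {crackle, wheeze, normal} for a single recording."""
    X = _design_matrix([features], model.feature_names)
    return str(model.pipeline.predict(X)[0])


def predict_many(model: ModelBundle, features: list[FeatureVector]) -> dict[str, str]:
    if not features:
        return {}
    X = _design_matrix(features, model.feature_names)
    pred = model.pipeline.predict(X)
    return {fv.recording_id: str(p) for fv, p in zip(features, pred)}


def save_model(path, model: ModelBundle) -> None:
    joblib.dump({"format": "lungsound-model", "version": model.version,
                 "bundle": model}, path)


def load_model(path) -> ModelBundle:
    """Load a saved model, refusing truncated files or version mismatches."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "lungsound-model":
        raise ValueError(f"{path} is not a lungsound model bundle")
    if payload.get("version") != _BUNDLE_VERSION:
        raise ValueError(
            f"model version {payload.get('version')} does not match "
            f"supported version {_BUNDLE_VERSION}"
        )
    return payload["bundle"]


def cross_validate(
    features: list[FeatureVector],
    labels: dict[str, str],
    n_folds: int = 5,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> tuple[float, dict[str, str]]:
    """Stratified k-fold cross-validation of the full train/predict cycle.

    Returns (accuracy, out-of-fold predictions by recording_id).
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray([labels[fv.recording_id] for fv in features])
    _, class_counts = np.unique(y, return_counts=True)
    folds = int(min(n_folds, class_counts.min()))
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 members per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    predictions: dict[str, str] = {}
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        fold_model = train([features[i] for i in train_idx],
                           labels, hyperparams, seed=seed)
        predictions.update(
            predict_many(fold_model, [features[i] for i in test_idx])
        )
    correct = sum(predictions[fv.recording_id] == labels[fv.recording_id]
                  for fv in features)
    return correct / len(features), predictions
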