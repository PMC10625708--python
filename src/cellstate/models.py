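"""Base learners and the weighted soft-voting ensemble.

Four base-learner families — an RBF-kernel SVM with probability calibration,
a random forest, and two gradient-boosted tree implementations (XGBoost and
LightGBM) — are fitted independently on the same restricted gene subset and
combined by weighted averaging of their class-probability outputs (soft
voting).  The default weights are uniform (1, 1, 1, 1).

All learner hyperparameters are the library defaults plus an explicit seed
and single-threaded execution, so runs are reproducible; any default can be
overridden through ``BaseLearnerSpec.hyperparameters``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np

from .io import ExpressionMatrix, LabeledDataset, Layer

FAMILIES = ("svm", "random_forest", "xgboost", "lightgbm")
MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Unreadable or incompatible saved-model file."""


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner: a family name, a seed, and hyperparameter overrides."""

    family: str
    seed: int = 0
    hyperparameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


def default_specs(seed: int = 0) -> tuple[BaseLearnerSpec, ...]:
    """The four default base learners, in canonical family order."""
    return tuple(BaseLearnerSpec(f, seed=seed) for f in FAMILIES)


def build_estimator(spec: BaseLearnerSpec):
    """Instantiate the scikit-learn-compatible estimator for a spec."""
    params = dict(spec.hyperparameters)
    if spec.family == "svm":
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.svm import SVC

        # Platt-calibrated so the SVM can take part in soft voting
        svc = SVC(kernel="rbf", random_state=spec.seed, cache_size=500, **params)
        return CalibratedClassifierCV(svc, ensemble=False)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, verbosity=0, tree_method="hist", **params
        )
    if spec.family == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=spec.seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown family {spec.family!r}")


def _aligned_proba(estimator, X: np.ndarray, n_classes: int) -> np.ndarray:
    """predict_proba with columns aligned to integer classes 0..C-1."""
    proba = estimator.predict_proba(X)
    classes = np.asarray(estimator.classes_, dtype=np.int64)
    out = np.zeros((X.shape[0], n_classes))
    out[:, classes] = proba
    return out


@dataclass
class EnsembleModel:
    """Four fitted members, their voting weights, and the training gene subset."""

    members: tuple
    specs: tuple[BaseLearnerSpec, ...]
    weights: np.ndarray
    gene_subset: tuple[str, ...]
    class_names: tuple[str, ...]

    def member_proba(self, cells: ExpressionMatrix) -> list[np.ndarray]:
        X = self._restrict(cells)
        return [_aligned_proba(m, X, len(self.class_names)) for m in self.members]

    def _restrict(self, cells: ExpressionMatrix) -> np.ndarray:
        if cells.layer != Layer.LOG2P1:
            raise ValueError("prediction expects the normalized (log2p1) layer")
        return cells.values[:, cells.gene_index(self.gene_subset)]


def _validate_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (len(FAMILIES),):
        raise ValueError(f"need exactly {len(FAMILIES)} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("at least one weight must be positive")
    return w


def fit_ensemble(
    train: LabeledDataset,
    gene_subset: Sequence[str],
    specs: Sequence[BaseLearnerSpec] | None = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
) -> EnsembleModel:
    """Fit all four members on the same (cells x gene_subset) training data."""
    if train.matrix.layer != Layer.LOG2P1:
        raise ValueError("fit_ensemble expects the normalized (log2p1) layer")
    specs = tuple(specs) if specs is not None else default_specs()
    if len(specs) != len(FAMILIES):
        raise ValueError(f"need exactly {len(FAMILIES)} learner specs")
    w = _validate_weights(weights)
    idx = train.matrix.gene_index(gene_subset)  # raises naming unknown genes
    X = train.matrix.values[:, idx]
    y = train.label_codes()
    if len(np.unique(y)) != train.n_classes:
        raise ValueError("training data must contain every class in class_names")
    members = []
    for spec in specs:
        est = build_estimator(spec)
        est.fit(X, y)
        members.append(est)
    return EnsembleModel(
        members=tuple(members),
        specs=specs,
        weights=w,
        gene_subset=tuple(gene_subset),
        class_names=train.class_names,
    )


def predict_proba(model: EnsembleModel, cells: ExpressionMatrix) -> np.ndarray:
    """Row-wise weighted mean of member probabilities, renormalized to sum 1."""
    probas = model.member_proba(cells)
    w = model.weights
    combined = sum(wi * p for wi, p in zip(w, probas)) / w.sum()
    return combined / combined.sum(axis=1, keepdims=True)


def predict(model: EnsembleModel, cells: ExpressionMatrix) -> tuple[str, ...]:
    """Arg-max class per cell; ties resolve to the earliest class in class_names."""
    proba = predict_proba(model, cells)
    codes = np.argmax(proba, axis=1)  # first maximum wins
    return tuple(model.class_names[c] for c in codes)


def save_model(model: EnsembleModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "members": model.members,
        "specs": model.specs,
        "weights": model.weights,
        "gene_subset": model.gene_subset,
        "class_names": model.class_names,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EnsembleModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # unreadable / truncated / not a joblib archive
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a saved ensemble model")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {payload['format_version']} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return EnsembleModel(
        members=payload["members"],
        specs=payload["specs"],
        weights=np.asarray(payload["weights"]),
        gene_subset=tuple(payload["gene_subset"]),
        class_names=tuple(payload["class_names"]),
    )
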