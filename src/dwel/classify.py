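"""Random-forest leaf/wood classification, cross-validation and importances.

Three attribute sets are supported, mirroring the three classification types
the method compares: ``spectral`` (rho_nir, rho_swir, ndi), ``spatial``
(pc1/pc2 eigenvalue proportions at 16 scales) and ``spectral_spatial``
(both). Training labels are restricted to leaf and wood; ground is separated
by the ground filter upstream, not learned.

Accuracy reporting follows remote-sensing convention: the confusion matrix
has reference classes on rows and predictions on columns; producer's
accuracy is per-class recall (1 - omission error) and user's accuracy is
per-class precision (1 - commission error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import feature_columns

TRAIN_LABELS = ("leaf", "wood")

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestSettings:
    """Random-forest hyperparameters (defaults: 500 trees, sqrt feature
    subsampling per split, unbounded depth)."""

    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    n_jobs: int = 1


@dataclass
class ForestModel:
    """A trained forest bound to its attribute set and feature columns."""

    forest: RandomForestClassifier
    attribute_set: str
    feature_names: list[str]
    settings: ForestSettings = field(default_factory=ForestSettings)
    seed: int | None = None

    @property
    def importances(self) -> pd.Series:
        """Mean-impurity-decrease feature importances (sum to 1)."""
        return pd.Series(self.forest.feature_importances_,
                         index=self.feature_names)


def _feature_matrix(samples: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in samples.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {missing}")
    return samples[names].to_numpy(dtype=float)


def train(samples: pd.DataFrame, labels, attribute_set: str,
          settings: ForestSettings | None = None, seed: int = 0,
          scales=None, include_pc3: bool = False) -> ForestModel:
    """Train a random forest on the chosen attribute set.

    ``samples`` is a feature table from :func:`dwel.features.multiscale_features`
    (or any frame carrying the required columns); ``labels`` the per-row
    leaf/wood labels. Training is reproducible given ``seed``. Undefined-NDI
    sentinels (NaN) are handled by the forest's native missing-value
    support, so such points are effectively routed by their remaining
    attributes.
    """
    if settings is None:
        settings = ForestSettings()
    y = np.asarray(labels)
    present = set(np.unique(y))
    if not present <= set(TRAIN_LABELS):
        raise ValueError(f"labels must be in {TRAIN_LABELS}, got {sorted(present)}")
    if len(present) < 2:
        raise ValueError("training requires both leaf and wood samples")
    names = feature_columns(attribute_set, scales, include_pc3)
    X = _feature_matrix(samples, names)
    rf = RandomForestClassifier(
        n_estimators=settings.n_estimators, max_features=settings.max_features,
        max_depth=settings.max_depth, n_jobs=settings.n_jobs,
        random_state=seed)
    rf.fit(X, y)
    return ForestModel(rf, attribute_set, names, settings, seed)


def predict(model: ForestModel, samples: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and assigned-class probabilities for a feature table.

    Deterministic for a fixed model. Raises if the table lacks the model's
    feature columns (the error names them).
    """
    X = _feature_matrix(samples, model.feature_names)
    proba = model.forest.predict_proba(X)
    idx = np.argmax(proba, axis=1)
    labels = model.forest.classes_[idx]
    return labels, proba[np.arange(len(idx)), idx]


def predict_proba(model: ForestModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-class probability table (columns = class labels)."""
    X = _feature_matrix(samples, model.feature_names)
    return pd.DataFrame(model.forest.predict_proba(X),
                        columns=model.forest.classes_, index=samples.index)


# ---------------------------------------------------------------------------
# Accuracy assessment
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Confusion matrix (reference rows x prediction columns) with overall,
    producer's and user's accuracies. Metrics of a class with an empty
    reference row / prediction column are NaN."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    overall: float
    producers: dict[str, float]
    users: dict[str, float]
    n_train: int = 0
    n_test: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"overall accuracy: {self.overall:.4f} "
                 f"(train n={self.n_train}, test n={self.n_test})"]
        for c in self.classes:
            lines.append(f"  {c:6s} producer's {self.producers[c]:.4f}  "
                         f"user's {self.users[c]:.4f}")
        return "\n".join(lines)


def accuracy_metrics(confusion, classes: tuple[str, ...] = TRAIN_LABELS
                     ) -> AccuracyReport:
    """Accuracy report from a square count matrix (reference rows)."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain counts")
    overall = float(np.trace(cm) / total)
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prod = np.where(rows > 0, np.diag(cm) / np.where(rows > 0, rows, 1), np.nan)
        user = np.where(cols > 0, np.diag(cm) / np.where(cols > 0, cols, 1), np.nan)
    return AccuracyReport(tuple(classes), cm.astype(np.int64), overall,
                          dict(zip(classes, prod.astype(float))),
                          dict(zip(classes, user.astype(float))))


def confusion_matrix(reference, predicted,
                     classes: tuple[str, ...] = TRAIN_LABELS) -> np.ndarray:
    """Count matrix with reference on rows, predictions on columns."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            cm[i, j] = int(np.sum((ref == ci) & (pred == cj)))
    return cm


def stratified_split(labels, train_fraction: float = 0.75, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (train, test) positional index split."""
    y = np.asarray(labels)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_fraction, stratify=y,
                              random_state=seed)
    return np.sort(tr), np.sort(te)


def cross_validate(samples: pd.DataFrame, labels, attribute_set: str,
                   train_fraction: float = 0.75, stratified: bool = True,
                   settings: ForestSettings | None = None, seed: int = 0,
                   scales=None, include_pc3: bool = False) -> AccuracyReport:
    """Hold-out cross-validation: train on a stratified 75% of the labelled
    samples, report accuracies on the remaining 25%."""
    y = np.asarray(labels)
    for c in TRAIN_LABELS:
        if np.sum(y == c) < 4:
            raise ValueError(f"class {c!r} needs >= 4 samples for a "
                             f"{train_fraction:.0%} stratified split")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_fraction,
                              stratify=y if stratified else None,
                              random_state=seed)
    model = train(samples.iloc[tr], y[tr], attribute_set, settings, seed,
                  scales, include_pc3)
    pred, _ = predict(model, samples.iloc[te])
    report = accuracy_metrics(confusion_matrix(y[te], pred))
    report.n_train, report.n_test = len(tr), len(te)
    return report


# ---------------------------------------------------------------------------
# Feature-importance summaries across scans
# ---------------------------------------------------------------------------

def fis_summary(models: list[ForestModel]) -> pd.DataFrame:
    """Distribution of feature importance scores across per-scan models.

    One row per feature (in the models' column order): mean, median,
    quartiles, 5th/95th percentiles and the coefficient of variation
    (population standard deviation / mean; 0 where the mean is 0).
    """
    if not models:
        raise ValueError("need at least one model")
    sets = {m.attribute_set for m in models}
    if len(sets) > 1:
        raise ValueError(f"models mix attribute sets: {sorted(sets)}")
    names = models[0].feature_names
    for m in models:
        if m.feature_names != names:
            raise ValueError("models disagree on feature columns")
    imp = np.stack([m.importances.to_numpy() for m in models])  # (scan, feature)
    mean = imp.mean(axis=0)
    std = imp.std(axis=0)  # population convention
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, std / np.where(mean > 0, mean, 1), 0.0)
    q = np.percentile(imp, [5, 25, 50, 75, 95], axis=0)
    return pd.DataFrame({
        "mean": mean, "median": q[2], "q25": q[1], "q75": q[3],
        "p05": q[0], "p95": q[4], "cv": cv,
    }, index=pd.Index(names, name="feature"))


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def save_model(model: ForestModel, path) -> None:
    """Persist a trained model as a self-describing, versioned archive."""
    joblib.dump({
        "format": "dwel-forest-model",
        "format_version": ARCHIVE_FORMAT_VERSION,
        "attribute_set": model.attribute_set,
        "feature_names": model.feature_names,
        "settings": model.settings,
        "seed": model.seed,
        "forest": model.forest,
    }, path)


def load_model(path) -> ForestModel:
    payload = joblib.load(path)
    if payload.get("format") != "dwel-forest-model":
        raise ValueError(f"{path} is not a dwel forest-model archive")
    if payload.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version "
                         f"{payload.get('format_version')}")
    return ForestModel(payload["forest"], payload["attribute_set"],
                       payload["feature_names"], payload["settings"],
                       payload["seed"])
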