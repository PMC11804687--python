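"""Gradient-boosted tree classification of walking speed / jogging windows.

Wraps XGBoost with the study-shaped protocol: participant-grouped six-fold
grid search for hyperparameters, then leave-one-subject-out (LOSO)
cross-validation with the chosen parameters.  All folds are grouped by
participant so no subject ever appears on both sides of a split.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import METADATA_COLUMNS, feature_columns
from .io import CLASSES

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the model schema."""


class ConfigurationError(ValueError):
    """A cross-validation configuration is impossible for the given data."""


#: Hyperparameter grid searched by default (sklearn-style key names).
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100, 300],
    "subsample": [0.8],
    "colsample_bytree": [0.8],
}

#: Fixed parameters used when no grid search is requested.
DEFAULT_PARAMS: dict = {
    "max_depth": 3,
    "learning_rate": 0.3,
    "n_estimators": 100,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
}


@dataclass
class TrainedModel:
    """Fitted ensemble plus everything needed to apply it elsewhere."""

    booster: xgb.XGBClassifier
    params: dict
    feature_schema: list[str]
    classes: list[str]
    train_seed: int

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(out_dir / "model.ubj")
        sidecar = {
            "params": self.params,
            "feature_schema": self.feature_schema,
            "classes": self.classes,
            "train_seed": self.train_seed,
        }
        with open(out_dir / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedModel":
        out_dir = Path(out_dir)
        with open(out_dir / "model.json") as fh:
            sidecar = json.load(fh)
        booster = xgb.XGBClassifier()
        booster._estimator_type = "classifier"
        booster.load_model(out_dir / "model.ubj")
        return cls(booster=booster, **sidecar)


def _new_classifier(params: dict, seed: int) -> xgb.XGBClassifier:
    clf = xgb.XGBClassifier(
        **params, random_state=seed, n_jobs=1, tree_method="hist", verbosity=0
    )
    # xgboost's sklearn wrapper needs this marker for (de)serialization when
    # paired with scikit-learn >= 1.6, which dropped the mixin attribute
    clf._estimator_type = "classifier"
    return clf


def _encode_labels(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    present = [c for c in CLASSES if c in set(labels)]
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    index = {c: i for i, c in enumerate(present)}
    return labels.map(index).to_numpy(), present


def train_model(features: pd.DataFrame, params: dict, seed: int) -> TrainedModel:
    """Fit a multiclass boosted-tree model on a FeatureMatrix.

    Refitting with the same data, params and seed reproduces identical
    predictions (single-threaded, histogram tree method).
    """
    if len(features) == 0:
        raise ValueError("empty feature matrix")
    schema = feature_columns(features)
    y, present = _encode_labels(features["label"])
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = _new_classifier(params, seed)
    clf.fit(features[schema].to_numpy(), y)
    return TrainedModel(booster=clf, params=dict(params), feature_schema=schema,
                        classes=present, train_seed=seed)


def predict(model: TrainedModel, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities for a FeatureMatrix.

    Columns are realigned to the model schema by name.  Returns
    ``(labels, probabilities)`` with probability columns in
    ``model.classes`` order; the arg-max tie-break follows that order.
    """
    have = set(feature_columns(features))
    missing = [c for c in model.feature_schema if c not in have]
    extra = sorted(have - set(model.feature_schema))
    if missing or extra:
        raise SchemaError(f"feature schema mismatch; missing={missing}, "
                          f"extra={extra}")
    proba = model.booster.predict_proba(features[model.feature_schema].to_numpy())
    labels = np.array(model.classes, dtype=object)[np.argmax(proba, axis=1)]
    return labels, proba


def grouped_folds(groups: np.ndarray, n_splits: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic participant-grouped folds (contiguous blocks of the
    sorted unique groups).  Returns (train_idx, val_idx) pairs."""
    uniq = sorted(set(groups))
    if len(uniq) < n_splits:
        raise ConfigurationError(
            f"need at least {n_splits} participants for {n_splits}-fold "
            f"grouped CV, got {len(uniq)}"
        )
    assignment = {g: i % n_splits for i, g in enumerate(uniq)}
    fold_of = np.array([assignment[g] for g in groups])
    out = []
    for f in range(n_splits):
        val = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        out.append((train, val))
    return out


def grid_search_hyperparameters(
    features: pd.DataFrame,
    grid: dict[str, list] | None = None,
    folds: int = 6,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Participant-grouped k-fold grid search maximizing validation accuracy.

    Ties are broken toward the smaller ensemble, then the lower learning
    rate, then grid order.  Returns ``(best_params, cv_table)``.
    """
    grid = DEFAULT_GRID if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("grid must be non-empty")
    keys = list(grid)
    combos = [dict(zip(keys, vals))
              for vals in itertools.product(*(grid[k] for k in keys))]
    groups = features["participant_id"].to_numpy()
    fold_list = grouped_folds(groups, folds)
    schema = feature_columns(features)
    X = features[schema].to_numpy()
    y, _ = _encode_labels(features["label"])
    rows = []
    for idx, combo in enumerate(combos):
        accs = []
        for train, val in fold_list:
            clf = _new_classifier(combo, seed)
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[val]) == y[val])))
        rows.append({**combo, "mean_val_accuracy": float(np.mean(accs)),
                     "fold_accuracies": json.dumps([round(a, 6) for a in accs]),
                     "_order": idx})
        logger.info("grid %d/%d %s -> %.4f", idx + 1, len(combos), combo,
                    rows[-1]["mean_val_accuracy"])
    table = pd.DataFrame(rows)
    best_row = table.sort_values(
        by=["mean_val_accuracy", "n_estimators", "learning_rate", "_order"],
        ascending=[False, True, True, True],
    ).iloc[0]
    best = {k: best_row[k] for k in keys}
    # restore native python types for json round-tripping
    best = {k: (v.item() if hasattr(v, "item") else v) for k, v in best.items()}
    return best, table.drop(columns="_order")


def loso_folds(participants) -> list[tuple[list[str], str]]:
    """LOSO fold plan: (training participants, held-out participant) pairs."""
    uniq = sorted(set(participants))
    if len(uniq) < 2:
        raise ConfigurationError("LOSO needs at least 2 participants")
    return [([p for p in uniq if p != test], test) for test in uniq]


def run_loso(features: pd.DataFrame, params: dict, seed: int) -> pd.DataFrame:
    """Leave-one-subject-out cross-validation.

    One fold per participant; each fold trains on everyone else and
    predicts the held-out subject's windows.  Returns the per-window
    prediction table (metadata + ``true``/``predicted`` labels + one
    probability column per class), covering every input window exactly once.
    """
    plan = loso_folds(features["participant_id"])
    frames = []
    for train_ids, test_id in plan:
        train = features[features["participant_id"] != test_id]
        test = features[features["participant_id"] == test_id]
        model = train_model(train, params, seed)
        labels, proba = predict(model, test)
        out = test[METADATA_COLUMNS].copy()
        out = out.rename(columns={"label": "true"})
        out["predicted"] = labels
        for c in CLASSES:
            if c in model.classes:
                out[f"prob_{c}"] = proba[:, model.classes.index(c)]
            else:
                out[f"prob_{c}"] = 0.0
        frames.append(out)
        logger.info("LOSO fold %s: accuracy %.4f", test_id,
                    float(np.mean(labels == out["true"].to_numpy())))
    return pd.concat(frames, ignore_index=True)
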