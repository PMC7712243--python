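"""Classifier training, tuning and screening.

Three supervised classifiers are supported, each tuned over the grid the
screening study prescribes:

* ``lr`` — L1-penalised logistic regression, C in [0.01, 100] (log grid);
* ``svm`` — RBF-kernel SVM, C in [0.01, 100], gamma in [0.001, 100];
* ``ab`` — AdaBoost over decision stumps, learning rate in [0.01, 1],
  number of estimators 50..1000 in steps of 10.

Model selection uses nested cross-validation: a stratified 15-fold outer
loop estimates generalisation error while a stratified 5-fold inner loop
picks hyperparameters by ROC AUC.  Standardization and feature selection
(correlation-cluster reduction for LR, mutual information for SVM/AdaBoost)
are fitted inside each outer training set only, so no information from the
held-out fold leaks into the fit.  Class imbalance is handled by seeded
undersampling of the majority class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import (
    CohortTable,
    Standardizer,
    apply_standardizer,
    fit_standardizer,
    reduce_by_correlation,
    select_by_mutual_information,
)
from .desat import AT_RISK, HEALTHY, FeatureVector
from .metrics import EvalReport, confusion_from_labels, rates, roc_auc, summarize_folds

__all__ = [
    "ALGORITHMS",
    "default_grid",
    "balance",
    "nested_cv",
    "train_final",
    "screen",
    "evaluate",
    "FittedClassifier",
    "CVResult",
    "MissingFeatureError",
    "save_model",
    "load_model",
]

ALGORITHMS = ("lr", "svm", "ab")

#: printed hyperparameter bounds, per algorithm
GRID_BOUNDS = {
    "lr": {"C": (0.01, 100.0)},
    "svm": {"C": (0.01, 100.0), "gamma": (0.001, 100.0)},
    "ab": {"learning_rate": (0.01, 1.0), "n_estimators": (50, 1000)},
}


class MissingFeatureError(KeyError):
    """A feature required by a fitted classifier is absent from the input."""


def default_grid(
    algorithm: str,
    points_per_decade: int = 5,
    ab_lr_points: int = 10,
    ab_estimator_step: int = 10,
) -> Dict[str, Sequence]:
    """Hyperparameter grid within the prescribed bounds.

    Log grids use ``points_per_decade``; the AdaBoost learning-rate grid is
    linear with ``ab_lr_points`` points and the estimator-count grid steps
    by ``ab_estimator_step`` from 50 to 1000.
    """
    if algorithm == "lr":
        return {"C": np.logspace(-2, 2, 4 * points_per_decade + 1)}
    if algorithm == "svm":
        return {
            "C": np.logspace(-2, 2, 4 * points_per_decade + 1),
            "gamma": np.logspace(-3, 2, 5 * points_per_decade + 1),
        }
    if algorithm == "ab":
        return {
            "learning_rate": np.linspace(0.01, 1.0, ab_lr_points),
            "n_estimators": list(range(50, 1001, ab_estimator_step)),
        }
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _make_estimator(algorithm: str, params: Dict, seed: int):
    if algorithm == "lr":
        return LogisticRegression(
            penalty="l1", solver="liblinear", max_iter=5000,
            random_state=seed, **params,
        )
    if algorithm == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if algorithm == "ab":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            random_state=seed, **{k: v for k, v in params.items()},
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous risk score: posterior probability or SVM margin."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def balance(table: CohortTable, seed: int = 0) -> CohortTable:
    """Undersample the majority class to the minority size (seeded)."""
    y = table.y
    if y is None:
        raise ValueError("balance requires a labeled table")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if n_pos > n_neg:
        pos_idx = np.sort(rng.choice(pos_idx, size=n_neg, replace=False))
    elif n_neg > n_pos:
        neg_idx = np.sort(rng.choice(neg_idx, size=n_pos, replace=False))
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    return table.subset(keep)


def _select_features(
    table: CohortTable, algorithm: str, seed: int, selection: Optional[str]
) -> List[str]:
    """Per-algorithm feature selection: correlation clusters for LR, MI otherwise."""
    mode = selection or ("correlation" if algorithm == "lr" else "mutual_info")
    if mode == "none":
        return list(table.feature_names)
    if mode == "correlation":
        return reduce_by_correlation(table)
    if mode == "mutual_info":
        return select_by_mutual_information(table, seed=seed)
    raise ValueError(f"unknown selection mode {mode!r}")


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    grid: Dict[str, Sequence],
    k_inner: int,
    seed: int,
) -> Dict:
    """Exhaustive grid search maximizing mean inner-CV AUC; first-best ties."""
    inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))
    keys = list(grid)
    best_params, best_auc = None, -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        aucs = []
        for tr, te in splits:
            model = _make_estimator(algorithm, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            auc, _ = roc_auc(_scores(model, X[te]), y[te])
            aucs.append(auc)
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return best_params


@dataclass
class FittedClassifier:
    """A deployable screening model: scaler + feature list + fitted estimator."""

    algorithm: str
    params: Dict
    feature_names: List[str]
    standardizer: Standardizer
    model: object
    seed: int = 0

    def _matrix(self, rows: pd.DataFrame) -> np.ndarray:
        for name in self.feature_names:
            if name not in rows.columns or rows[name].isna().any():
                raise MissingFeatureError(f"feature {name!r} missing from input")
        Z = rows[self.feature_names].copy()
        for name in self.feature_names:
            Z[name] = (Z[name] - self.standardizer.means[name]) / self.standardizer.stds[name]
        return Z.to_numpy(dtype=float)

    def predict(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Risk scores and labels for a feature table."""
        X = self._matrix(rows)
        scores = _scores(self.model, X)
        preds = self.model.predict(X)
        labels = np.where(preds == 1, AT_RISK, HEALTHY)
        return pd.DataFrame({"risk_score": scores, "label": labels}, index=rows.index)


@dataclass
class CVResult:
    """Outcome of one nested cross-validation run."""

    algorithm: str
    fold_reports: List[EvalReport]
    fold_params: List[Dict]
    fold_features: List[List[str]]
    seed: int
    k_outer: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.fold_reports]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))

    def summary(self) -> pd.DataFrame:
        """Across-fold mean ± SD of every KPI (fractions)."""
        return summarize_folds(self.fold_reports)

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "k_outer": self.k_outer,
            "folds": [r.as_dict() for r in self.fold_reports],
            "fold_params": [
                {k: (v.item() if hasattr(v, "item") else v) for k, v in p.items()}
                for p in self.fold_params
            ],
            "fold_features": self.fold_features,
            "summary": {
                stat: {k: float(v) for k, v in row.items()}
                for stat, row in self.summary().iterrows()
            },
        }


def nested_cv(
    table: CohortTable,
    algorithm: str = "lr",
    grid: Optional[Dict[str, Sequence]] = None,
    k_outer: int = 15,
    k_inner: int = 5,
    seed: int = 0,
    selection: Optional[str] = None,
    standardize_scope: str = "fold",
) -> CVResult:
    """Stratified nested cross-validation.

    The outer loop estimates out-of-sample performance; within each outer
    training set the standardizer is fitted, features are selected, and the
    inner loop grid-searches hyperparameters by AUC.  With
    ``standardize_scope="dataset"`` the z-scoring is instead fitted once on
    the full table before splitting (whole-dataset convention).
    """
    y = table.y
    if y is None:
        raise ValueError("nested_cv requires a labeled table")
    if grid is None:
        grid = default_grid(algorithm)
    if standardize_scope not in ("fold", "dataset"):
        raise ValueError("standardize_scope must be 'fold' or 'dataset'")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_outer:
        raise ValueError(
            f"need at least k_outer={k_outer} rows per class, have {counts.tolist()}"
        )
    global_std = fit_standardizer(table) if standardize_scope == "dataset" else None

    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    reports, fold_params, fold_feats = [], [], []
    for tr_idx, te_idx in outer.split(table.X, y):
        train, test = table.subset(tr_idx), table.subset(te_idx)
        std = global_std or fit_standardizer(train)
        train_z, test_z = apply_standardizer(std, train), apply_standardizer(std, test)
        feats = _select_features(train_z, algorithm, seed, selection)
        Xtr = train_z.data[feats].to_numpy(dtype=float)
        Xte = test_z.data[feats].to_numpy(dtype=float)
        ytr, yte = train_z.y, test_z.y

        best = _grid_search(Xtr, ytr, algorithm, grid, k_inner, seed)
        model = _make_estimator(algorithm, best, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        scores = _scores(model, Xte)
        preds = model.predict(Xte)
        report = rates(confusion_from_labels(yte, preds))
        report.auc, report.roc_points = roc_auc(scores, yte)
        reports.append(report)
        fold_params.append(best)
        fold_feats.append(feats)
    return CVResult(algorithm, reports, fold_params, fold_feats, seed, k_outer)


def train_final(
    table: CohortTable,
    algorithm: str = "lr",
    grid: Optional[Dict[str, Sequence]] = None,
    k_inner: int = 5,
    seed: int = 0,
    selection: Optional[str] = None,
) -> FittedClassifier:
    """Grid-search on the full table and fit a deployable classifier."""
    y = table.y
    if y is None or table.n == 0:
        raise ValueError("train_final requires a non-empty labeled table")
    if grid is None:
        grid = default_grid(algorithm)
    std = fit_standardizer(table)
    table_z = apply_standardizer(std, table)
    feats = _select_features(table_z, algorithm, seed, selection)
    X = table_z.data[feats].to_numpy(dtype=float)
    best = _grid_search(X, y, algorithm, grid, k_inner, seed)
    model = _make_estimator(algorithm, best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return FittedClassifier(algorithm, best, feats, std, model, seed)


def screen(classifier: FittedClassifier, features: FeatureVector | dict) -> dict:
    """Classify one subject from its oximetry features."""
    d = features.as_dict() if isinstance(features, FeatureVector) else dict(features)
    row = pd.DataFrame([d])
    out = classifier.predict(row).iloc[0]
    return {"label": str(out["label"]), "risk_score": float(out["risk_score"])}


def evaluate(classifier: FittedClassifier, table: CohortTable) -> EvalReport:
    """Apply a fitted classifier to a labeled table (transfer evaluation)."""
    y = table.y
    if y is None:
        raise ValueError("evaluate requires a labeled table")
    pred = classifier.predict(table.data)
    report = rates(confusion_from_labels(table.labels, pred["label"]))
    report.auc, report.roc_points = roc_auc(pred["risk_score"].to_numpy(), y)
    return report


def save_model(classifier: FittedClassifier, path) -> None:
    """Serialize a fitted classifier (self-describing payload)."""
    payload = {
        "format": "oxiscreen-model",
        "version": 1,
        "algorithm": classifier.algorithm,
        "params": classifier.params,
        "feature_names": classifier.feature_names,
        "standardizer": {
            "means": classifier.standardizer.means,
            "stds": classifier.standardizer.stds,
            "fitted_on": classifier.standardizer.fitted_on,
        },
        "seed": classifier.seed,
        "model": classifier.model,
    }
    joblib.dump(payload, path)


def load_model(path) -> FittedClassifier:
    payload = joblib.load(path)
    if payload.get("format") != "oxiscreen-model":
        raise ValueError(f"{path} is not an oxiscreen model artifact")
    std = Standardizer(**payload["standardizer"])
    return FittedClassifier(
        payload["algorithm"], payload["params"], payload["feature_names"],
        std, payload["model"], payload.get("seed", 0),
    )
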