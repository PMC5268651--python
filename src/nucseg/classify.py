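"""Supervised classification of nuclei: normal vs dysmorphic.

Protocol: downsample the majority class to the minority size, stratified
2/3 train / 1/3 test split, hyperparameters tuned by stratified 10-fold
cross-validation on the training set only (z-scoring is fitted inside the
CV pipeline, so no test information leaks into the fit).  Reported rates:
MCR (misclassified / total) and FNR (dysmorphic predicted normal /
total dysmorphic) -- the dysmorphic class is the positive class because a
false negative is a missed dysmorphic nucleus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     cross_val_predict, train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger("nucseg")

POSITIVE_CLASS = "dysmorphic"

MODELS = ("svm_rbf", "rf", "lda", "qda", "nb")


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 1 / 3
    cv_folds: int = 10
    seed: int = 0


@dataclass
class ClassifierReport:
    model: str
    train_mcr: float
    train_fnr: float
    test_mcr: float
    test_fnr: float
    confusion: np.ndarray
    best_params: dict = field(default_factory=dict)


@dataclass
class FittedModel:
    """A fitted pipeline plus the feature schema it was trained on."""

    name: str
    pipeline: Pipeline
    feature_names: list[str]
    train_table: pd.DataFrame
    label_col: str
    report: ClassifierReport | None = None


def balance_dataset(table: pd.DataFrame, label_col: str, seed: int) -> pd.DataFrame:
    """Downsample the majority class to the minority count, without replacement."""
    counts = table[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("need two classes to balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, grp in table.groupby(label_col, sort=True):
        if len(grp) > n_min:
            idx = rng.choice(len(grp), size=n_min, replace=False)
            grp = grp.iloc[np.sort(idx)]
        parts.append(grp)
    return pd.concat(parts).sort_index().reset_index(drop=True)


def _build_estimator(model: str, cv: StratifiedKFold, seed: int) -> GridSearchCV:
    if model == "svm_rbf":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(kernel="rbf"))])
        grid = {"clf__C": [1.0, 10.0, 100.0],
                "clf__gamma": ["scale", 0.01, 0.1]}
    elif model == "rf":
        # headline defaults (500 trees, 3 features per split) in the grid
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", RandomForestClassifier(
                            n_estimators=500, random_state=seed))])
        grid = {"clf__max_features": [3, "sqrt"]}
    elif model == "lda":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", LinearDiscriminantAnalysis())])
        grid = {}
    elif model == "qda":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", QuadraticDiscriminantAnalysis())])
        grid = {"clf__reg_param": [0.0, 0.1]}
    elif model == "nb":
        est = Pipeline([("scale", StandardScaler()), ("clf", GaussianNB())])
        grid = {}
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=1)


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    mcr = float(np.mean(y_true != y_pred))
    pos = y_true == POSITIVE_CLASS
    fnr = float(np.mean(y_pred[pos] != POSITIVE_CLASS)) if pos.any() else 0.0
    classes = sorted(set(y_true) | set(y_pred))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[classes.index(t), classes.index(p)] += 1
    return mcr, fnr, conf


def train_evaluate(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                   model: str, split: SplitSpec = SplitSpec()
                   ) -> tuple[FittedModel, ClassifierReport]:
    """Train one classifier under the split/CV protocol and report rates."""
    X = features.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("nucleus_id", "border") if c in features], errors="ignore")
    if X.isna().any().any():
        raise ValueError("features contain missing values")
    y = pd.Series(np.asarray(labels), name="class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=split.test_fraction, stratify=y, random_state=split.seed)
    folds = split.cv_folds
    min_class = y_tr.value_counts().min()
    if min_class < folds:
        warnings.warn(f"reducing CV folds {folds} -> {min_class}")
        folds = max(2, int(min_class))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split.seed)
    search = _build_estimator(model, cv, split.seed)
    search.fit(X_tr, y_tr)
    cv_pred = cross_val_predict(search.best_estimator_, X_tr, y_tr, cv=cv)
    train_mcr, train_fnr, _ = _rates(y_tr, cv_pred)
    test_pred = search.best_estimator_.predict(X_te)
    test_mcr, test_fnr, conf = _rates(y_te, test_pred)
    report = ClassifierReport(model=model, train_mcr=train_mcr,
                              train_fnr=train_fnr, test_mcr=test_mcr,
                              test_fnr=test_fnr, confusion=conf,
                              best_params=dict(search.best_params_))
    table = X_tr.copy()
    table["class"] = y_tr.to_numpy()
    fitted = FittedModel(name=model, pipeline=search.best_estimator_,
                         feature_names=list(X.columns), train_table=table,
                         label_col="class", report=report)
    logger.info("%s: test MCR %.3f FNR %.3f (params %s)",
                model, test_mcr, test_fnr, search.best_params_)
    return fitted, report


def fit_model(features: pd.DataFrame, labels: pd.Series | np.ndarray,
              model: str, cv_folds: int = 10, seed: int = 0) -> FittedModel:
    """Fit one classifier on the full supplied table (CV-tuned, no test split).

    Building block for workflows that manage their own held-out data, e.g.
    iterative retraining.
    """
    X = features.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("nucleus_id", "border") if c in features], errors="ignore")
    y = pd.Series(np.asarray(labels), name="class")
    folds = min(cv_folds, int(y.value_counts().min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    search = _build_estimator(model, cv, seed)
    search.fit(X, y)
    table = X.copy()
    table["class"] = y.to_numpy()
    return FittedModel(name=model, pipeline=search.best_estimator_,
                       feature_names=list(X.columns), train_table=table,
                       label_col="class")


def predict(model: FittedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Deterministic predictions (and decision scores where available)."""
    missing = [c for c in model.feature_names if c not in features.columns]
    extra = [c for c in features.select_dtypes(include=[np.number]).columns
             if c not in model.feature_names + ["nucleus_id", "border"]]
    if missing:
        raise ValueError(f"feature schema mismatch; missing {missing}, extra {extra}")
    X = features[model.feature_names]
    out = pd.DataFrame({"prediction": model.pipeline.predict(X)})
    if hasattr(model.pipeline, "decision_function"):
        try:
            out["score"] = model.pipeline.decision_function(X)
        except AttributeError:
            pass
    if "nucleus_id" in features:
        out.insert(0, "nucleus_id", features["nucleus_id"].to_numpy())
    return out


def retrain_from_labels(model: FittedModel, new_rows: pd.DataFrame,
                        seed: int = 0) -> FittedModel:
    """Refit after appending newly labelled rows (non-interactive retraining).

    ``new_rows`` must carry the training feature columns plus the label
    column.  Returns a new fitted model with a fresh CV report; retraining
    with zero new rows and the same seed reproduces the previous fit.
    """
    if len(new_rows):
        missing = [c for c in model.feature_names + [model.label_col]
                   if c not in new_rows.columns]
        if missing:
            raise ValueError(f"new rows missing columns {missing}")
        table = pd.concat([model.train_table,
                           new_rows[model.feature_names + [model.label_col]]],
                          ignore_index=True)
    else:
        table = model.train_table
    y = table[model.label_col]
    X = table[model.feature_names]
    folds = min(10, int(y.value_counts().min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    search = _build_estimator(model.name, cv, seed)
    search.fit(X, y)
    cv_pred = cross_val_predict(search.best_estimator_, X, y, cv=cv)
    mcr, fnr, conf = _rates(y, cv_pred)
    report = ClassifierReport(model=model.name, train_mcr=mcr, train_fnr=fnr,
                              test_mcr=np.nan, test_fnr=np.nan, confusion=conf,
                              best_params=dict(search.best_params_))
    return FittedModel(name=model.name, pipeline=search.best_estimator_,
                       feature_names=model.feature_names, train_table=table,
                       label_col=model.label_col, report=report)
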