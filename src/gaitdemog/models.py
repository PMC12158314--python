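"""Feature selection and the classifier/regressor zoo, including the stacking ensemble.

Protocol: the window-level feature table is split 70/30 at the *subject*
level (windows overlap by 50%, so a window-level split leaks fragments of
the same strides across the partition; a window-level split remains
available for comparison).  Recursive feature elimination (RFE) with a
linear-weight estimator — logistic regression for sex, a linear
support-vector regressor for age — reduces the catalogue to 30 features.
Models are trained with their standard hyperparameters (below); the sex
stacking ensemble uses SVC, kNN and random forest bases whose out-of-fold
class probabilities are concatenated with the original features
(passthrough) and fed to a LightGBM meta-model.

Median imputation and z-score standardization are fit on the training split
only.  Distance- and margin-based models (LR, SVC/SVR, kNN, linear
regression) see standardized features; tree ensembles see unscaled ones.
Sex labels are encoded male=1, female=0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import (StratifiedGroupKFold, StratifiedKFold,
                                     cross_val_score, train_test_split)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR, LinearSVR
from xgboost import XGBClassifier, XGBRegressor

from .errors import ConfigurationError, DataError
from .features import LABEL_COLUMNS, feature_names

TASKS = ("sex", "age")
#: model kinds whose inputs are z-scored (distance/margin based)
SCALED_KINDS = {"lr", "svc", "svr", "knn", "linear"}

CLASSIFIER_KINDS = ("lr", "svc", "knn", "rf", "xgboost", "lightgbm")
REGRESSOR_KINDS = ("linear", "svr", "knn", "rf", "xgboost", "lightgbm")


@dataclass(frozen=True)
class ModelConfig:
    """One model specification: kind, task, optional hyperparameter
    overrides, scaling override and seed."""

    kind: str
    task: str = "sex"
    params: dict = field(default_factory=dict)
    scale: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(f"task must be one of {TASKS}, got {self.task!r}")
        kinds = CLASSIFIER_KINDS if self.task == "sex" else REGRESSOR_KINDS
        if self.kind not in kinds + ("stacking",):
            raise ConfigurationError(f"unknown {self.task} model kind {self.kind!r}")


@dataclass
class TrainedPredictor:
    """A fitted pipeline (imputer -> optional scaler -> estimator) plus the
    feature-name contract and a training manifest."""

    pipeline: Pipeline
    feature_names: list[str]
    task: str
    manifest: dict


def encode_sex(values) -> np.ndarray:
    return np.asarray([1 if v == "male" else 0 for v in values], dtype=int)


def _labels(df: pd.DataFrame, task: str) -> np.ndarray:
    return encode_sex(df["sex"]) if task == "sex" else df["age"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    df: pd.DataFrame,
    train_fraction: float = 0.7,
    by_subject: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the feature table into disjoint train/test partitions.

    With ``by_subject`` (the default) whole subjects are assigned to one
    side, stratified by sex, so no subject's windows leak across the split;
    otherwise rows are split directly (stratified by sex).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    if not by_subject:
        idx_train, idx_test = train_test_split(
            np.arange(len(df)), train_size=train_fraction,
            random_state=int(rng.integers(2**31)), stratify=df["sex"].to_numpy(),
        )
        return df.iloc[np.sort(idx_train)].copy(), df.iloc[np.sort(idx_test)].copy()
    subjects = df[["subject_id", "sex"]].drop_duplicates("subject_id")
    if len(subjects) < 2:
        raise DataError("subject-level split needs at least 2 subjects")
    train_ids: list[str] = []
    for _, grp in subjects.groupby("sex", sort=True):
        ids = grp["subject_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round(train_fraction * len(ids)))
        train_ids.extend(ids[:n_train])
    train_mask = df["subject_id"].isin(train_ids)
    return df[train_mask].copy(), df[~train_mask].copy()


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def rfe_select(
    train: pd.DataFrame,
    task: str,
    n_keep: int = 30,
    seed: int = 0,
    step: int = 1,
    columns: Sequence[str] | None = None,
) -> list[str]:
    """Recursive feature elimination down to ``n_keep`` features.

    Features are median-imputed and z-scored, then an estimator with linear
    weights — logistic regression for sex, a linear support-vector regressor
    for age (an RBF kernel has no per-feature coefficients to rank) — is
    refit repeatedly, dropping the ``step`` lowest-|weight| features per
    iteration.  Returns the surviving names in the input column order.
    """
    if task not in TASKS:
        raise ConfigurationError(f"task must be one of {TASKS}, got {task!r}")
    cols = list(columns) if columns is not None else feature_names(train)
    X = train[cols].to_numpy(dtype=float)
    keep_mask = ~np.all(np.isnan(X), axis=0)
    cols = [c for c, k in zip(cols, keep_mask) if k]
    X = X[:, keep_mask]
    X = SimpleImputer(strategy="median").fit_transform(X)
    if not np.all(np.isfinite(X)):
        raise DataError("feature matrix contains non-finite values after imputation")
    if n_keep >= X.shape[1]:
        return cols
    X = StandardScaler().fit_transform(X)
    y = _labels(train, task)
    if task == "sex":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    else:
        est = LinearSVR(random_state=seed, max_iter=5000, dual="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rfe = RFE(est, n_features_to_select=n_keep, step=step).fit(X, y)
    return [c for c, keep in zip(cols, rfe.support_) if keep]


# ---------------------------------------------------------------------------
# model zoo
# ---------------------------------------------------------------------------

def make_classifier(kind: str, seed: int = 0, **overrides):
    """Classifier with its standard hyperparameters (overridable)."""
    defaults = {
        "lr": lambda: LogisticRegression(C=0.1, solver="lbfgs", max_iter=2000,
                                         random_state=seed, **overrides),
        "svc": lambda: SVC(C=10, kernel="rbf", probability=True,
                           random_state=seed, **overrides),
        "knn": lambda: KNeighborsClassifier(n_neighbors=3, weights="distance",
                                            metric="manhattan", **overrides),
        "rf": lambda: RandomForestClassifier(n_estimators=100, bootstrap=False,
                                             criterion="gini", random_state=seed,
                                             n_jobs=1, **overrides),
        "xgboost": lambda: XGBClassifier(n_estimators=500, learning_rate=0.1,
                                         subsample=0.7, max_depth=10,
                                         random_state=seed, n_jobs=1,
                                         eval_metric="logloss", verbosity=0,
                                         **overrides),
        "lightgbm": lambda: LGBMClassifier(n_estimators=500, learning_rate=0.1,
                                           subsample=0.4, random_state=seed,
                                           n_jobs=1, verbose=-1, **overrides),
    }
    if kind not in defaults:
        raise ConfigurationError(f"unknown classifier kind {kind!r}")
    return defaults[kind]()


def make_regressor(kind: str, seed: int = 0, **overrides):
    """Regressor with its standard hyperparameters (overridable)."""
    defaults = {
        "linear": lambda: LinearRegression(**overrides),
        "svr": lambda: SVR(C=150, kernel="rbf", epsilon=0.001, **overrides),
        "knn": lambda: KNeighborsRegressor(n_neighbors=3, metric="manhattan",
                                           weights="distance", **overrides),
        "rf": lambda: RandomForestRegressor(n_estimators=100, random_state=seed,
                                            n_jobs=1, **overrides),
        "xgboost": lambda: XGBRegressor(n_estimators=300, learning_rate=0.1,
                                        max_depth=10, subsample=0.8,
                                        random_state=seed, n_jobs=1, verbosity=0,
                                        **overrides),
        "lightgbm": lambda: LGBMRegressor(n_estimators=500, learning_rate=0.1,
                                          max_depth=-1, subsample=0.5,
                                          random_state=seed, n_jobs=1, verbose=-1,
                                          **overrides),
    }
    if kind not in defaults:
        raise ConfigurationError(f"unknown regressor kind {kind!r}")
    return defaults[kind]()


def _build_pipeline(estimator, scale: bool) -> Pipeline:
    steps = [("imputer", SimpleImputer(strategy="median"))]
    if scale:
        steps.append(("scaler", StandardScaler()))
    steps.append(("model", estimator))
    return Pipeline(steps)


def train_predictor(
    train: pd.DataFrame,
    config: ModelConfig,
    columns: Sequence[str] | None = None,
    cv_folds: int = 0,
) -> TrainedPredictor:
    """Fit one model on the training split (imputer and scaler fit on train
    only).  With ``cv_folds`` > 0, k-fold cross-validation scores on the
    training split are recorded in the manifest."""
    cols = list(columns) if columns is not None else feature_names(train)
    if len(train) == 0:
        raise DataError("training set is empty")
    y = _labels(train, config.task)
    if config.task == "sex" and len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    if config.task == "sex":
        est = make_classifier(config.kind, seed=config.seed, **config.params)
    else:
        est = make_regressor(config.kind, seed=config.seed, **config.params)
    scale = config.scale if config.scale is not None else config.kind in SCALED_KINDS
    pipe = _build_pipeline(est, scale)
    X = train[cols].to_numpy(dtype=float)
    manifest = {
        "kind": config.kind, "task": config.task, "seed": config.seed,
        "scale": scale, "params": est.get_params(deep=False) if hasattr(est, "get_params") else {},
        "n_train": int(len(train)), "n_features": len(cols),
    }
    manifest["params"] = {k: v for k, v in manifest["params"].items()
                          if isinstance(v, (int, float, str, bool, type(None)))}
    if cv_folds and config.task == "sex":  # CV before the final fit
        scores = cross_val_score(pipe, X, y, cv=StratifiedKFold(
            cv_folds, shuffle=True, random_state=config.seed), scoring="accuracy")
        manifest["cv_accuracy"] = [float(s) for s in scores]
    elif cv_folds:
        scores = cross_val_score(pipe, X, y, cv=cv_folds, scoring="r2")
        manifest["cv_r2"] = [float(s) for s in scores]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        pipe.fit(X, y)
    return TrainedPredictor(pipeline=pipe, feature_names=cols, task=config.task,
                            manifest=manifest)


class StackedClassifier(BaseEstimator, ClassifierMixin):
    """Passthrough stacking: out-of-fold base probabilities + original features.

    During fit, each base classifier is trained on the complement of every
    CV fold and emits positive-class probabilities for the held-out fold;
    the meta-model is trained on [one OOF probability column per base ||
    original features] (the passthrough), and the bases are then refit on
    the full training data for the prediction path.  When per-sample
    ``groups`` (e.g. subject ids) are supplied at fit time, the folds are
    group-aware so windows of one subject never inform their own
    out-of-fold probabilities.
    """

    def __init__(self, estimators, final_estimator, n_folds=5, passthrough=True,
                 random_state=0):
        self.estimators = estimators
        self.final_estimator = final_estimator
        self.n_folds = n_folds
        self.passthrough = passthrough
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_folds < 2:
            raise ConfigurationError("stacking needs at least 2 folds")
        if not self.estimators:
            raise ConfigurationError("stacking needs at least one base model")
        self.classes_ = np.unique(y)
        if groups is not None:
            cv = StratifiedGroupKFold(self.n_folds, shuffle=True,
                                      random_state=self.random_state)
            folds = list(cv.split(X, y, np.asarray(groups)))
        else:
            cv = StratifiedKFold(self.n_folds, shuffle=True,
                                 random_state=self.random_state)
            folds = list(cv.split(X, y))
        oof = np.zeros((len(X), len(self.estimators)))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            for tr, va in folds:
                for j, (_, est) in enumerate(self.estimators):
                    fold_est = clone(est).fit(X[tr], y[tr])
                    oof[va, j] = fold_est.predict_proba(X[va])[:, 1]
            self.estimators_ = [clone(est).fit(X, y) for _, est in self.estimators]
            self.final_estimator_ = clone(self.final_estimator).fit(
                self._meta_input(oof, X), y)
        return self

    def _meta_input(self, probs, X):
        return np.hstack([probs, X]) if self.passthrough else probs

    def _base_probs(self, X):
        return np.column_stack([est.predict_proba(X)[:, 1] for est in self.estimators_])

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*feature names.*")
            return self.final_estimator_.predict_proba(
                self._meta_input(self._base_probs(X), X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_stacking(
    train: pd.DataFrame,
    columns: Sequence[str] | None = None,
    base_kinds: Sequence[str] = ("svc", "knn", "rf"),
    meta_params: dict | None = None,
    passthrough: bool = True,
    n_folds: int = 5,
    seed: int = 0,
    group_by_subject: bool = True,
) -> TrainedPredictor:
    """Sex stacking ensemble: SVC, kNN and random-forest bases, LightGBM
    meta-model on out-of-fold base probabilities concatenated with the
    original features.  Folds are grouped by subject_id (when present and
    ``group_by_subject``) to keep the out-of-fold probabilities honest under
    the subject-level evaluation protocol; the meta LightGBM runs its 0.4
    row-subsampling every boosting round (subsample_freq=1)."""
    cols = list(columns) if columns is not None else feature_names(train)
    y = _labels(train, "sex")
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    meta = LGBMClassifier(n_estimators=100, learning_rate=0.1, subsample=0.4,
                          subsample_freq=1, random_state=seed, n_jobs=1,
                          verbose=-1, **(meta_params or {}))
    bases = [(k, make_classifier(k, seed=seed)) for k in base_kinds]
    stack = StackedClassifier(estimators=bases, final_estimator=meta,
                              n_folds=n_folds, passthrough=passthrough,
                              random_state=seed)
    pipe = _build_pipeline(stack, scale=True)
    X = train[cols].to_numpy(dtype=float)
    groups = None
    if group_by_subject and "subject_id" in train.columns:
        groups = train["subject_id"].to_numpy()
    pipe.fit(X, y, model__groups=groups)
    manifest = {
        "kind": "stacking", "task": "sex", "seed": seed, "scale": True,
        "bases": list(base_kinds), "meta": "lightgbm",
        "passthrough": passthrough, "n_folds": n_folds,
        "grouped_folds": groups is not None,
        "n_train": int(len(train)), "n_features": len(cols),
    }
    return TrainedPredictor(pipeline=pipe, feature_names=cols, task="sex",
                            manifest=manifest)


# ---------------------------------------------------------------------------
# prediction and persistence
# ---------------------------------------------------------------------------

def predict(predictor: TrainedPredictor, df: pd.DataFrame):
    """Predict on a feature table (columns aligned by name).

    Classifiers return (labels, positive-class scores); regressors return
    predicted ages.
    """
    missing = [c for c in predictor.feature_names if c not in df.columns]
    if missing:
        raise DataError(f"feature table is missing column(s): {missing}")
    X = df[predictor.feature_names].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*feature names.*")
        if predictor.task == "sex":
            labels = predictor.pipeline.predict(X)
            scores = predictor.pipeline.predict_proba(X)[:, 1]
            return np.asarray(labels, dtype=int), scores
        return predictor.pipeline.predict(X)


def save_predictor(predictor: TrainedPredictor, path) -> None:
    joblib.dump({"format_version": 1,
                 "pipeline": predictor.pipeline,
                 "feature_names": predictor.feature_names,
                 "task": predictor.task,
                 "manifest": predictor.manifest}, path)


def load_predictor(path) -> TrainedPredictor:
    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise DataError(f"unsupported predictor format: {blob.get('format_version')!r}")
    return TrainedPredictor(pipeline=blob["pipeline"],
                            feature_names=blob["feature_names"],
                            task=blob["task"], manifest=blob["manifest"])
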