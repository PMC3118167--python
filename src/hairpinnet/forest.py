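"""Random-forest classification of hairpin feature vectors.

The estimator follows the original protocol: a forest of ``ntree`` trees,
``mtry`` candidate features per split, out-of-bag (OOB) error recorded at
fit time, and prediction scores defined as the fraction of trees voting
for the positive class (label at the 0.5 vote threshold, ties positive).
Hyperparameters are tuned by seeded, stratified 10-fold cross-validated
grid search over ``ntree`` in {500, 1000, 1500, 2000} and ``mtry`` in
1..24, ties resolved toward the smaller ``ntree`` then smaller ``mtry``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, FeatureMatrix, N_FEATURES
from .records import HairpinError

POSITIVE, NEGATIVE = "positive", "negative"

DEFAULT_NTREE_GRID = (500, 1000, 1500, 2000)
DEFAULT_MTRY_GRID = tuple(range(1, N_FEATURES + 1))

_MODEL_FORMAT = "hairpinnet-rf-1"


@dataclass(frozen=True)
class RfConfig:
    """Forest hyperparameters plus the seeds controlling every random draw."""

    ntree: int = 500
    mtry: int = 5
    seed: int = 0
    k_folds: int = 10

    def __post_init__(self):
        if self.ntree < 1:
            raise HairpinError("ntree must be >= 1")
        if self.mtry < 1:
            raise HairpinError("mtry must be >= 1")
        if self.k_folds < 2:
            raise HairpinError("k_folds must be >= 2")


class HairpinForestClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style binary random-forest classifier with vote-fraction scores.

    Parameters
    ----------
    ntree : int
        Number of trees grown from bootstrap samples.
    mtry : int
        Number of features sampled as split candidates at each node.
    random_state : int or None
        Seed for bootstrap and feature sampling.

    Fitted attributes (trailing underscore): ``forest_``, ``classes_``,
    ``positive_label_``, ``oob_error_``, ``feature_names_in_`` (when fit
    on a DataFrame), ``n_features_in_``.
    """

    def __init__(self, ntree: int = 500, mtry: int = 5,
                 random_state: int | None = None):
        self.ntree = ntree
        self.mtry = mtry
        self.random_state = random_state

    # get_params/set_params come from BaseEstimator

    # -- input handling -----------------------------------------------------
    def _coerce_X(self, X, fitting: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = list(X.columns)
            elif getattr(self, "feature_names_in_", None) is not None:
                missing = set(self.feature_names_in_) - set(X.columns)
                if missing:
                    raise HairpinError(
                        f"feature column(s) missing: {sorted(missing)}")
                X = X[self.feature_names_in_]  # name-based realignment
            arr = X.to_numpy(dtype=float)
        else:
            if fitting:
                self.feature_names_in_ = None
            arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise HairpinError("X must be 2-dimensional")
        if not fitting and arr.shape[1] != self.n_features_in_:
            raise HairpinError(
                f"X has {arr.shape[1]} features, model expects "
                f"{self.n_features_in_}")
        if not np.isfinite(arr).all():
            raise HairpinError("X contains non-finite values")
        return arr

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y) -> "HairpinForestClassifier":
        Xa = self._coerce_X(X, fitting=True)
        ya = np.asarray(y)
        classes = np.unique(ya)
        if len(classes) != 2:
            raise HairpinError(
                f"need exactly 2 classes, got {len(classes)}")
        if not 1 <= self.mtry <= Xa.shape[1]:
            raise HairpinError(
                f"mtry={self.mtry} outside [1, {Xa.shape[1]}]")
        self.classes_ = classes
        self.positive_label_ = (POSITIVE if POSITIVE in classes
                                else classes[-1])
        self.n_features_in_ = Xa.shape[1]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.ntree, max_features=self.mtry,
            oob_score=True, random_state=self.random_state, n_jobs=1)
        self.forest_.fit(Xa, ya)
        self.oob_error_ = float(1.0 - self.forest_.oob_score_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "forest_"):
            raise HairpinError("classifier is not fitted")

    def vote_scores(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class, per sample."""
        self._check_fitted()
        Xa = self._coerce_X(X, fitting=False)
        pos_idx = list(self.forest_.classes_).index(self.positive_label_)
        votes = np.zeros(Xa.shape[0])
        for tree in self.forest_.estimators_:
            votes += tree.predict(Xa) == pos_idx
        return votes / len(self.forest_.estimators_)

    def predict(self, X) -> np.ndarray:
        """Class labels at the 0.5 vote-fraction threshold (ties positive)."""
        scores = self.vote_scores(X)
        neg = [c for c in self.classes_ if c != self.positive_label_][0]
        return np.where(scores >= 0.5, self.positive_label_, neg)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.vote_scores(X)
        out = np.empty((len(scores), 2))
        for k, cls in enumerate(self.classes_):
            out[:, k] = scores if cls == self.positive_label_ else 1 - scores
        return out

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class TrainedModel:
    """A fitted forest with its configuration and feature-order contract."""

    clf: HairpinForestClassifier
    config: RfConfig
    feature_names: tuple[str, ...]
    oob_error: float
    importance: object | None = field(default=None)


def _validate_matrix(data: FeatureMatrix):
    if data.y is None:
        raise HairpinError("training data must be labelled")
    classes = np.unique(np.asarray(data.y, dtype=object))
    if len(classes) < 2:
        raise HairpinError("single-class data: both classes are required")


def train(data: FeatureMatrix, cfg: RfConfig | None = None) -> TrainedModel:
    """Fit a forest on a labelled feature matrix."""
    cfg = cfg or RfConfig()
    _validate_matrix(data)
    clf = HairpinForestClassifier(cfg.ntree, cfg.mtry, cfg.seed)
    clf.fit(data.X, np.asarray(data.y, dtype=object))
    return TrainedModel(clf=clf, config=cfg,
                        feature_names=tuple(data.X.columns),
                        oob_error=clf.oob_error_)


def predict(model: TrainedModel, data: FeatureMatrix) -> pd.DataFrame:
    """Per-record vote score and label; columns realigned by feature name."""
    if set(model.feature_names) - set(data.X.columns):
        raise HairpinError("feature columns do not match the model")
    X = data.X[list(model.feature_names)]
    return pd.DataFrame({
        "id": data.ids,
        "score": model.clf.vote_scores(X),
        "label": model.clf.predict(X),
    })


def grid_search(data: FeatureMatrix,
                ntree_grid=DEFAULT_NTREE_GRID,
                mtry_grid=DEFAULT_MTRY_GRID,
                k_folds: int = 10, seed: int = 0) -> RfConfig:
    """Pick (ntree, mtry) maximizing mean stratified k-fold CV accuracy.

    Ties are broken toward the smaller ntree, then the smaller mtry; the
    fold assignment is stratified by class and fixed by ``seed`` across
    all grid points.
    """
    _validate_matrix(data)
    X = data.X.to_numpy(dtype=float)
    y = np.asarray(data.y, dtype=object)
    n_features = X.shape[1]
    for mtry in mtry_grid:
        if not 1 <= mtry <= n_features:
            raise HairpinError(f"grid mtry={mtry} outside [1, {n_features}]")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_cfg, best_acc = None, -np.inf
    for ntree, mtry in itertools.product(sorted(ntree_grid),
                                         sorted(mtry_grid)):
        accs = []
        for fold_idx, (tr, te) in enumerate(folds):
            clf = HairpinForestClassifier(ntree, mtry, random_state=seed)
            # OOB needs no separate toggle: cost is negligible next to fitting
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_cfg, best_acc = (ntree, mtry), mean_acc
    return RfConfig(ntree=best_cfg[0], mtry=best_cfg[1], seed=seed,
                    k_folds=k_folds)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (config + feature names + fitted forest)."""
    payload = {
        "format": _MODEL_FORMAT,
        "config": asdict(model.config),
        "feature_names": list(model.feature_names),
        "oob_error": model.oob_error,
        "classifier": model.clf,
    }
    joblib.dump(payload, path)


def load_model(path, expected_features=FEATURE_NAMES) -> TrainedModel:
    """Load a model archive, verifying format and feature-name contract."""
    payload = joblib.load(path)
    if payload.get("format") != _MODEL_FORMAT:
        raise HairpinError("not a hairpinnet model archive")
    names = tuple(payload["feature_names"])
    if expected_features is not None and names != tuple(expected_features):
        raise HairpinError("model feature names do not match the expected "
                           "canonical order")
    return TrainedModel(clf=payload["classifier"],
                        config=RfConfig(**payload["config"]),
                        feature_names=names,
                        oob_error=payload["oob_error"])
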