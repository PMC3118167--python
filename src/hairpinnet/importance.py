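"""Feature importance and recursive feature elimination.

Two importance strategies are provided:

* **permutation importance** — the mean decrease in accuracy when one
  feature column is shuffled, averaged over repeats, with a 2.5/97.5
  percentile confidence interval over the repeats;
* **conditional importance** — the same statistic, but the column is
  shuffled *within strata* formed by jointly quartile-binning every
  feature whose absolute Pearson correlation with it exceeds a threshold
  (default 0.2).  Shuffling within strata preserves the correlation
  structure under the null, so importance shared with correlated
  features is discounted.  With no correlated feature the stratification
  degenerates to a single stratum and the two strategies coincide draw
  for draw.

Recursive elimination ranks features by the average of the two scores,
removes the lowest-ranked feature, re-evaluates with the resampling
protocol, and repeats until a single feature remains — yielding one
evaluation per feature-set size, nested from the full set down to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import resampling_protocol
from .features import FeatureMatrix
from .forest import HairpinForestClassifier, RfConfig, train
from .records import HairpinError

CI_PERCENTILES = (2.5, 97.5)
DEFAULT_CORR_THRESHOLD = 0.2


def _strata_for_feature(X: np.ndarray, f: int, threshold: float
                        ) -> list[np.ndarray]:
    """Index groups from joint quartile bins of features correlated with f."""
    n, p = X.shape
    correlated = []
    xf = X[:, f]
    for g in range(p):
        if g == f:
            continue
        xg = X[:, g]
        if np.std(xf) == 0 or np.std(xg) == 0:
            continue
        r = np.corrcoef(xf, xg)[0, 1]
        if np.isfinite(r) and abs(r) > threshold:
            correlated.append(g)
    if not correlated:
        return [np.arange(n)]
    keys = np.zeros(n, dtype=np.int64)
    for g in correlated:
        edges = np.quantile(X[:, g], [0.25, 0.5, 0.75])
        bins = np.searchsorted(edges, X[:, g], side="right")
        keys = keys * 4 + bins
    return [np.flatnonzero(keys == key) for key in np.unique(keys)]


def _accuracy_drops(model: HairpinForestClassifier, X: np.ndarray,
                    y: np.ndarray, strata_per_feature: list[list[np.ndarray]],
                    n_repeats: int, rng: np.random.Generator) -> np.ndarray:
    """Matrix (n_repeats x n_features) of accuracy drops under permutation."""
    base_acc = model.score(X, y)
    n, p = X.shape
    drops = np.empty((n_repeats, p))
    for rep in range(n_repeats):
        for f in range(p):
            Xp = X.copy()
            for idx in strata_per_feature[f]:
                Xp[idx, f] = X[idx[rng.permutation(len(idx))], f]
            drops[rep, f] = base_acc - model.score(Xp, y)
    return drops


def _summarize(drops: np.ndarray, feature_names) -> pd.DataFrame:
    lo, hi = np.percentile(drops, CI_PERCENTILES, axis=0)
    return pd.DataFrame({
        "score": drops.mean(axis=0), "ci_low": lo, "ci_high": hi,
    }, index=list(feature_names))


def permutation_importance(model: HairpinForestClassifier, X, y,
                           n_repeats: int = 100,
                           random_state: int | None = None) -> pd.DataFrame:
    """Mean decrease in accuracy per feature under marginal permutation."""
    names = _feature_names(X)
    Xa = np.asarray(X, dtype=float)
    rng = np.random.default_rng(random_state)
    strata = [[np.arange(Xa.shape[0])] for _ in range(Xa.shape[1])]
    drops = _accuracy_drops(model, Xa, np.asarray(y), strata, n_repeats, rng)
    return _summarize(drops, names)


def conditional_importance(model: HairpinForestClassifier, X, y,
                           correlation_threshold: float = DEFAULT_CORR_THRESHOLD,
                           n_repeats: int = 100,
                           random_state: int | None = None) -> pd.DataFrame:
    """Mean decrease in accuracy under within-strata (conditional) permutation."""
    names = _feature_names(X)
    Xa = np.asarray(X, dtype=float)
    rng = np.random.default_rng(random_state)
    strata = [_strata_for_feature(Xa, f, correlation_threshold)
              for f in range(Xa.shape[1])]
    drops = _accuracy_drops(model, Xa, np.asarray(y), strata, n_repeats, rng)
    return _summarize(drops, names)


def _feature_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"feature_{k}" for k in range(np.asarray(X).shape[1])]


@dataclass
class ImportanceReport:
    """Both importance strategies side by side, one row per feature."""

    frame: pd.DataFrame  # columns: permutation_score/_ci_low/_ci_high,
    #          conditional_score/_ci_low/_ci_high

    def average_scores(self) -> pd.Series:
        """Per-feature mean of the two strategies (the elimination ranking)."""
        return (self.frame["permutation_score"]
                + self.frame["conditional_score"]) / 2.0

    def ranking(self) -> list[str]:
        """Features from most to least important by average score."""
        avg = self.average_scores()
        return list(avg.sort_values(ascending=False, kind="stable").index)


def importance_report(data: FeatureMatrix, cfg: RfConfig | None = None,
                      n_repeats: int = 100, refit: bool = True,
                      correlation_threshold: float = DEFAULT_CORR_THRESHOLD,
                      seed: int | None = None) -> ImportanceReport:
    """Run both importance strategies, averaged over repeats.

    With ``refit=True`` (default) a fresh forest is trained per repeat on
    a stratified bootstrap resample and the drops are measured on the
    out-of-resample records — the repeats then average over model
    construction as well as over permutations.  With ``refit=False`` a
    single forest is fitted once and only the permutations are repeated.
    """
    if data.y is None:
        raise HairpinError("importance analysis needs labelled data")
    cfg = cfg or RfConfig()
    seed = cfg.seed if seed is None else seed
    X = data.X.to_numpy(dtype=float)
    y = np.asarray(data.y, dtype=object)
    names = list(data.X.columns)
    p = X.shape[1]
    rng = np.random.default_rng(seed)

    perm = np.empty((n_repeats, p))
    cond = np.empty((n_repeats, p))
    if refit:
        classes = np.unique(y)
        idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
        for rep in range(n_repeats):
            boot = np.concatenate([
                rng.choice(idx, size=len(idx), replace=True)
                for idx in idx_by_class.values()])
            oob = np.setdiff1d(np.arange(len(y)), boot)
            if len(np.unique(y[oob])) < 2:
                oob = np.arange(len(y))  # degenerate draw; fall back
            clf = HairpinForestClassifier(
                cfg.ntree, cfg.mtry,
                random_state=int(rng.integers(2**31 - 1)))
            clf.fit(X[boot], y[boot])
            marg = [[np.arange(len(oob))] for _ in range(p)]
            strat = [_strata_for_feature(X[oob], f, correlation_threshold)
                     for f in range(p)]
            perm[rep] = _accuracy_drops(clf, X[oob], y[oob], marg, 1, rng)[0]
            cond[rep] = _accuracy_drops(clf, X[oob], y[oob], strat, 1, rng)[0]
    else:
        clf = HairpinForestClassifier(
            cfg.ntree, cfg.mtry, random_state=int(rng.integers(2**31 - 1)))
        clf.fit(X, y)
        marg = [[np.arange(len(y))] for _ in range(p)]
        strat = [_strata_for_feature(X, f, correlation_threshold)
                 for f in range(p)]
        perm = _accuracy_drops(clf, X, y, marg, n_repeats, rng)
        cond = _accuracy_drops(clf, X, y, strat, n_repeats, rng)

    frame = pd.DataFrame(index=names)
    for tag, drops in (("permutation", perm), ("conditional", cond)):
        summary = _summarize(drops, names)
        frame[f"{tag}_score"] = summary["score"]
        frame[f"{tag}_ci_low"] = summary["ci_low"]
        frame[f"{tag}_ci_high"] = summary["ci_high"]
    return ImportanceReport(frame=frame)


@dataclass(frozen=True)
class EliminationStep:
    """One rung of the elimination ladder."""

    features: tuple[str, ...]
    sensitivity: float
    specificity: float


def recursive_elimination(data: FeatureMatrix, cfg: RfConfig | None = None,
                          n_train_per_class: int | None = None,
                          eval_repeats: int = 3,
                          importance_repeats: int = 5,
                          seed: int = 0) -> list[EliminationStep]:
    """Delete-lowest-importance-feature elimination down to one feature.

    Returns one :class:`EliminationStep` per feature-set size, from the
    full set to a single feature (nested sets).  At each rung SE and SP
    are measured by the resampling protocol at ``eval_repeats`` repeats,
    then the feature with the lowest average importance (permutation and
    conditional averaged, ``refit=False`` at ``importance_repeats``
    repeats) is removed.  Ties go to the earlier feature in column order.
    """
    if data.y is None:
        raise HairpinError("elimination needs labelled data")
    cfg = cfg or RfConfig()
    y = np.asarray(data.y, dtype=object)
    if n_train_per_class is None:
        smallest = min(np.sum(y == c) for c in np.unique(y))
        n_train_per_class = max(1, int(smallest * 0.6))

    features = list(data.X.columns)
    steps: list[EliminationStep] = []
    rng = np.random.default_rng(seed)
    while features:
        sub = FeatureMatrix(ids=list(data.ids),
                            X=_subset(data.X, features), y=y)
        report = resampling_protocol(sub, n_train_per_class, eval_repeats,
                                     seed=int(rng.integers(2**31 - 1)),
                                     cfg=_clamped(cfg, len(features)))
        steps.append(EliminationStep(features=tuple(features),
                                     sensitivity=report.se,
                                     specificity=report.sp))
        if len(features) == 1:
            break
        imp = importance_report(sub, _clamped(cfg, len(features)),
                                n_repeats=importance_repeats, refit=False,
                                seed=int(rng.integers(2**31 - 1)))
        avg = imp.average_scores()
        lowest = min(features, key=lambda f: (avg[f], -features.index(f)))
        # ties: min() keeps the earlier feature via the reversed index key
        features = [f for f in features if f != lowest]
    return steps


def _clamped(cfg: RfConfig, n_features: int) -> RfConfig:
    mtry = min(cfg.mtry, n_features)
    return RfConfig(ntree=cfg.ntree, mtry=mtry, seed=cfg.seed,
                    k_folds=cfg.k_folds)


def _subset(X: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    sub = X[features].copy()
    return sub
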