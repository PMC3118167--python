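"""Performance evaluation: SE/SP/ACC, ROC/AUC, repeated random resampling.

The headline protocol is repeated stratified subsampling: per repeat a
fixed number of records per class is drawn for training and the held-out
remainder is scored; sensitivity, specificity, accuracy and AUC are
averaged over repeats and the vertical spread of the ROC curves is
summarized by 10/25/50/75/90 percentile bands on a fixed FPR grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .features import FeatureMatrix
from .forest import POSITIVE, HairpinForestClassifier, RfConfig
from .records import HairpinError

logger = logging.getLogger(__name__)

PERCENTILES = (10, 25, 50, 75, 90)
FPR_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class Confusion:
    """Counts of true/false positive/negative calls."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise HairpinError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(truth, predicted, positive: str = POSITIVE) -> Confusion:
    """Tally a confusion matrix from equal-length label vectors."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise HairpinError("truth and prediction lengths differ")
    tpos, ppos = t == positive, p == positive
    return Confusion(TP=int(np.sum(tpos & ppos)),
                     TN=int(np.sum(~tpos & ~ppos)),
                     FP=int(np.sum(~tpos & ppos)),
                     FN=int(np.sum(tpos & ~ppos)))


def se_sp_acc(c: Confusion) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n.

    A metric whose denominator is zero is undefined and reported as NaN.
    """
    se = c.TP / (c.TP + c.FN) if c.TP + c.FN else float("nan")
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP else float("nan")
    acc = (c.TP + c.TN) / c.n if c.n else float("nan")
    return se, sp, acc


def roc_auc(scores, truth, positive: str = POSITIVE
            ) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds and trapezoidal AUC.

    Ties contribute half, so the AUC equals the Mann-Whitney probability
    that a random positive outscores a random negative.  Raises when only
    one class is present.
    """
    t = np.asarray(truth) == positive
    s = np.asarray(scores, dtype=float)
    if t.all() or not t.any():
        raise HairpinError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(t, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def vertical_average_roc(curves: list[np.ndarray],
                         grid: np.ndarray = FPR_GRID) -> pd.DataFrame:
    """Vertically average ROC curves on a fixed FPR grid.

    Each curve is linearly interpolated at the grid (duplicate FPR values
    collapse to their maximum TPR first); columns are the mean and the
    10/25/50/75/90 percentiles of TPR at each grid point.
    """
    if not curves:
        raise HairpinError("need at least one ROC curve")
    tprs = np.empty((len(curves), len(grid)))
    for k, curve in enumerate(curves):
        fpr, tpr = curve[:, 0], curve[:, 1]
        # collapse vertical segments: keep max TPR at each distinct FPR
        df = pd.DataFrame({"fpr": fpr, "tpr": tpr}).groupby("fpr").max()
        tprs[k] = np.interp(grid, df.index.to_numpy(),
                            df["tpr"].to_numpy())
    out = {"fpr": grid, "tpr_mean": tprs.mean(axis=0)}
    for p in PERCENTILES:
        out[f"tpr_p{p}"] = np.percentile(tprs, p, axis=0)
    return pd.DataFrame(out)


@dataclass
class EvalReport:
    """Aggregated metrics of a repeated-resampling evaluation."""

    se: float
    sp: float
    acc: float
    auc: float
    per_repeat: pd.DataFrame            # one row per repeat: SE/SP/ACC/AUC
    percentiles: pd.DataFrame           # metric x p10..p90
    roc: pd.DataFrame                   # vertical-averaged ROC bands
    seed: int
    n_train_per_class: int
    repeats: int
    curves: list = field(default_factory=list, repr=False)

    def summary(self) -> dict:
        return {"SE": self.se, "SP": self.sp, "ACC": self.acc,
                "AUC": self.auc, "repeats": self.repeats,
                "n_train_per_class": self.n_train_per_class,
                "seed": self.seed}


def evaluate_split(clf: HairpinForestClassifier, X_test, y_test
                   ) -> tuple[float, float, float, float, np.ndarray]:
    """SE/SP/ACC/AUC and the ROC curve of one fitted model on one test set."""
    scores = clf.vote_scores(X_test)
    pred = np.where(scores >= 0.5, clf.positive_label_,
                    [c for c in clf.classes_ if c != clf.positive_label_][0])
    se, sp, acc = se_sp_acc(confusion(y_test, pred,
                                      positive=clf.positive_label_))
    curve, auc = roc_auc(scores, y_test, positive=clf.positive_label_)
    return se, sp, acc, auc, curve


def resampling_protocol(data: FeatureMatrix, n_train_per_class: int,
                        repeats: int, seed: int,
                        cfg: RfConfig | None = None) -> EvalReport:
    """Repeated stratified random-subsampling evaluation.

    Per repeat, ``n_train_per_class`` records of each class are drawn
    (without replacement) for training and the remainder is used for
    testing; metrics are averaged over repeats (NaN metrics excluded with
    a logged count) and ROC curves are vertically averaged.  All
    randomness derives from ``seed``.
    """
    if data.y is None:
        raise HairpinError("resampling evaluation needs labelled data")
    cfg = cfg or RfConfig()
    y = np.asarray(data.y, dtype=object)
    X = data.X.reset_index(drop=True)
    classes = np.unique(y)
    if len(classes) != 2:
        raise HairpinError("need exactly 2 classes")
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in idx_by_class.items():
        if len(idx) <= n_train_per_class:
            raise HairpinError(
                f"class {c!r} has {len(idx)} records; need more than "
                f"n_train_per_class={n_train_per_class}")

    rng = np.random.default_rng(seed)
    rows, curves = [], []
    for rep in range(repeats):
        train_idx = np.concatenate([
            rng.choice(idx_by_class[c], size=n_train_per_class, replace=False)
            for c in classes])
        mask = np.zeros(len(y), dtype=bool)
        mask[train_idx] = True
        clf = HairpinForestClassifier(
            cfg.ntree, cfg.mtry,
            random_state=int(rng.integers(2**31 - 1)))
        clf.fit(X[mask], y[mask])
        se, sp, acc, auc, curve = evaluate_split(clf, X[~mask], y[~mask])
        rows.append({"repeat": rep, "SE": se, "SP": sp, "ACC": acc,
                     "AUC": auc})
        curves.append(curve)

    per_repeat = pd.DataFrame(rows)
    metrics = per_repeat[["SE", "SP", "ACC", "AUC"]]
    n_na = int(metrics.isna().sum().sum())
    if n_na:
        logger.warning("%d undefined metric value(s) excluded from averages",
                       n_na)
    means = metrics.mean(skipna=True)
    pct = pd.DataFrame(
        {f"p{p}": metrics.quantile(p / 100.0) for p in PERCENTILES})
    return EvalReport(
        se=float(means["SE"]), sp=float(means["SP"]),
        acc=float(means["ACC"]), auc=float(means["AUC"]),
        per_repeat=per_repeat, percentiles=pct,
        roc=vertical_average_roc(curves), seed=seed,
        n_train_per_class=n_train_per_class, repeats=repeats,
        curves=curves)


def plot_roc(report: EvalReport, path) -> None:
    """Write the vertically averaged ROC with percentile bands (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roc = report.roc
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(roc["fpr"], roc["tpr_p10"], roc["tpr_p90"],
                    alpha=0.2, label="10-90 percentile")
    ax.fill_between(roc["fpr"], roc["tpr_p25"], roc["tpr_p75"],
                    alpha=0.35, label="25-75 percentile")
    ax.plot(roc["fpr"], roc["tpr_mean"], lw=2,
            label=f"vertical average (AUC={report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
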