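"""Per-recording aggregation, OSA severity grouping, screening and statistics.

Recordings are summarized by the mean of each per-minute index over valid
minutes, graded by apnea-hypopnea index (AHI: <5 normal, 5-30 mild-moderate,
>=30 severe), and screened normal-vs-apneic with either Fisher's linear
discriminant (default for a single index) or an SVM under stratified 2-fold
cross-validation.  Group differences use one-way ANOVA with Fisher's LSD
post-hoc; index-severity association uses the Pearson correlation with AHI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import NuSVC

__all__ = [
    "GroupLabel",
    "ScreeningMetrics",
    "GroupStats",
    "assign_group",
    "aggregate_recording",
    "FisherDiscriminant",
    "svm_2fold",
    "confusion_metrics",
    "roc_auc",
    "pearson_corr",
    "anova_lsd",
    "screen_cohort",
]

GROUP_ORDER = ("N", "MOSA", "SOSA")


@dataclass(frozen=True)
class GroupLabel:
    ahi: float
    group: str

    @property
    def apneic(self) -> bool:
        return self.group != "N"


def assign_group(ahi: float) -> GroupLabel:
    """Severity grade from AHI: N (<5), MOSA (5 <= AHI < 30), SOSA (>= 30)."""
    if ahi < 0:
        raise ValueError(f"AHI must be >= 0, got {ahi}")
    if ahi < 5:
        g = "N"
    elif ahi < 30:
        g = "MOSA"
    else:
        g = "SOSA"
    return GroupLabel(ahi=float(ahi), group=g)


def aggregate_recording(per_minute: pd.DataFrame, feature_cols=None) -> pd.Series:
    """Mean of each feature over valid minutes of one recording.

    Expects a ``valid`` boolean column; raises if no minute is valid.
    """
    valid = per_minute[per_minute["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("recording has zero valid minutes")
    if feature_cols is None:
        feature_cols = [
            c for c in valid.columns if c not in ("record_id", "minute", "valid")
        ]
    agg = valid[feature_cols].mean()
    agg["n_valid_minutes"] = len(valid)
    return agg


class FisherDiscriminant:
    """Two-class linear discriminant with equal priors.

    Projects onto ``w = Sw^-1 (mu1 - mu0)`` (pooled within-class covariance)
    and thresholds at the midpoint of the projected class means, so the
    decision is deterministic and balanced.  Works for a single feature
    (where it reduces to the midpoint-of-means rule) or several.
    """

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.asarray(y).size > 1:
            X = X.T
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("Fisher discriminant needs exactly two classes in training data")
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        if len(X0) < 2 or len(X1) < 2:
            raise ValueError("need >= 2 samples per class")
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        sw = np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1) + np.cov(
            X1, rowvar=False, ddof=1
        ) * (len(X1) - 1)
        sw = np.atleast_2d(sw)
        self.w_ = np.linalg.pinv(sw) @ (mu1 - mu0)
        self.threshold_ = float(self.w_ @ (mu0 + mu1) / 2.0)
        self.classes_ = classes
        return self

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w_.size:
            X = X.T
        return X @ self.w_ - self.threshold_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])


@dataclass(frozen=True)
class ScreeningMetrics:
    """Confusion counts with accuracy/sensitivity/specificity as percentages."""

    tp: int
    tn: int
    fp: int
    fn: int
    auc: float = float("nan")

    @property
    def acc(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")

    @property
    def sen(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def spe(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": round(self.acc, 1), "SEN": round(self.sen, 1),
            "SPE": round(self.spe, 1), "AUC": self.auc,
        }


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ScreeningMetrics:
    """Metrics from raw confusion counts (positives = apneic)."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if tp + tn + fp + fn == 0:
        raise ValueError("total count must be positive")
    return ScreeningMetrics(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _counts(y_true, y_pred) -> ScreeningMetrics:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return confusion_metrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def svm_2fold(features, labels, seed: int = 0) -> ScreeningMetrics:
    """Stratified 2-fold cross-validated SVM (NuSVC) screening metrics.

    Predictions from the two held-out folds are pooled into one confusion
    matrix; the split is controlled by ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y, minlength=2)) < 4:
        raise ValueError("need >= 2 samples per class per fold (>= 4 per class)")
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        clf = NuSVC(nu=0.5, kernel="rbf", gamma="scale")
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
    return _counts(y, pred)


def roc_auc(scores, labels) -> float:
    """AUC of the ROC; ties handled as in the Mann-Whitney statistic."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class GroupStats:
    """One-way ANOVA with Fisher's LSD post-hoc pairwise comparisons."""

    means: dict
    sds: dict
    ns: dict
    f_stat: float
    p_value: float
    lsd_p: dict = field(default_factory=dict)  # (group_a, group_b) -> p


def anova_lsd(groups: dict[str, np.ndarray]) -> GroupStats:
    """One-way ANOVA F test plus LSD pairwise t-tests on pooled within-group MSE.

    The LSD test uses t = (mi - mj) / sqrt(MSE (1/ni + 1/nj)) with the
    within-group degrees of freedom; it is the least conservative standard
    post-hoc (no multiplicity adjustment).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    n_tot = sum(a.size for a in arrs.values())
    df_w = n_tot - len(names)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    if ssw == 0:
        raise ValueError("zero within-group variance: ANOVA degenerate")
    mse = ssw / df_w
    f_stat, p_value = stats.f_oneway(*arrs.values())
    lsd = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = arrs[a], arrs[b]
            t = (xa.mean() - xb.mean()) / np.sqrt(mse * (1 / xa.size + 1 / xb.size))
            lsd[(a, b)] = float(2 * stats.t.sf(abs(t), df_w))
    return GroupStats(
        means={k: float(a.mean()) for k, a in arrs.items()},
        sds={k: float(a.std(ddof=1)) for k, a in arrs.items()},
        ns={k: int(a.size) for k, a in arrs.items()},
        f_stat=float(f_stat),
        p_value=float(p_value),
        lsd_p=lsd,
    )


def screen_cohort(
    aggregates: pd.DataFrame,
    index: str = "npsampen",
    classifier: str = "fisher",
    seed: int = 0,
) -> dict:
    """Full screening report for a cohort of per-recording aggregates.

    ``aggregates`` needs one row per recording with the index column and an
    ``ahi`` column.  Screening is normal (AHI < 5) vs. apneic.  Scores are
    oriented from the training-set class means so that apneic recordings
    score higher (entropy indices fall with severity, LF/HF rises), then fed
    to the ROC; Fisher's discriminant (resubstitution, as single-index
    screening is usually reported) or a 2-fold-CV SVM supplies the confusion
    counts.
    """
    vals = aggregates[index].to_numpy(dtype=float)
    ahi = aggregates["ahi"].to_numpy(dtype=float)
    y = np.array([1 if assign_group(a).apneic else 0 for a in ahi])
    flip = -1.0 if vals[y == 1].mean() < vals[y == 0].mean() else 1.0
    scores = flip * vals

    if classifier == "fisher":
        clf = FisherDiscriminant().fit(vals[:, None], y)
        m = _counts(y, clf.predict(vals[:, None]))
    elif classifier == "svm":
        m = svm_2fold(vals, y, seed=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    auc = roc_auc(scores, y)
    r, p = pearson_corr(vals, ahi)

    groups = {g: vals[[assign_group(a).group == g for a in ahi]] for g in GROUP_ORDER}
    groups = {g: v for g, v in groups.items() if v.size >= 2}
    gstats = anova_lsd(groups) if len(groups) >= 2 else None

    report = {
        "index": index,
        "classifier": classifier,
        "metrics": ScreeningMetrics(m.tp, m.tn, m.fp, m.fn, auc=auc).as_dict(),
        "pearson_r": r,
        "pearson_p": p,
    }
    if gstats is not None:
        report["group_means"] = gstats.means
        report["group_sds"] = gstats.sds
        report["anova_p"] = gstats.p_value
        report["lsd_p"] = {f"{a}_vs_{b}": v for (a, b), v in gstats.lsd_p.items()}
    return report
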