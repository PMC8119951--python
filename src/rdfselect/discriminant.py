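"""PC1-score discrimination: min-max integration, PCA projection, separation
testing and ROC / F-score evaluation.

The discriminant statistic is a subject's coordinate on the first principal
component of the combined, per-group min-max rescaled expression matrix.
:class:`PC1Discriminant` is a scikit-learn style estimator: ``fit`` performs
PCA (mean centering only, no variance scaling), ``decision_function`` returns
label-oriented PC1 scores usable for ROC analysis, and new cohorts are
projected through the stored mean and loadings as ``(X - mu) @ L``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.diagnostic import lilliefors

from .containers import CASE, CombinedDataset, ComparisonGroup, DataError

__all__ = [
    "minmax_rescale",
    "combine_groups",
    "PC1Discriminant",
    "fit_pc1_model",
    "separation_test",
    "roc_metrics",
    "best_f_threshold",
    "ClassifierMetrics",
]


def minmax_rescale(expression: pd.DataFrame) -> pd.DataFrame:
    """Rescale each gene (row) of one group's log2 matrix to [0, 1].

    ``(x - min) / (max - min)`` per gene; a gene constant within the group maps
    to the degenerate fill value 0.5.  The result is invariant to any affine
    transform of the input row.
    """
    X = expression.to_numpy(dtype=float)
    mn = X.min(axis=1, keepdims=True)
    mx = X.max(axis=1, keepdims=True)
    span = mx - mn
    out = np.where(span == 0, 0.5, (X - mn) / np.where(span == 0, 1.0, span))
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def combine_groups(
    groups: Sequence[ComparisonGroup], gene_set: Sequence[str]
) -> CombinedDataset:
    """Min-max rescale each group and row-concatenate into one dataset.

    Rescaling happens within each comparison group, which removes additive
    per-group (batch) offsets before the cohorts are integrated.
    """
    gene_set = list(gene_set)
    missing_report = {
        g.name: [x for x in gene_set if x not in g.expression.index] for g in groups
    }
    missing_report = {k: v for k, v in missing_report.items() if v}
    if missing_report:
        raise DataError(f"genes missing from groups: {missing_report}")
    blocks, labels, gids = [], [], []
    for g in groups:
        rescaled = minmax_rescale(g.expression.loc[gene_set])
        blocks.append(rescaled.T)
        labels.append(g.labels)
        gids.append(pd.Series(g.name, index=g.subjects))
    X = pd.concat(blocks, axis=0)
    return CombinedDataset(
        X=X,
        labels=pd.concat(labels).rename("label"),
        group_ids=pd.concat(gids).rename("group"),
    )


class PC1Discriminant(BaseEstimator):
    """First-principal-component case/control discriminant.

    ``fit`` runs PCA on the mean-centered matrix (no variance scaling; the
    input is assumed to be on a common [0, 1] scale already).  PC1 is oriented
    so that the gene with the largest absolute loading has a positive loading;
    when labels are supplied, a separate label orientation makes
    ``decision_function`` scores higher for cases, so one ROC convention works
    for tissues whose raw PC1 points either way.

    Attributes (after fit)
    ----------------------
    mean_ : ndarray, per-gene mean of the training matrix (``mu``)
    loadings_ : ndarray (n_genes, n_components), orthonormal, PC1 first (``L``)
    explained_variance_ratio_ : ndarray, non-increasing, sums to <= 1
    scores_ : ndarray, raw training PC1 scores ``(X - mu) @ L[:, 0]``
    score_min_, score_max_ : training min/max used to rescale scores to [0, 1]
    orientation_ : +1/-1, label orientation applied by ``decision_function``
    threshold_ : best-F decision threshold on oriented training scores
    """

    def __init__(self, positive_label=CASE):
        self.positive_label = positive_label

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise DataError("need a 2-D matrix with >= 2 subjects and >= 1 gene")
        if not np.isfinite(X).all():
            raise DataError("non-finite values in input matrix")
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = vt.T
        # deterministic sign convention: largest-|loading| entry positive
        flipped = []
        for k in range(loadings.shape[1]):
            j = int(np.argmax(np.abs(loadings[:, k])))
            if loadings[j, k] < 0:
                loadings[:, k] = -loadings[:, k]
                flipped.append(k)
        var = s**2 / (n - 1)
        total = var.sum()
        self.explained_variance_ratio_ = var / total if total > 0 else var
        self.loadings_ = loadings
        self.sign_convention_ = {"flipped_components": flipped}
        self.scores_ = Xc @ loadings[:, 0]
        self.score_min_ = float(self.scores_.min())
        self.score_max_ = float(self.scores_.max())
        self.orientation_ = 1.0
        if y is not None:
            y = np.asarray(y)
            case = y == self.positive_label if y.dtype.kind in "OU" else y.astype(bool)
            if case.all() or (~case).all():
                raise DataError("both labels must be present to orient the score")
            if self.scores_[case].mean() < self.scores_[~case].mean():
                self.orientation_ = -1.0
            oriented = self.orientation_ * self.scores_
            self.threshold_, self.train_metrics_ = best_f_threshold(oriented, case)
        return self

    # -- scoring ----------------------------------------------------------
    def score_samples(self, X) -> np.ndarray:
        """Raw PC1 scores ``(X - mu) @ L[:, 0]`` (sign convention, unoriented)."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_[:, 0]

    def transform(self, X) -> np.ndarray:
        return self.score_samples(X)[:, None]

    def decision_function(self, X) -> np.ndarray:
        """Label-oriented PC1 scores (higher = more case-like)."""
        return self.orientation_ * self.score_samples(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return self.decision_function(X) >= self.threshold_

    def rescale_scores(self, scores) -> np.ndarray:
        """Min-max rescale raw scores with the stored *training* min/max."""
        check_is_fitted(self, "score_min_")
        span = self.score_max_ - self.score_min_
        if span == 0:
            return np.full_like(np.asarray(scores, float), 0.5)
        return (np.asarray(scores, float) - self.score_min_) / span

    # -- persistence ------------------------------------------------------
    def to_dict(self, genes: Sequence[str] | None = None) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "genes": list(genes) if genes is not None else None,
            "mean": self.mean_.tolist(),
            "loadings": self.loadings_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "sign_convention": self.sign_convention_,
            "orientation": self.orientation_,
            "score_min": self.score_min_,
            "score_max": self.score_max_,
            "threshold": getattr(self, "threshold_", None),
        }

    def save(self, path: str | Path, genes: Sequence[str] | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(genes), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PC1Discriminant":
        model = cls()
        model.mean_ = np.asarray(d["mean"], float)
        model.loadings_ = np.asarray(d["loadings"], float)
        model.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], float)
        model.sign_convention_ = d["sign_convention"]
        model.orientation_ = float(d["orientation"])
        model.score_min_ = float(d["score_min"])
        model.score_max_ = float(d["score_max"])
        if d.get("threshold") is not None:
            model.threshold_ = float(d["threshold"])
        model.scores_ = None
        return model

    @classmethod
    def load(cls, path: str | Path) -> tuple["PC1Discriminant", list | None]:
        d = json.loads(Path(path).read_text())
        return cls.from_dict(d), d.get("genes")


def fit_pc1_model(data: CombinedDataset) -> tuple[PC1Discriminant, pd.DataFrame]:
    """Fit the PC1 discriminant on a combined dataset.

    Returns the fitted model and a score table (subject, group, label, raw and
    [0, 1]-rescaled PC1 score).
    """
    model = PC1Discriminant().fit(data.X.to_numpy(float), data.labels.to_numpy())
    scores = pd.DataFrame(
        {
            "group": data.group_ids,
            "label": data.labels,
            "pc1_raw": model.scores_,
            "pc1_rescaled": model.rescale_scores(model.scores_),
        },
        index=data.X.index,
    )
    return model, scores


def separation_test(
    scores, labels, context: str = "standalone", positive_label=CASE
) -> tuple[float, str]:
    """Case/control separation p-value for PC1 scores.

    ``context="rdfs"`` always uses the two-sample (Student) t-test, the
    standardized comparison inside the search loop.  ``context="standalone"``
    first checks normality of each label group with a Lilliefors test and
    falls back to the Mann-Whitney U test when normality is rejected
    (p < 0.05) in either group.  Both tests are invariant to affine rescaling
    of the scores.  Returns ``(p, test_name)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = labels == positive_label if labels.dtype.kind in "OU" else labels.astype(bool)
    a, b = scores[case], scores[~case]
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >= 2 subjects per label for a separation test")
    if context == "rdfs":
        res = stats.ttest_ind(a, b)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        return p, "t-test"
    if context != "standalone":
        raise ValueError(f"unknown context {context!r}")
    normal = all(lilliefors(x, dist="norm")[1] >= 0.05 for x in (a, b) if len(x) >= 4)
    if not normal:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), "mann-whitney"
    res = stats.ttest_ind(a, b)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return p, "t-test"


@dataclass
class ClassifierMetrics:
    """ROC curve, AUC and (optionally) fixed-threshold metrics."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float | None = None
    f_score: float | None = None
    tpr_at: float | None = None
    fpr_at: float | None = None
    ppv_at: float | None = None

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def roc_metrics(scores, labels, positive_label=CASE) -> ClassifierMetrics:
    """ROC over all score thresholds with trapezoid AUC.

    The AUC equals the tie-corrected Mann-Whitney statistic U / (n1 * n2);
    scores are expected to be oriented so cases score high (as produced by
    :meth:`PC1Discriminant.decision_function`).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label if labels.dtype.kind in "OU" else labels.astype(bool)
    if y.all() or (~y).all():
        raise DataError("both labels required for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassifierMetrics(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def best_f_threshold(scores, labels, positive_label=CASE) -> tuple[float, ClassifierMetrics]:
    """Threshold maximizing the F-score (harmonic mean of TPR and PPV).

    Candidates are the midpoints between consecutive sorted unique scores plus
    +/- infinity; a subject is called positive when its score is >= the
    threshold.  Ties in F are broken toward the candidate with the larger gap
    between its neighbouring scores.  F-scores are meant to be computed on
    training subjects only.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label if labels.dtype.kind in "OU" else labels.astype(bool)
    if y.all() or (~y).all():
        raise DataError("both labels required to choose a threshold")
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    gaps = np.diff(u)
    cands = np.concatenate(([-np.inf], mids, [np.inf]))
    margins = np.concatenate(([0.0], gaps, [0.0]))
    n_pos = int(y.sum())
    best = (-1.0, -1.0, 0)  # (F, margin, -index) ordering
    best_stats = None
    for i, t in enumerate(cands):
        pred = scores >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        tpr = tp / n_pos
        ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
        f = 2 * tpr * ppv / (tpr + ppv) if tpr + ppv > 0 else 0.0
        key = (f, margins[i])
        if key > best[:2]:
            best = (f, margins[i], i)
            fprt = fp / int((~y).sum())
            best_stats = (float(t), f, tpr, fprt, ppv)
    t, f, tpr, fprt, ppv = best_stats
    base = roc_metrics(scores, y)
    base.threshold, base.f_score, base.tpr_at, base.fpr_at, base.ppv_at = t, f, tpr, fprt, ppv
    return t, base
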