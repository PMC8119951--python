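"""External-cohort validation of a fitted PC1 discriminant.

A validation cohort is min-max rescaled within itself, genes missing from its
platform are imputed from the training cohorts, and subjects are projected
through the stored model as ``S_val = (X_val - mu) @ L``.  Direction
concordance compares per-gene regulation (log2 fold-change sign) in the
validation cohort with the reference up/down calls.

Leakage note: the faithful ``label_mean`` imputation fills a missing gene
with the training mean of subjects sharing the validation subject's *disease
label*, which uses the label being predicted; every output produced under
this mode carries an explicit leakage warning.  ``overall_mean`` is the
leakage-safe alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CASE, CombinedDataset, DataError
from .discriminant import PC1Discriminant, roc_metrics
from .preprocess import bh_adjust

__all__ = [
    "LeakageWarning",
    "impute_missing_genes",
    "project_cohort",
    "direction_concordance",
    "ProjectionResult",
]

IMPUTATION_MODES = ("label_mean", "overall_mean")


class LeakageWarning(UserWarning):
    """Emitted when label-aware imputation reads the labels being predicted."""


@dataclass
class ProjectionResult:
    """Validation-cohort PC1 scores and performance."""

    scores: pd.DataFrame            # subject x (pc1_raw, pc1_rescaled[, label])
    auc: float | None
    imputed_genes: list
    imputation_mode: str | None
    leakage_warning: bool

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "imputed_genes": list(self.imputed_genes),
            "imputation_mode": self.imputation_mode,
            "leakage_warning": self.leakage_warning,
        }


def impute_missing_genes(
    X_val: pd.DataFrame,
    model_genes,
    training_data: CombinedDataset,
    labels: pd.Series | None = None,
    mode: str = "label_mean",
) -> tuple[pd.DataFrame, list]:
    """Fill genes absent from a rescaled validation matrix (subjects x genes).

    ``label_mean`` fills each missing gene with the training mean among
    subjects of the same disease label (requires validation labels; emits a
    :class:`LeakageWarning`); ``overall_mean`` uses the pooled training mean.
    Returns the completed matrix (model gene order) and the imputed gene list.
    """
    if mode not in IMPUTATION_MODES:
        raise ValueError(f"mode must be one of {IMPUTATION_MODES}, got {mode!r}")
    model_genes = list(model_genes)
    missing = [g for g in model_genes if g not in X_val.columns]
    if not missing:
        return X_val.loc[:, model_genes], []
    absent = [g for g in missing if g not in training_data.X.columns]
    if absent:
        raise DataError(f"genes missing from the training cohorts too: {absent}")
    out = X_val.copy()
    if mode == "label_mean":
        if labels is None:
            raise DataError("label_mean imputation requires validation labels")
        warnings.warn(
            "label_mean imputation reads the validation labels being predicted",
            LeakageWarning,
        )
        train_case = training_data.case_mask
        val_case = (labels == CASE).to_numpy()
        for g in missing:
            col = training_data.X[g].to_numpy(float)
            fill = np.where(val_case, col[train_case].mean(), col[~train_case].mean())
            out[g] = fill
    else:
        for g in missing:
            out[g] = training_data.X[g].to_numpy(float).mean()
    return out.loc[:, model_genes], missing


def project_cohort(
    X_val: pd.DataFrame,
    model: PC1Discriminant,
    model_genes,
    labels: pd.Series | None = None,
    imputed_genes: list | None = None,
    imputation_mode: str | None = None,
) -> ProjectionResult:
    """Project a completed validation matrix through the fitted model.

    Scores are ``(X_val - mu) @ L`` with PC1 extracted, then min-max rescaled
    with the *training* score range so selection and validation subjects stay
    on one scale.  AUC is computed when labels are available.
    """
    model_genes = list(model_genes)
    if list(X_val.columns) != model_genes:
        extra = [g for g in X_val.columns if g not in model_genes]
        missing = [g for g in model_genes if g not in X_val.columns]
        raise DataError(
            f"validation genes do not match model genes (missing={missing}, extra={extra})"
        )
    raw = model.score_samples(X_val.to_numpy(float))
    scores = pd.DataFrame(
        {"pc1_raw": raw, "pc1_rescaled": model.rescale_scores(raw)}, index=X_val.index
    )
    auc = None
    if labels is not None:
        scores["label"] = labels
        auc = roc_metrics(model.orientation_ * raw, labels.to_numpy()).auc
    return ProjectionResult(
        scores=scores,
        auc=auc,
        imputed_genes=list(imputed_genes or []),
        imputation_mode=imputation_mode,
        leakage_warning=imputation_mode == "label_mean",
    )


def direction_concordance(
    validation_deg: pd.DataFrame, reference_directions: pd.Series
) -> pd.DataFrame:
    """Per-gene regulation-direction agreement with the reference calls.

    ``reference_directions`` maps gene -> "up"/"down".  A gene is concordant
    iff its validation log2 fold-change sign matches the reference direction;
    a zero fold change is non-concordant by convention.  BH q-values over the
    shared genes' validation p-values are reported alongside.
    """
    shared = [g for g in reference_directions.index if g in validation_deg.index]
    if not shared:
        raise DataError("no shared genes between validation DEGs and reference")
    sub = validation_deg.loc[shared]
    fc = sub["log2fc"].to_numpy(float)
    ref = reference_directions.loc[shared].to_numpy()
    concordant = ((fc > 0) & (ref == "up")) | ((fc < 0) & (ref == "down"))
    return pd.DataFrame(
        {
            "direction_ref": ref,
            "log2fc_val": fc,
            "concordant": concordant,
            "p": sub["p"].to_numpy(float),
            "q": bh_adjust(sub["p"].to_numpy(float)),
        },
        index=pd.Index(shared, name="gene"),
    )
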