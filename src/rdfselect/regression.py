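"""Gene-phenotype multiple linear regression with collinearity screening and
effect-modification analysis.

Gene expression (log2) is the response; an exposure (lung function as FEV1 %
predicted, or lung damage as % emphysema) plus adjustment covariates are the
predictors.  Categorical covariates are coded as dichotomous indicators.
Predictors are screened with the variance inflation factor (VIF); collinear
exposures (VIF > 2) are never co-included and get separate models.  A
categorical variable is an effect modifier when its strata show different
exposure effects (opposite slope signs, or significance in only a strict
subset of strata) and at least one stratum association is significant, in
which case stratified fits are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import DataError
from .preprocess import bh_adjust

__all__ = [
    "RegressionSpec",
    "compute_vif",
    "detect_effect_modifiers",
    "fit_gene_regressions",
    "VIF_THRESHOLD",
]

VIF_THRESHOLD = 2.0


@dataclass
class RegressionSpec:
    """What to regress on what.

    ``exposure`` is the single variable of interest; ``covariates`` are the
    adjustment terms (categorical ones are dummy-coded); ``strata`` optionally
    names a categorical variable driving separate per-category fits.
    """

    exposure: str
    covariates: list = field(default_factory=list)
    strata: str | None = None


def _dummy_design(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric design matrix with categorical columns dummy-coded (drop-first)."""
    parts = []
    for c in columns:
        col = data[c]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(col.astype(float).to_frame(c))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)


def compute_vif(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per predictor.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from regressing
    predictor *j* (with intercept) on the remaining predictors.  A perfectly
    collinear predictor is reported as ``inf``.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise DataError("VIF needs >= 2 predictors")
    if n <= p:
        raise DataError("VIF needs more subjects than predictors")
    vifs = []
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        if tss == 0:
            vifs.append(np.inf)  # constant predictor: aliased with the intercept
            continue
        r2 = 1.0 - float((resid**2).sum()) / tss
        vifs.append(np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"vif": vifs}, index=design.columns)
    out["flag"] = out["vif"] > VIF_THRESHOLD
    return out


def _ols(y: np.ndarray, design: pd.DataFrame):
    X = sm.add_constant(design.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify the first column whose removal restores full column rank
        for c in design.columns:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                raise DataError(f"design is rank deficient; column {c!r} is aliased")
        raise DataError("design is rank deficient")
    return sm.OLS(y, X).fit()


def detect_effect_modifiers(
    data: pd.DataFrame,
    response: str,
    exposure: str,
    covariates=(),
    candidates=(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratified screens for effect modification of the exposure-gene slope.

    For each candidate categorical variable, the exposure association is fit
    within every category (adjusted for the remaining covariates).  The
    variable is flagged a modifier iff the stratum slopes differ in sign or
    only a strict subset of strata is significant, AND at least one stratum
    has p < ``alpha``.  Strata with too few subjects are skipped with a
    warning.
    """
    rows = []
    for cand in candidates:
        strata_fits = []
        adj = [c for c in covariates if c != cand]
        for level, sub in data.groupby(cand, observed=True):
            design = _dummy_design(sub, [exposure] + adj)
            if len(sub) < design.shape[1] + 2:
                warnings.warn(
                    f"stratum {cand}={level!r} has too few subjects; skipped"
                )
                continue
            fit = _ols(sub[response].to_numpy(float), design)
            strata_fits.append(
                (level, float(fit.params[exposure]), float(fit.pvalues[exposure]))
            )
        if len(strata_fits) < 2:
            continue
        slopes = np.array([s for _, s, _ in strata_fits])
        pvals = np.array([p for _, _, p in strata_fits])
        sig = pvals < alpha
        differs = (len(set(np.sign(slopes))) > 1) or (sig.any() and not sig.all())
        is_modifier = bool(differs and sig.any())
        for level, slope, p in strata_fits:
            rows.append(
                {
                    "candidate": cand,
                    "stratum": level,
                    "slope": slope,
                    "p": p,
                    "modifier": is_modifier,
                }
            )
    return pd.DataFrame(rows)


def fit_gene_regressions(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: RegressionSpec,
    genes=None,
) -> pd.DataFrame:
    """OLS of each gene's log2 expression on the exposure + covariates.

    ``expression`` is genes x subjects; ``metadata`` is subjects x variables.
    When ``spec.strata`` is set, a separate model is fit per category.
    Returns one row per gene (and stratum): exposure estimate, SE, two-sided
    p, plus BH q-values across genes within each stratum.
    """
    genes = list(genes) if genes is not None else list(expression.index)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise DataError(f"genes absent from expression matrix: {missing}")
    if spec.exposure not in metadata.columns:
        raise DataError(f"exposure {spec.exposure!r} absent from metadata")
    strata_iter = (
        [(None, metadata)]
        if spec.strata is None
        else list(metadata.groupby(spec.strata, observed=True))
    )
    rows = []
    for level, meta in strata_iter:
        design = _dummy_design(meta, [spec.exposure] + list(spec.covariates))
        for g in genes:
            y = expression.loc[g, meta.index].to_numpy(float)
            fit = _ols(y, design)
            rows.append(
                {
                    "gene": g,
                    "stratum": level if level is not None else "all",
                    "term": spec.exposure,
                    "estimate": float(fit.params[spec.exposure]),
                    "se": float(fit.bse[spec.exposure]),
                    "p": float(fit.pvalues[spec.exposure]),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for level in out["stratum"].unique():
        m = out["stratum"] == level
        out.loc[m, "q"] = bh_adjust(out.loc[m, "p"].to_numpy())
    return out
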