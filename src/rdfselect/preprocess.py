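"""Array preprocessing: background correction, quantile normalization, probe
collapse, per-group differential testing and demographic matching checks.

The normalization chain for one-color arrays is applied consecutively:
normexp background correction -> quantile normalization -> log2.  Probes are
then filtered (controls and unmapped removed) and collapsed to one probe per
gene by the highest-mean rule.  Differential expression within a comparison
group is a per-gene two-sample t-test on log2 values with Benjamini-Hochberg
adjusted q-values reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr
from statsmodels.stats.multitest import multipletests

from .containers import ComparisonGroup, DataError, ProbeMatrix

__all__ = [
    "normexp_background_correct",
    "quantile_normalize",
    "collapse_probes",
    "group_deg_test",
    "bh_adjust",
    "demographic_match_check",
    "normalize_chain",
]


def _normexp_moments(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments fit of the normal+exponential convolution.

    Model: observed ``X = S + B`` with signal ``S ~ Exp(mean alpha)`` and
    background ``B ~ N(mu, sigma^2)``.  Moments: ``E X = mu + alpha``,
    ``Var X = sigma^2 + alpha^2``, third central moment ``= 2 alpha^3``.
    """
    m = float(np.mean(x))
    v = float(np.var(x))
    m3 = float(np.mean((x - m) ** 3))
    alpha = max(np.cbrt(max(m3, 1e-12) / 2.0), 1e-6)
    sigma2 = max(v - alpha**2, 1e-12)
    mu = m - alpha
    return mu, np.sqrt(sigma2), alpha


def normexp_background_correct(
    intensities: pd.DataFrame | np.ndarray,
) -> pd.DataFrame | np.ndarray:
    """Background-correct linear-scale intensities column by column.

    Each column (array) is fit by the normal+exponential convolution via the
    method of moments, and every intensity ``x`` is replaced by the posterior
    expected signal ``E[S | X = x]``, which is strictly positive and monotone
    increasing in ``x``.
    """
    is_frame = isinstance(intensities, pd.DataFrame)
    X = intensities.to_numpy(dtype=float) if is_frame else np.asarray(intensities, float)
    if not np.isfinite(X).all() or (X < 0).any():
        raise DataError("intensities must be finite and non-negative")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            name = intensities.columns[j] if is_frame else j
            raise DataError(f"column {name!r} has zero variance; cannot fit background")
        mu, sigma, alpha = _normexp_moments(col)
        # posterior mean of a positive exponential signal under Gaussian noise:
        # E[S|x] = sigma * h(z), z = (x - mu - sigma^2/alpha)/sigma, with
        # h(z) = z + phi(z)/Phi(z) > 0 (inverse Mills ratio shift)
        z = (col - mu - sigma**2 / alpha) / sigma
        h = z + np.exp(stats.norm.logpdf(z) - log_ndtr(z))
        deep = z < -6  # asymptotic branch avoids catastrophic cancellation
        if deep.any():
            t = np.where(deep, -z, 1.0)
            h = np.where(deep, (1.0 - 2.0 / t**2) / t, h)
        out[:, j] = sigma * h
    out = np.maximum(out, np.finfo(float).tiny)
    if is_frame:
        return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)
    return out


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Quantile-normalize columns to the mean distribution of order statistics.

    Each column is replaced by the cross-column means of the order statistics,
    assigned by within-column rank; tied values within a column receive the
    mean of the target values spanned by their rank run.  Afterwards all
    columns share one sorted value multiset (exactly so when there are no
    ties).
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, float)
    if np.isnan(X).any():
        raise DataError("quantile normalization requires complete data")
    n = X.shape[0]
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sc = col[order]
        vals = target.copy()
        run_breaks = np.flatnonzero(np.diff(sc) != 0) + 1
        starts = np.concatenate(([0], run_breaks))
        ends = np.concatenate((run_breaks, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                vals[s:e] = target[s:e].mean()
        out[order, j] = vals
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def collapse_probes(pm: ProbeMatrix) -> pd.DataFrame:
    """Filter and collapse a probe matrix to one row per gene.

    Control probes and probes without a gene id are removed; among probes
    sharing a gene id, only the one with the highest mean intensity over all
    samples is kept (ties resolved to the first probe in input order).
    """
    ann = pm.annotation
    keep = (~ann["is_control"].astype(bool)) & ann["gene_id"].notna()
    if not keep.any():
        raise DataError("no probes remain after removing controls and unmapped probes")
    inten = pm.intensities.loc[keep[keep].index]
    gene_ids = ann.loc[keep[keep].index, "gene_id"]
    means = inten.mean(axis=1)
    best = means.groupby(gene_ids, sort=False).idxmax()  # first max wins ties
    out = inten.loc[best.to_numpy()]
    out.index = pd.Index(best.index, name="gene")
    return out


def normalize_chain(pm: ProbeMatrix) -> pd.DataFrame:
    """normexp background correction -> quantile normalization -> log2 -> collapse.

    Returns a genes x samples log2 expression matrix.
    """
    corrected = normexp_background_correct(pm.intensities)
    normalized = quantile_normalize(corrected)
    # collapse on the linear scale (the highest-mean rule refers to intensities)
    collapsed = collapse_probes(ProbeMatrix(intensities=normalized, annotation=pm.annotation))
    return np.log2(collapsed)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_deg_test(group: ComparisonGroup, test_variant: str = "student") -> pd.DataFrame:
    """Per-gene differential test for one comparison group.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (case minus
    control mean of log2 values), ``p`` (two-sample t-test; Student pooled by
    default, Welch with ``test_variant="welch"``) and ``q`` (BH-adjusted).
    A gene constant within both labels with equal means gets p = 1.
    """
    if test_variant not in ("student", "welch"):
        raise ValueError(f"unknown test variant {test_variant!r}")
    case = group.case_mask
    X = group.expression.to_numpy(dtype=float)
    a, b = X[:, case], X[:, ~case]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataError(f"group {group.name}: need >= 2 subjects per label")
    res = stats.ttest_ind(a, b, axis=1, equal_var=(test_variant == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance + equal means
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": bh_adjust(p)}, index=group.genes
    )


def demographic_match_check(group: ComparisonGroup) -> pd.DataFrame:
    """Case/control matching p-values for age, pack-years, FEV1 and gender.

    Continuous covariates are compared with a two-sample t-test; gender with
    Fisher's exact test on the 2x2 label x gender table.  Covariates missing
    from the group are reported as unavailable rather than raising.
    """
    case = group.case_mask
    rows = []
    for var in ("age", "pack_years", "fev1_pct_pred"):
        if var not in group.covariates.columns:
            rows.append({"variable": var, "test": "t-test", "p": np.nan, "available": False})
            continue
        vals = group.covariates[var].to_numpy(dtype=float)
        res = stats.ttest_ind(vals[case], vals[~case])
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        rows.append({"variable": var, "test": "t-test", "p": p, "available": True})
    if "gender" in group.covariates.columns:
        gender = group.covariates["gender"].astype(str)
        table = np.array(
            [
                [(gender[case] == "male").sum(), (gender[case] == "female").sum()],
                [(gender[~case] == "male").sum(), (gender[~case] == "female").sum()],
            ]
        )
        _, p = stats.fisher_exact(table)
        rows.append({"variable": "gender", "test": "fisher", "p": float(p), "available": True})
    else:
        rows.append({"variable": "gender", "test": "fisher", "p": np.nan, "available": False})
    return pd.DataFrame(rows)
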