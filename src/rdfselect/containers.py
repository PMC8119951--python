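"""Shared in-memory containers for multi-cohort case/control expression studies.

The unit of analysis is the *comparison group*: one cohort's expression matrix
together with per-subject disease labels and clinical covariates.  Comparison
groups of the same lung sample type (tissue) share a gene universe and are the
inputs to per-group differential testing, cross-group consistency voting and
min-max integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "COPD"
CONTROL = "control"

#: clinical covariate columns expected (where available) in ComparisonGroup.covariates
COVARIATE_COLUMNS = ("age", "gender", "pack_years", "fev1_pct_pred")


class ConfigurationError(ValueError):
    """Invalid configuration; message names the offending field."""


class DataError(ValueError):
    """Structurally invalid data (mismatched genes, missing labels, ...)."""


@dataclass
class ComparisonGroup:
    """One cohort: log2 expression (genes x subjects) + labels + covariates.

    Parameters
    ----------
    name : str
        Group identifier, e.g. ``"WLT1"`` or ``"AE3"``.
    tissue : str
        Lung sample type, ``"WLT"`` (whole lung tissue) or ``"AE"``
        (airway epithelium).
    smoking_status : str
        ``"FS"`` (former smoker) or ``"CS"`` (current smoker); cases and
        controls within a group share it by construction.
    expression : pandas.DataFrame
        Genes in rows, subjects in columns, log2 scale.
    labels : pandas.Series
        Per subject, ``"COPD"`` or ``"control"``; index equals the
        expression columns.
    covariates : pandas.DataFrame
        Per-subject clinical covariates (age, gender, pack_years,
        fev1_pct_pred, optionally pct_emphysema); index equals the
        expression columns.  May be empty.
    """

    name: str
    tissue: str
    smoking_status: str
    expression: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        subjects = self.expression.columns
        if not self.labels.index.equals(subjects):
            raise DataError(
                f"group {self.name}: label index does not match expression columns"
            )
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"group {self.name}: unknown labels {sorted(bad)}")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise DataError(f"group {self.name}: non-finite expression values")
        if len(self.covariates) and not self.covariates.index.equals(subjects):
            raise DataError(
                f"group {self.name}: covariate index does not match expression columns"
            )

    @property
    def subjects(self) -> pd.Index:
        return self.expression.columns

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()

    def n_subjects(self) -> int:
        return self.expression.shape[1]


@dataclass
class ProbeMatrix:
    """Probe-level linear-scale intensities plus probe annotation.

    ``annotation`` is indexed by probe id with columns ``gene_id`` (nullable)
    and ``is_control`` (bool).
    """

    intensities: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise DataError("duplicate probe ids in intensity matrix")
        if not self.intensities.index.equals(self.annotation.index):
            raise DataError("annotation index does not match intensity probes")
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise DataError("non-finite probe intensities")


@dataclass
class CombinedDataset:
    """Cross-cohort integrated matrix: subjects x genes, min-max rescaled.

    Every gene was rescaled to [0, 1] *within its comparison group* before the
    groups were row-concatenated, which removes per-group location/scale
    (batch) differences.
    """

    X: pd.DataFrame          # subjects x genes, values in [0, 1]
    labels: pd.Series        # subject -> COPD | control
    group_ids: pd.Series     # subject -> comparison-group name

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.X.index):
            raise DataError("combined dataset: label index mismatch")
        if not self.group_ids.index.equals(self.X.index):
            raise DataError("combined dataset: group-id index mismatch")

    @property
    def genes(self) -> pd.Index:
        return self.X.columns

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == CASE).to_numpy()

    def restrict(self, genes) -> "CombinedDataset":
        """Return a copy restricted (and ordered) to ``genes``."""
        missing = [g for g in genes if g not in self.X.columns]
        if missing:
            raise DataError(f"genes absent from combined dataset: {missing}")
        return CombinedDataset(self.X.loc[:, list(genes)], self.labels, self.group_ids)
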