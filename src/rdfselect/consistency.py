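"""Cross-cohort consistency selection of disease-associated genes.

A gene is retained only if it is (1) significantly differential in at least
``min_groups`` comparison groups of the tissue and (2) shows the same log2
fold-change sign in at least ``min_groups`` groups.  Two readings of the
combination are supported:

* ``joint`` (default, stricter): one witness set of >= ``min_groups`` groups
  must carry *both* significance and a common sign simultaneously.
* ``independent``: the two criteria are evaluated on possibly different
  groups; both must hold.

For a tissue with exactly ``min_groups`` groups the two modes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import DataError

MODES = ("joint", "independent")


@dataclass
class ConsistencySelection:
    """Selected genes with per-gene voting evidence.

    ``evidence`` is indexed by gene with columns ``n_significant``,
    ``sign_<group>`` (one per group, "+", "-" or "0"), ``mean_log2fc``,
    ``direction`` ("up"/"down") and ``selected``.
    """

    tissue: str
    min_groups: int
    mode: str
    alpha: float
    genes: list[str]
    evidence: pd.DataFrame


def _stacked(deg_tables: Mapping[str, pd.DataFrame]) -> tuple[list[str], pd.Index, np.ndarray, np.ndarray]:
    names = list(deg_tables)
    genes = deg_tables[names[0]].index
    for name in names[1:]:
        if not deg_tables[name].index.equals(genes):
            raise DataError(f"DEG table {name!r} has a different gene universe")
    P = np.column_stack([deg_tables[n]["p"].to_numpy(float) for n in names])
    FC = np.column_stack([deg_tables[n]["log2fc"].to_numpy(float) for n in names])
    return names, genes, P, FC


def select_consistent_degs(
    deg_tables: Mapping[str, pd.DataFrame],
    tissue: str,
    min_groups: int = 3,
    mode: str = "joint",
    alpha: float = 0.05,
) -> ConsistencySelection:
    """Apply the two cross-cohort criteria to per-group DEG tables.

    ``deg_tables`` maps comparison-group name to a table with ``log2fc`` and
    ``p`` columns on one shared gene universe.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(deg_tables) < min_groups:
        raise DataError(
            f"need >= {min_groups} DEG tables for tissue {tissue!r}, got {len(deg_tables)}"
        )
    names, genes, P, FC = _stacked(deg_tables)
    sig = P < alpha
    pos, neg = FC > 0, FC < 0
    n_sig = sig.sum(axis=1)
    if mode == "joint":
        keep = ((sig & pos).sum(axis=1) >= min_groups) | (
            (sig & neg).sum(axis=1) >= min_groups
        )
    else:
        same_sign = (pos.sum(axis=1) >= min_groups) | (neg.sum(axis=1) >= min_groups)
        keep = (n_sig >= min_groups) & same_sign
    mean_fc = FC.mean(axis=1)
    evidence = pd.DataFrame({"n_significant": n_sig}, index=genes)
    for j, name in enumerate(names):
        evidence[f"sign_{name}"] = np.where(pos[:, j], "+", np.where(neg[:, j], "-", "0"))
    evidence["mean_log2fc"] = mean_fc
    evidence["direction"] = np.where(mean_fc > 0, "up", "down")
    evidence["selected"] = keep
    return ConsistencySelection(
        tissue=tissue,
        min_groups=min_groups,
        mode=mode,
        alpha=alpha,
        genes=list(genes[keep]),
        evidence=evidence,
    )


def overlap_summary(
    deg_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    selection: ConsistencySelection | None = None,
) -> dict:
    """Venn-style overlap of per-group significant genes, plus up/down counts.

    Returns a dict with ``per_group`` (significant counts), ``venn`` (a Series
    mapping every non-empty group subset, keyed "A&B&...", to the number of
    genes significant in exactly that subset) and, when a selection is given,
    ``n_up``/``n_down`` counts of the selected genes by mean fold-change sign.
    """
    names, genes, P, _ = _stacked(deg_tables)
    sig = P < alpha
    membership = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(range(len(names)), r):
            in_subset = np.ones(len(genes), dtype=bool)
            for j in range(len(names)):
                in_subset &= sig[:, j] if j in subset else ~sig[:, j]
            membership["&".join(names[j] for j in subset)] = int(in_subset.sum())
    out = {
        "per_group": {n: int(sig[:, j].sum()) for j, n in enumerate(names)},
        "venn": pd.Series(membership, name="n_genes"),
    }
    if selection is not None:
        sel = selection.evidence.loc[selection.genes]
        out["n_up"] = int((sel["direction"] == "up").sum())
        out["n_down"] = int((sel["direction"] == "down").sum())
    return out
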