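"""Random depth-first search (RDFS) gene-set reduction.

The search minimizes the two-sample t-test p-value of case/control PC1 scores
by randomly removing single genes.  Starting from the full candidate set, a
random untried gene is tentatively removed, the PCA is refit on the reduced
set and the p-value recomputed; the removal is accepted only if the p-value
strictly decreases, in which case the search descends on that branch and the
untried pool is reset (a gene rejected earlier may become removable after the
set changes).  The search ends at a local optimum: no single-gene removal
decreases the p-value further.

Multi-run protocol: each run draws a fresh 90%/10% train/test split, executes
many independent search iterations on the training subjects, and keeps the
iteration with the lowest final p-value.  Genes present in *every* run's best
set form the persistent set.

Implementation note: only PC1 is needed inside the loop, so the top principal
direction is obtained by warm-started power iteration on the cached
covariance submatrix of the current gene set, with an exact symmetric
eigensolver as fallback; this matches a full PCA refit to high precision
(tested against full SVD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import stdtr
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .containers import CASE, CombinedDataset, DataError
from .discriminant import PC1Discriminant, best_f_threshold, roc_metrics

__all__ = [
    "RDFSTrace",
    "RDFSRunResult",
    "PersistenceResult",
    "rdfs_iteration",
    "run_search",
    "persistent_genes",
    "persistence_curve_export",
    "evaluate_gene_set",
    "RDFSSelector",
]


def _top_eigvec(C: np.ndarray, v0: np.ndarray | None = None,
                tol: float = 1e-13, max_iter: int = 400) -> np.ndarray:
    """Leading eigenvector of a PSD matrix by warm-started power iteration.

    Falls back to an exact symmetric eigensolver when convergence stalls
    (near-degenerate leading eigenvalues).
    """
    g = C.shape[0]
    if g == 1:
        return np.ones(1)
    if v0 is not None:
        nrm = np.linalg.norm(v0)
        v = v0 / nrm if nrm > 0 else None
    else:
        v = None
    if v is None:
        v = C.sum(axis=1)
        nrm = np.linalg.norm(v)
        v = v / nrm if nrm > 0 else np.full(g, 1.0 / np.sqrt(g))
    for _ in range(max_iter):
        w = C @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:  # C is (numerically) zero: any direction
            return v
        w /= nrm
        if w @ v < 0:
            w = -w
        delta = np.abs(w - v).max()
        v = w
        if delta < tol:
            return v
    _, vec = eigh(C, subset_by_index=(g - 1, g - 1))
    return vec[:, 0]


class _PC1TTest:
    """PC1-score pooled t-test objective on a fixed training matrix.

    Centers the candidate-gene matrix once and caches its covariance; the
    covariance of any gene subset is a submatrix, so each tentative removal
    costs one submatrix slice, a few power-iteration steps and a matvec.
    """

    def __init__(self, X: np.ndarray, case_mask: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.n, self.g = X.shape
        self.Xc = X - X.mean(axis=0)
        self.C = (self.Xc.T @ self.Xc) / (self.n - 1)
        self.case = np.asarray(case_mask, dtype=bool)
        self.ctrl = ~self.case
        self.n1 = int(self.case.sum())
        self.n2 = int(self.ctrl.sum())
        if self.n1 < 2 or self.n2 < 2:
            raise DataError("need >= 2 training subjects per label")
        self.df = self.n1 + self.n2 - 2

    def p_value(self, idx: np.ndarray, v0: np.ndarray | None = None
                ) -> tuple[float, np.ndarray]:
        """t-test p for the PC1 scores of the gene subset ``idx``."""
        C_sub = self.C[np.ix_(idx, idx)]
        v = _top_eigvec(C_sub, v0)
        s = self.Xc[:, idx] @ v
        a, b = s[self.case], s[self.ctrl]
        ma, mb = a.mean(), b.mean()
        va = a.var(ddof=1)
        vb = b.var(ddof=1)
        sp2 = ((self.n1 - 1) * va + (self.n2 - 1) * vb) / self.df
        se = np.sqrt(sp2 * (1.0 / self.n1 + 1.0 / self.n2))
        if se == 0:
            return (1.0 if ma == mb else 0.0), v
        t = (ma - mb) / se
        return 2.0 * float(stdtr(self.df, -abs(t))), v


@dataclass
class RDFSTrace:
    """Accepted-removal trace of one search iteration.

    ``steps`` holds ``(removed_gene, p_after_acceptance)`` in order; the tree
    depth is ``len(steps) + 1`` (the full set counts as depth 1, so the final
    set has N - depth + 1 genes).
    """

    initial_p: float
    steps: list = field(default_factory=list)
    rejected_attempts: int = 0

    @property
    def depth(self) -> int:
        return len(self.steps) + 1

    @property
    def final_p(self) -> float:
        return self.steps[-1][1] if self.steps else self.initial_p


def rdfs_iteration(
    X_train,
    case_mask,
    genes,
    rng: np.random.Generator,
    min_set_size: int = 2,
    _objective: _PC1TTest | None = None,
) -> tuple[list, RDFSTrace]:
    """One randomized depth-first elimination pass on training subjects only.

    ``X_train`` is the training-subject block (subjects x genes) of the
    combined rescaled matrix; test subjects must not be part of it.  Returns
    the locally optimal gene list and the acceptance trace.
    """
    genes = list(genes)
    if len(genes) < min_set_size:
        raise DataError(f"need >= {min_set_size} candidate genes")
    obj = _objective if _objective is not None else _PC1TTest(np.asarray(X_train, float), case_mask)
    if obj.g != len(genes):
        raise DataError("gene list does not match matrix width")
    idx = np.arange(len(genes))
    p_cur, v_cur = obj.p_value(idx)
    trace = RDFSTrace(initial_p=p_cur)
    if not np.isfinite(p_cur):
        warnings.warn("non-finite initial p-value; returning the full set")
        return genes, trace
    pool = list(rng.permutation(len(idx)))
    while len(idx) > min_set_size and pool:
        k = pool.pop(0)           # position within current idx
        removed = genes[idx[k]]
        cand = np.delete(idx, k)
        v0 = np.delete(v_cur, k)
        p_new, v_new = obj.p_value(cand, v0)
        if np.isfinite(p_new) and p_new < p_cur:
            idx, p_cur, v_cur = cand, p_new, v_new
            trace.steps.append((removed, p_new))
            pool = list(rng.permutation(len(idx)))
        else:
            trace.rejected_attempts += 1
            if not np.isfinite(p_new):
                warnings.warn("non-finite p-value for a tentative subset; treated as no improvement")
    final = [genes[i] for i in idx]
    return final, trace


def evaluate_gene_set(
    data: CombinedDataset,
    gene_list,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> dict:
    """Fit PC1 on the training rows of ``gene_list``, score train and test.

    Returns train/test AUC, the training separation p-value (t-test), the
    best-F threshold on training subjects and its metrics, plus the fitted
    model.
    """
    cols = [data.X.columns.get_loc(g) for g in gene_list]
    X = data.X.to_numpy(float)[:, cols]
    y = data.labels.to_numpy()
    model = PC1Discriminant().fit(X[train_idx], y[train_idx])
    s_train = model.decision_function(X[train_idx])
    s_test = model.decision_function(X[test_idx])
    train_roc = roc_metrics(s_train, y[train_idx])
    test_roc = roc_metrics(s_test, y[test_idx])
    thr, thr_metrics = best_f_threshold(s_train, y[train_idx])
    return {
        "model": model,
        "train_auc": train_roc.auc,
        "test_auc": test_roc.auc,
        "threshold": thr,
        "f_score": thr_metrics.f_score,
    }


@dataclass
class RDFSRunResult:
    """Result of one run: its split, per-iteration outcomes and best set."""

    run: int
    train_ids: list
    test_ids: list
    iteration_genes: list          # per iteration: final gene list
    iteration_p: list              # per iteration: final training p
    best_iteration: int
    best_genes: list
    best_p: float
    train_auc: float
    test_auc: float
    full_train_auc: float
    full_test_auc: float
    threshold: float
    f_score: float
    best_trace: RDFSTrace | None = None

    def to_dict(self) -> dict:
        d = {
            "run": self.run,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "iteration_p": [float(p) for p in self.iteration_p],
            "iteration_set_sizes": [len(g) for g in self.iteration_genes],
            "best_iteration": self.best_iteration,
            "best_genes": list(self.best_genes),
            "best_p": float(self.best_p),
            "train_auc": float(self.train_auc),
            "test_auc": float(self.test_auc),
            "full_train_auc": float(self.full_train_auc),
            "full_test_auc": float(self.full_test_auc),
            "threshold": float(self.threshold),
            "f_score": float(self.f_score),
        }
        return d


def _stratified_split(strata: np.ndarray, test_fraction: float, seed: int,
                      max_retries: int = 20) -> tuple[np.ndarray, np.ndarray]:
    n = len(strata)
    sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    train_idx, test_idx = next(sss.split(np.zeros(n), strata))
    return np.sort(train_idx), np.sort(test_idx)


def run_search(
    data: CombinedDataset,
    genes=None,
    n_runs: int = 10,
    n_iterations: int = 200,
    test_fraction: float = 0.1,
    min_set_size: int = 2,
    random_state: int = 0,
    keep_traces: bool = False,
) -> list[RDFSRunResult]:
    """Multi-run RDFS with per-run train/test splits.

    Splits are stratified by comparison group x disease label so both labels
    always appear in the held-out 10%.  All iterations of a run share the
    run's split and differ only in their RNG streams; the iteration with the
    lowest final training p-value becomes the run's best set, evaluated by
    AUC on training and held-out subjects.
    """
    if genes is None:
        genes = list(data.genes)
    else:
        genes = list(genes)
    data = data.restrict(genes)
    y = data.labels.to_numpy()
    case = data.case_mask
    strata = np.char.add(
        data.group_ids.to_numpy().astype(str), np.char.add("::", y.astype(str))
    )
    root = np.random.SeedSequence(random_state)
    run_seeds = root.spawn(n_runs)
    subjects = np.asarray(data.X.index)
    results = []
    for r in range(n_runs):
        kids = run_seeds[r].spawn(n_iterations + 1)
        split_seed = int(kids[0].generate_state(1)[0] % (2**31 - 1))
        train_idx, test_idx = _stratified_split(strata, test_fraction, split_seed)
        if len(set(y[test_idx])) < 2 or len(set(y[train_idx])) < 2:
            raise DataError("a split is missing one of the labels")
        Xtr = data.X.to_numpy(float)[train_idx]
        obj = _PC1TTest(Xtr, case[train_idx])
        iter_genes, iter_p, traces = [], [], []
        for i in range(n_iterations):
            rng = np.random.default_rng(kids[1 + i])
            final, trace = rdfs_iteration(
                Xtr, case[train_idx], genes, rng,
                min_set_size=min_set_size, _objective=obj,
            )
            iter_genes.append(final)
            iter_p.append(trace.final_p)
            traces.append(trace)
        best_i = int(np.argmin(iter_p))
        best_genes = iter_genes[best_i]
        best_eval = evaluate_gene_set(data, best_genes, train_idx, test_idx)
        full_eval = evaluate_gene_set(data, genes, train_idx, test_idx)
        results.append(
            RDFSRunResult(
                run=r,
                train_ids=list(subjects[train_idx]),
                test_ids=list(subjects[test_idx]),
                iteration_genes=iter_genes,
                iteration_p=iter_p,
                best_iteration=best_i,
                best_genes=best_genes,
                best_p=float(iter_p[best_i]),
                train_auc=best_eval["train_auc"],
                test_auc=best_eval["test_auc"],
                full_train_auc=full_eval["train_auc"],
                full_test_auc=full_eval["test_auc"],
                threshold=best_eval["threshold"],
                f_score=best_eval["f_score"],
                best_trace=traces[best_i] if keep_traces else None,
            )
        )
    return results


@dataclass
class PersistenceResult:
    """Genes surviving in every run's best set, plus the prefix-intersection curve."""

    genes: list
    curve: list  # curve[k-1] = |intersection of first k runs' best sets|


def persistent_genes(results: list[RDFSRunResult]) -> PersistenceResult:
    """Intersection of all runs' best sets, in first-run gene order."""
    if not results:
        raise DataError("need at least one run result")
    current = list(results[0].best_genes)
    curve = [len(current)]
    for res in results[1:]:
        member = set(res.best_genes)
        current = [g for g in current if g in member]
        curve.append(len(current))
    return PersistenceResult(genes=current, curve=curve)


def persistence_curve_export(pr: PersistenceResult) -> pd.DataFrame:
    """(k, intersection size) table; non-increasing in k."""
    return pd.DataFrame(
        {"n_runs": np.arange(1, len(pr.curve) + 1), "n_persistent": pr.curve}
    )


class RDFSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector wrapping the multi-run RDFS.

    ``fit(X, y)`` runs the full protocol on an array (optionally with a
    ``groups`` array of cohort ids; a single cohort is assumed otherwise) and
    exposes the persistent genes through the standard ``get_support`` /
    ``transform`` selector interface.

    Attributes
    ----------
    support_ : boolean mask of persistent features
    runs_ : list of :class:`RDFSRunResult`
    persistence_ : :class:`PersistenceResult`
    """

    def __init__(self, n_runs=10, n_iterations=200, test_fraction=0.1,
                 min_set_size=2, random_state=0):
        self.n_runs = n_runs
        self.n_iterations = n_iterations
        self.test_fraction = test_fraction
        self.min_set_size = min_set_size
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, g = X.shape
        self.n_features_in_ = g
        names = [f"f{j}" for j in range(g)]
        if y.dtype.kind in "OU":
            bad = set(np.unique(y)) - {CASE, "control"}
            if bad:
                raise DataError(f"string labels must be COPD/control, got {sorted(bad)}")
            lab = y.astype(str)
        else:
            lab = np.where(y.astype(bool), CASE, "control")
        labels = pd.Series(lab, index=pd.RangeIndex(n).astype(str))
        gids = pd.Series(
            np.asarray(groups).astype(str) if groups is not None else np.repeat("g0", n),
            index=labels.index,
        )
        data = CombinedDataset(
            X=pd.DataFrame(X, index=labels.index, columns=names),
            labels=labels, group_ids=gids,
        )
        self.runs_ = run_search(
            data,
            n_runs=self.n_runs,
            n_iterations=self.n_iterations,
            test_fraction=self.test_fraction,
            min_set_size=self.min_set_size,
            random_state=self.random_state,
        )
        self.persistence_ = persistent_genes(self.runs_)
        keep = {names.index(gname) for gname in self.persistence_.genes}
        self.support_ = np.array([j in keep for j in range(g)])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
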