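"""RDFS search invariants: objective correctness, monotone traces, local
optimality, determinism, persistence, and the selector wrapper."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdfselect import (
    CASE,
    CONTROL,
    DataError,
    RDFSSelector,
    combine_groups,
    generate_study,
    SimulationConfig,
    persistence_curve_export,
    persistent_genes,
    rdfs_iteration,
    run_search,
)
from rdfselect.containers import CombinedDataset
from rdfselect.discriminant import PC1Discriminant
from rdfselect.rdfs import RDFSRunResult, _PC1TTest, _top_eigvec


def _random_dataset(rng, n=40, g=12, shift=1.0):
    y = np.array([CASE] * (n // 2) + [CONTROL] * (n - n // 2))
    X = rng.random((n, g))
    X[: n // 2, : g // 3] += shift
    X = (X - X.min(0)) / np.ptp(X, axis=0)
    names = [f"G{j}" for j in range(g)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject")
    return CombinedDataset(
        X=pd.DataFrame(X, index=idx, columns=names),
        labels=pd.Series(y, index=idx),
        group_ids=pd.Series(["g0"] * n, index=idx),
    )


# ---------------------------------------------------------------------------
# objective: cached-covariance PC1 + t-test

def test_objective_matches_full_pca_and_scipy_ttest(rng):
    X = rng.random((30, 10))
    case = np.array([True] * 15 + [False] * 15)
    obj = _PC1TTest(X, case)
    for idx in (np.arange(10), np.array([0, 3, 4, 7]), np.array([2, 9])):
        p, v = obj.p_value(idx)
        model = PC1Discriminant().fit(X[:, idx])
        s = model.score_samples(X[:, idx])
        ref = stats.ttest_ind(s[case], s[~case], equal_var=True).pvalue
        assert p == pytest.approx(ref, abs=1e-8)
        # the returned direction spans the same axis as the full-PCA loading
        assert abs(abs(v @ model.loadings_[:, 0]) - 1.0) < 1e-8


def test_top_eigvec_matches_eigh(rng):
    for g in (2, 5, 12):
        A = rng.normal(size=(g + 3, g))
        C = A.T @ A / (g + 2)
        v = _top_eigvec(C)
        w, vecs = np.linalg.eigh(C)
        ref = vecs[:, -1]
        assert abs(abs(v @ ref) - 1.0) < 1e-8


def test_objective_warm_start_agrees_with_cold_start(rng):
    X = rng.random((25, 8))
    case = np.array([True] * 12 + [False] * 13)
    obj = _PC1TTest(X, case)
    idx = np.array([0, 1, 2, 5, 6])
    p_cold, v_cold = obj.p_value(idx)
    p_warm, _ = obj.p_value(idx, v0=v_cold + rng.normal(0, 0.05, size=5))
    assert p_warm == pytest.approx(p_cold, abs=1e-10)


# ---------------------------------------------------------------------------
# single iteration

def test_trace_p_strictly_decreasing(rng):
    data = _random_dataset(rng)
    case = (data.labels == CASE).to_numpy()
    final, trace = rdfs_iteration(data.X.to_numpy(), case, list(data.genes), rng)
    ps = [trace.initial_p] + [p for _, p in trace.steps]
    assert all(b < a for a, b in zip(ps, ps[1:]))
    assert len(final) == data.X.shape[1] - len(trace.steps)
    assert trace.depth == len(trace.steps) + 1
    # removed genes and surviving genes partition the candidates
    removed = [g for g, _ in trace.steps]
    assert sorted(removed + final) == sorted(data.genes)


def test_result_is_single_removal_local_optimum(rng):
    data = _random_dataset(rng, n=30, g=8)
    case = (data.labels == CASE).to_numpy()
    X = data.X.to_numpy()
    genes = list(data.genes)
    final, trace = rdfs_iteration(X, case, genes, rng)
    obj = _PC1TTest(X, case)
    idx = np.array([genes.index(g) for g in final])
    p_final, _ = obj.p_value(idx)
    assert p_final == pytest.approx(trace.final_p, abs=1e-12)
    if len(final) > 2:
        for k in range(len(idx)):
            p_k, _ = obj.p_value(np.delete(idx, k))
            assert p_k >= p_final


def test_min_set_size_respected(rng):
    data = _random_dataset(rng, n=30, g=5)
    case = (data.labels == CASE).to_numpy()
    final, _ = rdfs_iteration(
        data.X.to_numpy(), case, list(data.genes), rng, min_set_size=4
    )
    assert len(final) >= 4
    with pytest.raises(DataError):
        rdfs_iteration(data.X.to_numpy(), case, ["G0"], rng, min_set_size=2)


def test_iteration_deterministic_given_rng_state(rng):
    data = _random_dataset(rng, n=30, g=10)
    case = (data.labels == CASE).to_numpy()
    a = rdfs_iteration(data.X.to_numpy(), case, list(data.genes),
                       np.random.default_rng(5))
    b = rdfs_iteration(data.X.to_numpy(), case, list(data.genes),
                       np.random.default_rng(5))
    assert a[0] == b[0]
    assert a[1].steps == b[1].steps


# ---------------------------------------------------------------------------
# multi-run search

@pytest.fixture(scope="module")
def search_setup():
    cfg = SimulationConfig(
        n_genes=30, n_planted=6, n_decoy=2, effect_size=1.0,
        n_groups=2, n_cases_per_group=20, n_controls_per_group=20, seed=11,
    )
    study = generate_study(cfg)
    data = combine_groups(study.groups, list(study.genes))
    results = run_search(data, n_runs=4, n_iterations=8, random_state=3)
    return study, data, results


def test_run_search_structure(search_setup):
    study, data, results = search_setup
    assert len(results) == 4
    n = data.X.shape[0]
    for res in results:
        assert len(res.iteration_p) == 8
        assert res.best_p == min(res.iteration_p)
        assert res.best_genes == res.iteration_genes[res.best_iteration]
        # split partitions subjects, roughly 90/10
        assert sorted(res.train_ids + res.test_ids) == sorted(data.X.index)
        assert len(res.test_ids) == round(0.1 * n)
        # both labels present in held-out subjects
        test_labels = set(data.labels.loc[res.test_ids])
        assert test_labels == {CASE, CONTROL}
        assert 0.0 <= res.test_auc <= 1.0 and 0.0 <= res.train_auc <= 1.0


def test_run_search_deterministic(search_setup):
    study, data, results = search_setup
    again = run_search(data, n_runs=4, n_iterations=8, random_state=3)
    for a, b in zip(results, again):
        assert a.best_genes == b.best_genes
        assert a.iteration_p == b.iteration_p
        assert a.train_ids == b.train_ids
    other = run_search(data, n_runs=2, n_iterations=4, random_state=4)
    assert any(
        o.train_ids != r.train_ids or o.best_genes != r.best_genes
        for o, r in zip(other, results)
    )


def test_search_never_reads_test_subjects(search_setup):
    """Perturbing held-out rows must not change any search outcome."""
    study, data, results = search_setup
    X2 = data.X.copy()
    test_ids = results[0].test_ids
    X2.loc[test_ids] = np.random.default_rng(0).random((len(test_ids), X2.shape[1]))
    data2 = CombinedDataset(X=X2, labels=data.labels, group_ids=data.group_ids)
    res2 = run_search(data2, n_runs=1, n_iterations=8, random_state=3)
    assert res2[0].best_genes == results[0].best_genes
    assert res2[0].iteration_p == results[0].iteration_p
    assert res2[0].train_auc == results[0].train_auc


def test_run_result_to_dict_is_json_serializable(search_setup):
    import json

    _, _, results = search_setup
    d = results[0].to_dict()
    json.dumps(d)
    assert d["iteration_set_sizes"][d["best_iteration"]] == len(d["best_genes"])


# ---------------------------------------------------------------------------
# persistence

def test_persistent_genes_hand_example():
    def res(genes):
        return RDFSRunResult(
            run=0, train_ids=[], test_ids=[], iteration_genes=[genes],
            iteration_p=[0.1], best_iteration=0, best_genes=genes, best_p=0.1,
            train_auc=1, test_auc=1, full_train_auc=1, full_test_auc=1,
            threshold=0, f_score=1,
        )

    pr = persistent_genes([res(["a", "b", "c"]), res(["c", "a"]), res(["a", "d", "c"])])
    assert pr.genes == ["a", "c"]
    assert pr.curve == [3, 2, 2]
    tab = persistence_curve_export(pr)
    assert list(tab["n_runs"]) == [1, 2, 3]
    assert (np.diff(tab["n_persistent"]) <= 0).all()


def test_persistent_subset_of_every_best_set(search_setup):
    _, _, results = search_setup
    pr = persistent_genes(results)
    for res in results:
        assert set(pr.genes) <= set(res.best_genes)
    assert pr.curve[-1] == len(pr.genes)


def test_planted_genes_dominate_persistent_set(search_setup):
    study, _, results = search_setup
    pr = persistent_genes(results)
    planted = set(study.genes_with_role("planted"))
    if pr.genes:  # precision of the persistent set on an easy synthetic study
        precision = len(set(pr.genes) & planted) / len(pr.genes)
        assert precision >= 0.5


# ---------------------------------------------------------------------------
# sklearn selector

def test_selector_sklearn_interface(rng):
    X = rng.random((40, 10))
    y = np.array([1] * 20 + [0] * 20)
    X[:20, :3] += 1.2
    X = (X - X.min(0)) / np.ptp(X, axis=0)
    sel = RDFSSelector(n_runs=3, n_iterations=5, random_state=0).fit(X, y)
    assert sel.support_.shape == (10,)
    assert sel.transform(X).shape == (40, int(sel.support_.sum()))
    assert np.array_equal(sel.get_support(), sel.support_)
    assert len(sel.runs_) == 3


def test_selector_rejects_bad_string_labels(rng):
    X = rng.random((10, 4))
    with pytest.raises(DataError, match="sick"):
        RDFSSelector(n_runs=1, n_iterations=1).fit(X, np.array(["sick"] * 5 + [CONTROL] * 5))
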