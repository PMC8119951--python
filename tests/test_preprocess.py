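"""Normalization, probe collapsing, differential testing and matching checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rdfselect import (
    CASE,
    CONTROL,
    ComparisonGroup,
    DataError,
    ProbeMatrix,
    bh_adjust,
    collapse_probes,
    demographic_match_check,
    group_deg_test,
    normexp_background_correct,
    quantile_normalize,
)


# ---------------------------------------------------------------------------
# quantile normalization

def test_quantile_normalize_hand_example():
    df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [6.0, 4.0, 5.0]})
    out = quantile_normalize(df)
    np.testing.assert_allclose(out["A"], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out["B"], [4.5, 2.5, 3.5])


def test_quantile_normalize_identity_cases(rng):
    x = rng.normal(size=(20, 1))
    np.testing.assert_allclose(quantile_normalize(x), x)  # single column
    same = np.tile(rng.normal(size=20)[:, None], (1, 4))
    np.testing.assert_allclose(quantile_normalize(same), same)  # identical columns
    row = rng.normal(size=(1, 5))
    np.testing.assert_allclose(quantile_normalize(row), np.full((1, 5), row.mean()))


def test_quantile_normalize_tie_rule():
    # tied values receive the mean of the target values they span
    df = pd.DataFrame({"A": [1.0, 1.0, 5.0], "B": [2.0, 4.0, 6.0]})
    target = (np.sort(df["A"]) + np.sort(df["B"])) / 2  # [1.5, 2.5, 5.5]
    out = quantile_normalize(df)
    np.testing.assert_allclose(out["A"], [2.0, 2.0, 5.5])
    np.testing.assert_allclose(out["B"], target)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 30), st.integers(2, 6))
def test_quantile_normalize_properties(seed, n, m):
    """Idempotence and identical column multisets on tie-free matrices."""
    x = np.random.default_rng(seed).normal(size=(n, m))
    out = quantile_normalize(x)
    sorted_cols = np.sort(out, axis=0)
    for j in range(1, m):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
    np.testing.assert_allclose(quantile_normalize(out), out, atol=1e-12)


# ---------------------------------------------------------------------------
# normexp background correction

def test_normexp_positive_and_monotone(rng):
    x = rng.exponential(100, size=(500, 2)) + rng.normal(60, 10, size=(500, 2))
    x = np.clip(x, 0, None)
    out = normexp_background_correct(x)
    assert (out > 0).all()
    for j in range(2):
        order = np.argsort(x[:, j])
        assert (np.diff(out[order, j]) >= -1e-9).all()


def test_normexp_noise_free_limit(rng):
    # with vanishing background noise the correction reduces to x - mu
    mu = 50.0
    x = (mu + rng.exponential(200, size=(5000, 1))) + rng.normal(0, 0.5, size=(5000, 1))
    out = normexp_background_correct(x)
    err = out[:, 0] - (x[:, 0] - mu)
    # method-of-moments sampling noise bounds the achievable accuracy; the
    # correction must track x - mu up to a small fraction of the signal scale
    assert abs(np.median(err)) < 20.0
    slope = np.polyfit(x[:, 0], out[:, 0], 1)[0]
    assert 0.95 < slope < 1.05


def test_normexp_recovers_signal_slope(rng):
    s = rng.exponential(100, size=10000)
    x = s + rng.normal(50, 10, size=10000)
    out = normexp_background_correct(x[:, None])[:, 0]
    slope = np.polyfit(s, out, 1)[0]
    assert 0.9 < slope < 1.1


def test_normexp_zero_variance_column_errors():
    with pytest.raises(DataError, match="zero variance"):
        normexp_background_correct(np.full((10, 1), 3.0))


# ---------------------------------------------------------------------------
# probe collapsing

def _probe_matrix(values, gene_ids, controls):
    idx = pd.Index([f"p{i}" for i in range(len(values))], name="probe")
    inten = pd.DataFrame(values, index=idx, columns=["s1", "s2"])
    ann = pd.DataFrame({"gene_id": gene_ids, "is_control": controls}, index=idx)
    return ProbeMatrix(intensities=inten, annotation=ann)


def test_collapse_keeps_highest_mean_probe():
    pm = _probe_matrix(
        [[7.0, 7.4], [8.0, 8.2], [1.0, 1.0]],
        ["G1", "G1", None],
        [False, False, True],
    )
    out = collapse_probes(pm)
    assert list(out.index) == ["G1"]
    np.testing.assert_allclose(out.loc["G1"], [8.0, 8.2])


def test_collapse_tie_break_first_in_input_order():
    pm = _probe_matrix(
        [[5.0, 5.0], [4.0, 6.0], [2.0, 2.0], [1.0, 3.0], [9.0, 9.0]],
        ["G1", "G1", "G2", "G2", None],
        [False] * 5,
    )
    out = collapse_probes(pm)
    assert out.shape[0] == 2
    # G1: means tied at 5.0 -> first probe kept; brute-force argmax agrees
    np.testing.assert_allclose(out.loc["G1"], [5.0, 5.0])
    np.testing.assert_allclose(out.loc["G2"], [2.0, 2.0])


def test_collapse_gene_set_equals_annotation_minus_filtered(rng):
    genes = [f"G{i}" for i in range(10)]
    gene_ids = genes * 2 + [None] * 3
    controls = [False] * 20 + [True, False, False]
    vals = rng.random((23, 2)) + 0.5
    pm = _probe_matrix(vals, gene_ids, controls)
    out = collapse_probes(pm)
    assert set(out.index) == set(genes)


def test_collapse_all_filtered_errors():
    pm = _probe_matrix([[1.0, 1.0]], [None], [True])
    with pytest.raises(DataError):
        collapse_probes(pm)


# ---------------------------------------------------------------------------
# BH adjustment

def _bh_brute(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_hand_examples():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])
    np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 40))
def test_bh_matches_brute_force_step_up(seed, m):
    p = np.random.default_rng(seed).random(m)
    np.testing.assert_allclose(bh_adjust(p), _bh_brute(p), atol=1e-12)


# ---------------------------------------------------------------------------
# per-group differential test

def _make_group(case_vals, ctrl_vals, covariates=None):
    case_vals = np.atleast_2d(case_vals)
    ctrl_vals = np.atleast_2d(ctrl_vals)
    n1, n2 = case_vals.shape[1], ctrl_vals.shape[1]
    expr = pd.DataFrame(
        np.hstack([case_vals, ctrl_vals]),
        index=pd.Index([f"G{i}" for i in range(case_vals.shape[0])], name="gene"),
        columns=pd.Index([f"s{i}" for i in range(n1 + n2)], name="subject"),
    )
    labels = pd.Series([CASE] * n1 + [CONTROL] * n2, index=expr.columns, name="label")
    cov = covariates if covariates is not None else pd.DataFrame(index=expr.columns)
    return ComparisonGroup("WLT1", "WLT", "FS", expr, labels, cov)


def test_log2fc_is_mean_difference():
    g = _make_group([[2.0, 4.0]], [[1.0, 1.0]])
    deg = group_deg_test(g)
    assert deg["log2fc"].iloc[0] == pytest.approx(2.0)


def test_identical_distributions_give_null_result():
    g = _make_group([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
    deg = group_deg_test(g)
    assert deg["log2fc"].iloc[0] == 0.0
    assert deg["p"].iloc[0] == pytest.approx(1.0)


def test_student_t_matches_closed_form():
    a = np.array([5.1, 5.3, 5.2])
    b = np.array([4.1, 4.0, 4.2])
    g = _make_group([a], [b])
    deg = group_deg_test(g, test_variant="student")
    sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    p_ref = 2 * stats.t.sf(abs(t), df=4)
    assert deg["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10)


def test_label_swap_antisymmetry(rng):
    a = rng.normal(size=(5, 6))
    b = rng.normal(size=(5, 7))
    d1 = group_deg_test(_make_group(a, b))
    d2 = group_deg_test(_make_group(b, a))
    np.testing.assert_allclose(d1["log2fc"], -d2["log2fc"])
    np.testing.assert_allclose(d1["p"], d2["p"], atol=1e-12)


def test_welch_variant_differs_under_unequal_variance(rng):
    a = rng.normal(0, 3, size=(1, 10))
    b = rng.normal(0, 0.3, size=(1, 25))
    ps = group_deg_test(_make_group(a, b), "student")["p"].iloc[0]
    pw = group_deg_test(_make_group(a, b), "welch")["p"].iloc[0]
    assert ps != pw


# ---------------------------------------------------------------------------
# demographic matching

def test_demographic_check_identical_covariates():
    cov = pd.DataFrame(
        {
            "age": [60, 62, 64, 60, 62, 64],
            "gender": ["male", "female", "male", "male", "female", "male"],
            "pack_years": [30, 40, 50, 30, 40, 50],
            "fev1_pct_pred": [50, 60, 70, 50, 60, 70],
        },
        index=[f"s{i}" for i in range(6)],
    )
    g = _make_group([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]], cov)
    out = demographic_match_check(g).set_index("variable")
    for var in ("age", "pack_years", "fev1_pct_pred", "gender"):
        assert out.loc[var, "p"] == pytest.approx(1.0)


def test_demographic_check_extreme_gender_imbalance():
    n = 10
    cov = pd.DataFrame(
        {"gender": ["male"] * n + ["female"] * n},
        index=[f"s{i}" for i in range(2 * n)],
    )
    g = _make_group(np.arange(n)[None, :] * 0.1, np.arange(n)[None, :] * 0.1, cov)
    out = demographic_match_check(g).set_index("variable")
    assert out.loc["gender", "p"] < 0.001
    assert not out.loc["age", "available"]
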