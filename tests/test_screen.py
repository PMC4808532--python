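"""Unit tests for the TT, FDR and Bonferroni screens."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ttscreen import (
    DesignSpec,
    TTOptions,
    bonferroni_screen,
    fdr_screen,
    screen_all,
    split_train_test,
    tt_screen,
)
from ttscreen.model import build_design_matrix

from conftest import make_matrix


def bh_stepup_oracle(ps: np.ndarray, alpha: float) -> np.ndarray:
    """Literal step-up rule: largest k with p(k) <= (k/m) alpha; reject the k smallest."""
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if ps[order[k - 1]] <= k / m * alpha:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    # ties at the boundary: everything equal to the largest rejected p is rejected
    if k_max:
        reject |= ps <= ps[order[k_max - 1]]
    return reject


# ---------------------------------------------------------------------------
# split_train_test
# ---------------------------------------------------------------------------


def test_split_sizes_two_thirds_of_600():
    ids = [f"s{j}" for j in range(600)]
    train, test = split_train_test(ids, 2 / 3, np.random.default_rng(0))
    assert len(train) == 400 and len(test) == 200
    assert sorted(train + test) == sorted(ids)
    assert not set(train) & set(test)


def test_split_is_deterministic_given_seed():
    ids = [f"s{j}" for j in range(50)]
    a = split_train_test(ids, 0.6, np.random.default_rng(99))
    b = split_train_test(ids, 0.6, np.random.default_rng(99))
    assert a == b


def test_degenerate_split_errors():
    ids = [f"s{j}" for j in range(20)]
    with pytest.raises(ValueError, match="fittable minimum"):
        split_train_test(ids, 0.96, np.random.default_rng(0), min_size=5)


# ---------------------------------------------------------------------------
# FDR / Bonferroni
# ---------------------------------------------------------------------------


def test_fdr_hand_enumerated_example():
    ps = {"a": 0.001, "b": 0.01, "c": 0.03, "d": 0.04, "e": 0.2}
    assert fdr_screen(ps, 0.05) == {"a", "b", "c", "d"}


def test_fdr_all_ones_and_boundary():
    assert fdr_screen({"a": 1.0, "b": 1.0}, 0.05) == set()
    assert fdr_screen({"a": 0.05}, 0.05) == {"a"}  # <= is inclusive
    assert fdr_screen({}, 0.05) == set()


def test_bonferroni_examples_and_boundary():
    assert bonferroni_screen({"a": 1e-5, "b": 0.04, "c": 0.5}, 0.05) == {"a"}
    third = 0.05 / 3
    assert bonferroni_screen({"a": third, "b": third, "c": third}, 0.05) == {"a", "b", "c"}
    assert bonferroni_screen({}, 0.05) == set()


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
    st.floats(min_value=0.01, max_value=0.2),
)
def test_bonferroni_nested_in_fdr(ps, alpha):
    named = {f"p{i}": p for i, p in enumerate(ps)}
    assert bonferroni_screen(named, alpha) <= fdr_screen(named, alpha)


@settings(max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fdr_matches_stepup_oracle(seed):
    rng = np.random.default_rng(seed)
    ps = rng.random(rng.integers(1, 30))
    named = pd.Series(ps, index=[f"p{i}" for i in range(len(ps))])
    expect = set(named.index[bh_stepup_oracle(ps, 0.05)])
    assert fdr_screen(named, 0.05) == expect


def test_pvalue_validation():
    with pytest.raises(ValueError):
        fdr_screen({"a": 1.2}, 0.05)
    with pytest.raises(ValueError):
        bonferroni_screen({"a": -0.1}, 0.05)


# ---------------------------------------------------------------------------
# TT screen
# ---------------------------------------------------------------------------


def test_min_count_translation():
    assert TTOptions(cutoff_percent=50, n_iterations=100).min_count == 50
    assert TTOptions(cutoff_percent=30, n_iterations=100).min_count == 30
    assert TTOptions(cutoff_percent=50, n_iterations=7).min_count == 4  # ceil(3.5)


def test_options_validation():
    with pytest.raises(ValueError):
        TTOptions(train_fraction=1.2)
    with pytest.raises(ValueError):
        TTOptions(cutoff_percent=0)
    with pytest.raises(ValueError):
        TTOptions(engine="glm")


def test_vacuous_gates_select_every_site_every_iteration(small_sim, small_design):
    M, _, _, _ = small_sim
    opts = TTOptions(alpha_train=1.0, alpha_test=1.0, n_iterations=5, seed=1)
    res = tt_screen(M, small_design, opts)
    assert np.all(res.selection_count == 5)
    assert res.selected_tt.all()


def test_selection_threshold_and_cutoff_monotonicity(small_sim, small_design):
    M, _, _, _ = small_sim
    opts = TTOptions(n_iterations=20, seed=3)
    res = tt_screen(M, small_design, opts)
    np.testing.assert_array_equal(res.selected_tt, res.selection_count >= opts.min_count)
    # raising the cutoff never adds sites
    prev = None
    for cutoff in (30, 50, 70, 90):
        m = math.ceil(cutoff / 100 * opts.n_iterations)
        sel = set(np.flatnonzero(res.selection_count >= m))
        if prev is not None:
            assert sel <= prev
        prev = sel


def test_tt_screen_is_reproducible(small_sim, small_design):
    M, _, _, _ = small_sim
    opts = TTOptions(n_iterations=10, seed=77)
    a = tt_screen(M, small_design, opts)
    b = tt_screen(M, small_design, opts)
    np.testing.assert_array_equal(a.selection_count, b.selection_count)
    np.testing.assert_array_equal(a.selected_tt, b.selected_tt)
    pd.testing.assert_frame_equal(a.full_pvalues, b.full_pvalues)


def test_single_iteration_matches_hand_trace():
    """With i=1 and m=1, TT is one split-and-confirm; traced via statsmodels."""
    rng = np.random.default_rng(21)
    n = 24
    x1 = rng.normal(1, 1, n)
    cov = pd.DataFrame({"x1": x1}, index=[f"s{j}" for j in range(n)])
    Y = np.vstack(
        [
            4.0 * x1 + 0.2 * rng.standard_normal(n),  # strong
            rng.standard_normal(n),                    # null
            3.0 * x1 + 0.2 * rng.standard_normal(n),  # strong
            rng.standard_normal(n),                    # null
            0.2 * x1 + rng.standard_normal(n),         # weak
        ]
    )
    M = make_matrix(Y)
    design = DesignSpec(cov, ["x1"], ["x1"])
    opts = TTOptions(n_iterations=1, cutoff_percent=100, seed=5)
    res = tt_screen(M, design, opts)

    # independent trace: reproduce the split from the same seed stream
    child = np.random.SeedSequence(5).spawn(1)[0]
    dm_cols = build_design_matrix(design).n_columns
    train, test = split_train_test(
        [f"s{j}" for j in range(n)], opts.train_fraction,
        np.random.default_rng(child), dm_cols + 2,
    )
    tr = [int(s[1:]) for s in train]
    te = [int(s[1:]) for s in test]
    expected = []
    for y in Y:
        X_tr = sm.add_constant(x1[tr])
        p_tr = sm.OLS(y[tr], X_tr).fit().pvalues[1]
        if p_tr < 0.05:
            p_te = sm.OLS(y[te], sm.add_constant(x1[te])).fit().pvalues[1]
            expected.append(p_te < 0.05)
        else:
            expected.append(False)
    np.testing.assert_array_equal(res.selected_tt, np.array(expected))
    assert res.selected_tt[0] and res.selected_tt[2]


def test_screen_all_populates_three_methods_and_final_fits(small_sim, small_design):
    M, _, truth, _ = small_sim
    res = screen_all(M, small_design, TTOptions(n_iterations=10, seed=2))
    frame = res.to_frame()
    for col in ("selected_tt", "selected_fdr", "selected_bonf", "selection_count"):
        assert col in frame.columns
    # bonferroni nested in fdr on the same full-data p-values
    assert set(res.selected_sites("bonferroni")) <= set(res.selected_sites("fdr"))
    for method in ("tt", "fdr", "bonferroni"):
        for site in res.selected_sites(method):
            assert site in res.final_fits


def test_robust_engine_screen_smoke(small_sim, small_design):
    M, _, _, _ = small_sim
    sub = make_matrix(M.values[:15])
    sub.sample_ids = M.sample_ids
    res = tt_screen(sub, small_design, TTOptions(n_iterations=3, seed=4, engine="robust"))
    assert res.selection_count.shape == (15,)
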