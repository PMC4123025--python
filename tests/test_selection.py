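"""LASSO shortlist, exhaustive enumeration, and CV-based selection."""

import math

import numpy as np
import pandas as pd
import pytest

import coarselur as cl
from coarselur.selection import (
    ModelSpec,
    TermSet,
    count_subsets,
    enumerate_subsets,
    lasso_reduce,
    make_folds,
    select_best,
)


def _termset(X: pd.DataFrame, season=None, scope="city"):
    n = len(X)
    samples = pd.DataFrame(
        dict(
            season=season if season is not None else ["winter"] * n,
            city=["c"] * n,
        )
    )
    return TermSet(X.reset_index(drop=True), samples, scope)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "n_cands,cap",
    [(15, 6), (1, 6), (8, 3), (6, 6), (10, 0)],
)
def test_enumeration_count_matches_binomial_sum(n_cands, cap):
    cands = [f"v{i}" for i in range(n_cands)]
    specs = list(enumerate_subsets(cands, cap))
    assert len(specs) == count_subsets(n_cands, cap)
    assert len({s.terms for s in specs}) == len(specs)


def test_enumeration_exact_counts():
    assert count_subsets(15, 6) == 9949
    assert len(list(enumerate_subsets(["x"], 6))) == 2  # {} and {x}


def test_interaction_repair_forces_main_effects():
    spec = ModelSpec("coarse", ("imperv:season",)).repaired()
    assert spec.terms == ("imperv", "imperv:season", "season")
    # repair may push past the enumeration cap
    assert spec.n_parameters == 3
    specs = list(enumerate_subsets(["imperv", "season", "imperv:season"], 1))
    assert ("imperv", "imperv:season", "season") in {s.terms for s in specs}


def test_parameter_counting_rule():
    spec = ModelSpec("coarse", ("a", "b", "season", "a:season"))
    assert spec.n_parameters == 4  # intercept excluded; each term counts 1


# ---------------------------------------------------------------------------
# LASSO shortlist
# ---------------------------------------------------------------------------
def test_lasso_recovers_planted_support():
    """Three active columns out of twelve are recovered in >= 90% of seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(200, 12)), columns=[f"v{i:02d}" for i in range(12)]
        )
        y = 2.0 * X["v00"] - 1.5 * X["v05"] + 1.0 * X["v09"] + 0.3 * rng.normal(size=200)
        ts = _termset(X)
        support = lasso_reduce(ts, y.to_numpy(), max_vars=15)
        hits += {"v00", "v05", "v09"} <= set(support)
    assert hits >= 18


def test_lasso_support_cap_respected():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(100, 20)), columns=[f"v{i:02d}" for i in range(20)])
    y = X.to_numpy() @ rng.normal(size=20) + 0.1 * rng.normal(size=100)
    ts = _termset(X)
    support = lasso_reduce(ts, y, max_vars=5)
    assert 0 < len(support) <= 5
    # with a cap at the pool size every column is eligible
    full = lasso_reduce(ts, y, max_vars=20)
    assert set(full) == set(X.columns)


# ---------------------------------------------------------------------------
# CV selection
# ---------------------------------------------------------------------------
def test_fold_sizes_differ_by_at_most_one():
    for n, k in [(63, 10), (60, 10), (11, 10)]:
        folds = make_folds(n, k, seed=1)
        sizes = np.bincount(folds, minlength=k)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == n
    with pytest.raises(ValueError):
        make_folds(5, 10, seed=0)


def test_intercept_only_cv_rmse_near_sd():
    rng = np.random.default_rng(3)
    y = rng.normal(5.0, 2.0, 300)
    X = pd.DataFrame(dict(v=rng.normal(size=300)))
    ts = _termset(X)
    res = select_best([ModelSpec("coarse", ())], ts, y, k=10, seed=0)
    assert res.cv_rmse == pytest.approx(y.std(ddof=0), rel=0.1)


def test_noiseless_truth_attains_zero_cv_rmse_and_wins():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
    y = 1.0 + 2.0 * X["a"] - 1.0 * X["c"]
    ts = _termset(X)
    specs = enumerate_subsets(list("abcde"), 3)
    res = select_best(specs, ts, y.to_numpy(), k=10, seed=2)
    assert res.cv_rmse < 1e-10
    assert {"a", "c"} <= set(res.best.terms)
    # ties at zero RMSE break toward fewer parameters: exactly {a, c}
    assert res.best.terms == ("a", "c")


def test_selection_deterministic_given_seed():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
    y = X["a"].to_numpy() + 0.5 * rng.normal(size=60)
    ts = _termset(X)
    r1 = select_best(enumerate_subsets(list("abcdef"), 3), ts, y, seed=9)
    r2 = select_best(enumerate_subsets(list("abcdef"), 3), ts, y, seed=9)
    assert r1.best.terms == r2.best.terms
    assert r1.cv_rmse == r2.cv_rmse


def test_noise_column_does_not_improve_selection():
    """Adding a pure-noise candidate leaves the selected CV RMSE
    non-improving in the median across seeds."""
    deltas = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + 0.8 * X["b"].to_numpy() + 0.5 * rng.normal(size=80)
        ts_small = _termset(X)
        r_small = select_best(enumerate_subsets(list("abcd"), 4), ts_small, y, seed=0)
        X2 = X.copy()
        X2["noise"] = rng.normal(size=80)
        ts_big = _termset(X2)
        r_big = select_best(
            enumerate_subsets(list("abcd") + ["noise"], 4), ts_big, y, seed=0
        )
        deltas.append(r_small.cv_rmse - r_big.cv_rmse)
    assert np.median(deltas) <= 1e-6


def test_rank_deficient_specs_discarded():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(dict(a=rng.normal(size=50)))
    X["b"] = X["a"]  # exact collinearity
    y = X["a"].to_numpy() + 0.1 * rng.normal(size=50)
    ts = _termset(X)
    res = select_best(enumerate_subsets(["a", "b"], 2), ts, y, seed=1)
    assert res.n_discarded >= 1
    assert res.best.terms in {("a",), ("b",)}


def test_sensitivity_switches_off_equal_primary_run(campaign, valid_samples):
    """With log-transform and 3-SD exclusion both off, the prepared data is
    bit-identical to the raw analysis set."""
    from coarselur.pipeline import RunConfig, prepare_outcome

    cfg = RunConfig(log_transform=False, drop_outliers_3sd=False)
    df, y = prepare_outcome(valid_samples, "coarse", cfg)
    pd.testing.assert_frame_equal(df, valid_samples.reset_index(drop=True))
    np.testing.assert_array_equal(y, valid_samples["coarse"].to_numpy())
    cfg_on = RunConfig(log_transform=True, drop_outliers_3sd=True)
    _, y_on = prepare_outcome(valid_samples, "coarse", cfg_on)
    assert not np.array_equal(y_on, y)
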