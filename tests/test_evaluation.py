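"""Evaluation metrics and cross-validation conventions."""

import math

import numpy as np
import pandas as pd
import pytest

import coarselur as cl
from coarselur.evaluation import corr_r2, cross_validate, r2_city, r2_pooled, rmse
from coarselur.selection import ModelSpec, TermSet


@pytest.mark.parametrize(
    "obs,pred,expected",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([0.0, 0.0], [3.0, 4.0], math.sqrt(25.0 / 2.0)),
        ([1.0], [4.0], 3.0),
    ],
)
def test_rmse_examples(obs, pred, expected):
    assert rmse(obs, pred) == pytest.approx(expected)


def test_rmse_empty_rejected():
    with pytest.raises(ValueError):
        rmse([], [])


def test_r2_city_perfect_prediction_is_one():
    obs = np.array([1.0, 2.0, 3.0, 10.0, 12.0, 14.0])
    cities = np.array(["a"] * 3 + ["b"] * 3)
    out = r2_city(obs, obs, cities)
    assert out["a"]["r2"] == pytest.approx(1.0)
    assert out["b"]["r2"] == pytest.approx(1.0)


def test_r2_city_mean_prediction_is_zero():
    obs = np.array([1.0, 2.0, 3.0, 10.0, 12.0, 14.0])
    cities = np.array(["a"] * 3 + ["b"] * 3)
    pred = np.where(cities == "a", 2.0, 12.0)
    out = r2_city(obs, pred, cities)
    assert out["a"]["r2"] == pytest.approx(0.0)
    assert out["b"]["r2"] == pytest.approx(0.0)


def test_r2_city_truncates_negative_but_keeps_raw():
    obs = np.array([1.0, 2.0, 3.0])
    pred = np.array([10.0, -5.0, 7.0])  # far worse than the city mean
    out = r2_city(obs, pred, np.array(["a"] * 3))
    assert out["a"]["r2"] == 0.0
    assert out["a"]["raw_r2"] < 0.0


def test_r2_city_zero_variance_reported_missing():
    out = r2_city([2.0, 2.0], [2.0, 2.1], ["a", "a"])
    assert out["a"]["r2"] is None


def test_r2_city_single_city_equals_pooled_definition():
    rng = np.random.default_rng(0)
    obs = rng.normal(size=40)
    pred = obs + rng.normal(0, 0.5, 40)
    single = r2_city(obs, pred, np.array(["only"] * 40))["only"]["raw_r2"]
    assert single == pytest.approx(r2_pooled(obs, pred))


def test_corr_r2_is_squared_correlation():
    rng = np.random.default_rng(1)
    obs = rng.normal(size=50)
    pred = 2 * obs + rng.normal(size=50)
    assert corr_r2(obs, pred) == pytest.approx(np.corrcoef(obs, pred)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# cross_validate
# ---------------------------------------------------------------------------
def _dataset(n, seed, n_cities=1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
    cities = [f"city{i % n_cities}" for i in range(n)]
    samples = pd.DataFrame(
        dict(
            season="winter",
            city=cities,
            x_m=rng.uniform(0, 10_000, n),
            y_m=rng.uniform(0, 10_000, n),
        )
    )
    scope = "pooled" if n_cities > 1 else "city"
    return X, samples, rng, scope


def test_cv_noiseless_truth_gives_r2_one():
    X, samples, _, scope = _dataset(60, 2)
    y = 1.0 + 2.0 * X["a"].to_numpy()
    ts = TermSet(X, samples, scope)
    rep = cross_validate(ModelSpec("coarse", ("a",), scope), ts, y, samples, seed=0)
    assert rep.cv_r2 == pytest.approx(1.0)
    assert rep.cv_rmse == pytest.approx(0.0, abs=1e-10)


def test_cv_pure_noise_truncates_to_zero_in_most_seeds():
    zeros = 0
    for seed in range(15):
        X, samples, rng, scope = _dataset(60, seed)
        y = rng.normal(size=60)
        ts = TermSet(X, samples, scope)
        rep = cross_validate(ModelSpec("coarse", ("a", "b"), scope), ts, y, samples, seed=seed)
        zeros += rep.cv_r2 == 0.0 and rep.cv_r2_raw < 0.0
    assert zeros >= 10


def test_cv_optimism_in_sample_r2_exceeds_cv_r2():
    """At field scale (n~60, moderate noise) the in-sample fit is
    optimistic relative to the cross-validated fit, in the median."""
    from coarselur.selection import fit_ols_spec

    diffs = []
    for seed in range(20):
        X, samples, rng, scope = _dataset(60, 200 + seed)
        y = X["a"].to_numpy() + 0.8 * X["b"].to_numpy() + 1.0 * rng.normal(size=60)
        ts = TermSet(X, samples, scope)
        spec = ModelSpec("coarse", ("a", "b"), scope)
        rep = cross_validate(spec, ts, y, samples, seed=seed)
        fitted = fit_ols_spec(spec, ts, y)
        Xd, _ = ts.matrix_for(spec.terms)
        beta = np.array([c for _, c in fitted.coefficients])
        in_sample = r2_pooled(y, Xd @ beta)
        diffs.append(in_sample - rep.cv_r2_raw)
    assert np.median(diffs) > 0


def test_cv_pooled_scope_reports_per_city():
    X, samples, rng, scope = _dataset(90, 5, n_cities=3)
    y = 2.0 + X["a"].to_numpy() + 0.3 * rng.normal(size=90)
    ts = TermSet(X, samples, scope)
    rep = cross_validate(ModelSpec("coarse", ("a",), scope), ts, y, samples, seed=3)
    assert set(rep.per_city) == {"city0", "city1", "city2"}
    for entry in rep.per_city.values():
        assert entry["r2"] is None or 0.0 <= entry["r2"] <= 1.0
        assert entry["rmse"] >= 0.0


def test_selected_model_not_worse_than_intercept_only(clean_campaign):
    """The pipeline's selected model never loses to the null model by more
    than fold noise on the same split."""
    valid, _ = cl.apply_qc(clean_campaign.samples)
    y = valid["coarse"].to_numpy()
    cov = clean_campaign.covariates.align_to(valid)
    screened, _ = cl.screen_covariates(cov, y)
    res, ts, _ = cl.select_model(screened, valid, y, seed=4)
    null = cross_validate(ModelSpec("coarse", ()), ts, y, valid, seed=4)
    assert res.cv_rmse <= null.cv_rmse + 1e-9


def test_uk_cv_refits_variogram_per_fold(clean_campaign):
    """UK cross-validation runs end to end with per-fold variogram refits and
    stays close to LUR when residuals are nugget-dominated."""
    valid, _ = cl.apply_qc(clean_campaign.samples)
    y = valid["coarse"].to_numpy()
    cov = clean_campaign.covariates.align_to(valid)
    screened, _ = cl.screen_covariates(cov, y)
    res, ts, _ = cl.select_model(screened, valid, y, seed=6)
    lur = cross_validate(res.best, ts, y, valid, seed=6, mode="lur")
    uk = cross_validate(res.best, ts, y, valid, seed=6, mode="uk")
    assert np.isfinite(uk.cv_rmse)
    assert abs(uk.cv_r2 - lur.cv_r2) < 0.2  # loose sanity; tight bound in acceptance
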