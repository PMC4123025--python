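"""LUR fits, variogram estimation, and universal-kriging behaviour."""

import numpy as np
import pandas as pd
import pytest

import coarselur as cl
from coarselur.selection import ModelSpec, TermSet
from coarselur.spatial import (
    VariogramFit,
    fit_lur,
    fit_uk,
    fit_variogram,
    make_grid,
    predict,
)
from coarselur.synthetic import exponential_field


def _dataset(n=60, seed=0, city="c"):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    samples = pd.DataFrame(
        dict(
            season=["winter"] * n,
            city=[city] * n,
            x_m=rng.uniform(0, 10_000, n),
            y_m=rng.uniform(0, 10_000, n),
        )
    )
    ts = TermSet(X, samples, "city")
    return X, samples, ts, rng


# ---------------------------------------------------------------------------
# LUR
# ---------------------------------------------------------------------------
def test_lur_noiseless_recovers_truth_exactly():
    X, samples, ts, _ = _dataset(seed=1)
    y = 2.0 + 1.5 * X["a"].to_numpy() - 0.7 * X["b"].to_numpy()
    model = fit_lur(ModelSpec("coarse", ("a", "b")), ts, y, samples)
    coefs = dict(model.spec.coefficients)
    assert coefs["intercept"] == pytest.approx(2.0, abs=1e-10)
    assert coefs["a"] == pytest.approx(1.5, abs=1e-10)
    assert coefs["b"] == pytest.approx(-0.7, abs=1e-10)


def test_lur_intercept_only_is_mean():
    X, samples, ts, rng = _dataset(seed=2)
    y = rng.normal(5, 1, len(X))
    model = fit_lur(ModelSpec("coarse", ()), ts, y, samples)
    assert dict(model.spec.coefficients)["intercept"] == pytest.approx(y.mean())


def test_lur_rank_deficiency_names_collinear_terms():
    X, samples, ts, rng = _dataset(seed=3)
    X2 = X.copy()
    X2["d"] = X2["a"]
    ts2 = TermSet(X2, samples, "city")
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        fit_lur(ModelSpec("coarse", ("a", "d")), ts2, rng.normal(size=len(X)), samples)


def test_lur_coefficient_sampling_sd_matches_closed_form():
    """Empirical coefficient RMSE over 50 noise draws matches the OLS
    closed-form sampling SD within 20% (fixed design)."""
    X, samples, ts, _ = _dataset(n=500, seed=4)
    sigma = 0.8
    Xd = np.column_stack([np.ones(500), X[["a", "b", "c"]].to_numpy()])
    cov = sigma**2 * np.linalg.inv(Xd.T @ Xd)
    closed_form_sd = np.sqrt(np.diag(cov))
    spec = ModelSpec("coarse", ("a", "b", "c"))
    errs = []
    for seed in range(50):
        rng = np.random.default_rng(100 + seed)
        y = Xd @ np.array([3.0, 1.0, -0.5, 0.25]) + rng.normal(0, sigma, 500)
        model = fit_lur(spec, ts, y, samples)
        beta = np.array([c for _, c in model.spec.coefficients])
        errs.append(beta - np.array([3.0, 1.0, -0.5, 0.25]))
    emp_sd = np.sqrt(np.mean(np.square(errs), axis=0))
    np.testing.assert_allclose(emp_sd, closed_form_sd, rtol=0.35)
    assert np.median(np.abs(emp_sd / closed_form_sd - 1.0)) < 0.20


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------
def test_white_noise_residuals_are_nugget_dominated():
    fracs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 10_000, (150, 2))
        z = rng.normal(size=150)
        vg = fit_variogram(z, xy)
        fracs.append(vg.nugget_fraction)
    assert np.median(fracs) > 0.8


def test_duplicated_points_zero_lag_finite_fit():
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 5000, (30, 2))
    z = rng.normal(size=30)
    vg = fit_variogram(np.concatenate([z, z]), np.vstack([xy, xy]))
    assert np.isfinite([vg.nugget, vg.partial_sill, vg.range_m]).all()


def test_coincident_points_rejected():
    with pytest.raises(ValueError):
        fit_variogram(np.zeros(25), np.zeros((25, 2)))


def test_variogram_parameter_validation():
    with pytest.raises(ValueError):
        VariogramFit(nugget=-0.1, partial_sill=1.0, range_m=100.0)


# ---------------------------------------------------------------------------
# kriging / UK
# ---------------------------------------------------------------------------
def test_uk_equals_lur_when_partial_sill_zero():
    X, samples, ts, rng = _dataset(seed=5)
    y = X["a"].to_numpy() + rng.normal(size=len(X))
    model = fit_lur(ModelSpec("coarse", ("a",)), ts, y, samples)
    model.variograms = {"c": VariogramFit(nugget=0.5, partial_sill=0.0, range_m=1000.0)}
    lur_pred = predict(model, ts, samples, mode="lur")
    uk_pred = predict(model, ts, samples, mode="uk")
    np.testing.assert_array_equal(lur_pred, uk_pred)


def test_uk_zero_nugget_interpolates_training_points():
    X, samples, ts, rng = _dataset(seed=6)
    y = X["a"].to_numpy() + rng.normal(size=len(X))
    model = fit_lur(ModelSpec("coarse", ("a",)), ts, y, samples)
    model.variograms = {"c": VariogramFit(nugget=0.0, partial_sill=1.0, range_m=2000.0)}
    uk_pred = predict(model, ts, samples, mode="uk")
    np.testing.assert_allclose(uk_pred, y, atol=1e-8)


def test_translation_invariance_of_predictions():
    X, samples, ts, rng = _dataset(seed=7)
    y = X["a"].to_numpy() + rng.normal(size=len(X))
    model = fit_uk(ModelSpec("coarse", ("a",)), ts, y, samples)
    base = predict(model, ts, samples, mode="uk")
    shifted = samples.copy()
    shifted[["x_m", "y_m"]] += 1.0e5
    model2 = fit_uk(ModelSpec("coarse", ("a",)), ts, y, shifted)
    np.testing.assert_allclose(predict(model2, ts, shifted, mode="uk"), base, atol=1e-8)


def test_uk_beats_lur_under_strong_spatial_residual():
    """With a long-range, low-nugget residual field, UK improves held-out
    RMSE over LUR in >= 80% of seeds."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 120
        xy = rng.uniform(0, 10_000, (n, 2))
        X = pd.DataFrame(dict(a=rng.normal(size=n)))
        eta = exponential_field(xy, 1.5, 3000.0, rng)
        y = 2.0 + 1.0 * X["a"].to_numpy() + eta + rng.normal(0, 0.1, n)
        samples = pd.DataFrame(
            dict(season="winter", city="c", x_m=xy[:, 0], y_m=xy[:, 1])
        )
        train = np.arange(n) < 80
        ts_tr = TermSet(X[train].reset_index(drop=True), samples[train].reset_index(drop=True), "city")
        ts_te = TermSet(X[~train].reset_index(drop=True), samples[~train].reset_index(drop=True), "city")
        spec = ModelSpec("coarse", ("a",))
        uk = fit_uk(spec, ts_tr, y[train], samples[train].reset_index(drop=True))
        p_lur = predict(uk, ts_te, samples[~train].reset_index(drop=True), mode="lur")
        p_uk = predict(uk, ts_te, samples[~train].reset_index(drop=True), mode="uk")
        obs = y[~train]
        wins += cl.rmse(obs, p_uk) < cl.rmse(obs, p_lur)
    assert wins >= 0.8 * n_seeds


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------
def test_grid_spacing_urban_vs_rural():
    layout = cl.default_layouts()[0]
    grid = make_grid(layout, urban_spacing_m=250.0, rural_spacing_m=1000.0)
    urban = grid[grid["urban"]]
    rural = grid[~grid["urban"]]
    assert len(urban) == 41 * 41  # 10 km core at 250 m spacing
    xs = np.unique(np.diff(np.unique(urban["x_m"])))
    assert np.allclose(xs, 250.0)
    xs_r = np.unique(np.diff(np.unique(rural["x_m"])))
    assert np.allclose(xs_r, 1000.0)
    # no rural node falls inside the urban core
    assert not layout.urban_core.contains_points(
        rural["x_m"].to_numpy(), rural["y_m"].to_numpy()
    ).any()
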