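"""LUR fitting, variogram estimation, universal kriging, prediction grids.

Land-use regression (LUR) is ordinary least squares of concentrations on the
selected geographic terms.  Universal kriging (UK) is realised as a two-stage
approximation: fit the LUR, then krige its residuals under an exponential
variogram fitted to the empirical semivariance (weighted least squares with
pair-count weights).  When the fitted partial sill is zero the kriging term
vanishes and UK predictions equal LUR predictions exactly; with zero nugget,
UK interpolates the training data exactly at training locations.

Only the exponential model gamma(h) = nugget + psill * (1 - exp(-h/range))
is provided; its effective range (95% of the sill) is about 3x the range
parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

from .selection import ModelSpec, TermSet, fit_ols_spec


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------
@dataclass
class VariogramFit:
    nugget: float
    partial_sill: float
    range_m: float
    model: str = "exponential"
    bins: list[tuple[float, float, int]] = field(default_factory=list)  # (lag, gamma, n)

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_m <= 0:
            raise ValueError("invalid variogram parameters")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def nugget_fraction(self) -> float:
        return self.nugget / self.sill if self.sill > 0 else 1.0

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-h / self.range_m))

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = psill * exp(-h/range); the nugget acts only at h = 0."""
        h = np.asarray(h, float)
        c = self.partial_sill * np.exp(-h / self.range_m)
        return c + np.where(h == 0.0, self.nugget, 0.0)


def fit_variogram(
    residuals, coords, n_bins: int = 12, min_points: int = 20
) -> VariogramFit:
    """Fit an exponential variogram to residuals by pair-count-weighted WLS.

    Empirical semivariances are computed in ~``n_bins`` equal-count lag bins
    up to half the maximum pairwise distance.  Coincident points (zero lag)
    are retained in the first bin, where they inform the nugget.
    """
    z = np.asarray(residuals, float)
    xy = np.asarray(coords, float)
    if len(z) < min_points:
        raise ValueError(f"need at least {min_points} points")
    d = pdist(xy)
    if d.max() == 0:
        raise ValueError("all points are coincident")
    dz2 = 0.5 * pdist(z[:, None], metric="sqeuclidean")

    max_lag = 0.5 * d.max()
    use = d <= max_lag
    du, gu = d[use], dz2[use]
    order = np.argsort(du, kind="stable")
    du, gu = du[order], gu[order]
    splits = np.array_split(np.arange(len(du)), min(n_bins, max(1, len(du))))
    # nugget vs short-range sill is identified by the shortest lags, which an
    # equal-count scheme lumps into one wide bin: subdivide the first bin
    if len(splits[0]) >= 8:
        splits = np.array_split(splits[0], 4) + splits[1:]
    lags, gammas, counts = [], [], []
    for s in splits:
        if len(s) == 0:
            continue
        lags.append(float(du[s].mean()))
        gammas.append(float(gu[s].mean()))
        counts.append(len(s))
    lags_a = np.array(lags)
    gam_a = np.array(gammas)
    w = np.sqrt(np.array(counts, float))

    var_z = z.var(ddof=1)
    g0 = max(gam_a[0], 1e-12)

    def resid(p):
        nug, psill, rng_ = p
        model = nug + psill * (1.0 - np.exp(-lags_a / rng_))
        return w * (model - gam_a)

    # A flat semivariogram is non-identifiable: pure nugget and a slowly
    # rising partial sill fit equally well.  Run from several starts and,
    # within numerical ties, prefer the nugget-dominated solution (no claim
    # of spatial structure without evidence for it).
    r0 = max(max_lag / 3.0, 1.0)
    starts = [
        np.array([min(g0, var_z), max(var_z - min(g0, var_z), 0.05 * var_z + 1e-12), r0]),
        np.array([var_z, 0.05 * var_z + 1e-12, r0]),
        np.array([0.05 * var_z + 1e-12, var_z, lags_a[0] if lags_a[0] > 0 else r0]),
    ]
    solutions = []
    for init in starts:
        sol = least_squares(
            resid, init,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, max_lag]),
            max_nfev=2000,
        )
        solutions.append((float(np.sum(sol.fun**2)), sol.x))
    best_sse = min(s for s, _ in solutions)
    tol = best_sse * (1.0 + 1e-6) + 1e-12
    tied = [x for s, x in solutions if s <= tol]
    nug, psill, rng_ = (float(v) for v in max(tied, key=lambda x: x[0]))
    return VariogramFit(
        nugget=nug, partial_sill=psill, range_m=rng_,
        bins=list(zip(lags, gammas, counts)),
    )


def fit_variogram_ml(residuals, coords, min_points: int = 20) -> VariogramFit:
    """Gaussian maximum-likelihood fit of the exponential covariance model.

    Statistically more efficient than the moment-based WLS fit — it uses
    every pair rather than binned semivariances — at O(n^3) cost per
    likelihood evaluation, so it suits parameter estimation at moderate n
    rather than the inner loops of cross-validated kriging.
    """
    from scipy.optimize import minimize

    z = np.asarray(residuals, float)
    xy = np.asarray(coords, float)
    if len(z) < min_points:
        raise ValueError(f"need at least {min_points} points")
    n = len(z)
    D = squareform(pdist(xy))
    if D.max() == 0:
        raise ValueError("all points are coincident")
    var_z = z.var(ddof=1)
    zc = z - z.mean()

    def nll(p):
        lognug, logps, logr = p
        K = np.exp(logps) * np.exp(-D / np.exp(logr)) + np.exp(lognug) * np.eye(n)
        try:
            chol = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e10
        alpha = np.linalg.solve(chol, zc)
        return float(np.sum(np.log(np.diag(chol))) + 0.5 * alpha @ alpha)

    r0 = max(0.1 * D.max(), 1.0)
    starts = [
        [np.log(0.1 * var_z + 1e-12), np.log(0.9 * var_z + 1e-12), np.log(r0)],
        [np.log(0.5 * var_z + 1e-12), np.log(0.5 * var_z + 1e-12), np.log(2.5 * r0)],
    ]
    best = None
    for init in starts:
        sol = minimize(
            nll, init, method="Nelder-Mead",
            options=dict(maxiter=300, xatol=1e-3, fatol=1e-4),
        )
        if best is None or sol.fun < best.fun:
            best = sol
    nug, psill, rng_ = (float(v) for v in np.exp(best.x))
    return VariogramFit(nugget=nug, partial_sill=psill, range_m=rng_)


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------
@dataclass
class FittedModel:
    spec: ModelSpec  # with coefficients
    scope: str
    residuals: np.ndarray = field(repr=False)
    coords: np.ndarray = field(repr=False)
    cities: np.ndarray = field(repr=False)
    variograms: dict[str, VariogramFit] = field(default_factory=dict)
    training_hash: int = 0

    @property
    def is_uk(self) -> bool:
        return bool(self.variograms)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")


def fit_lur(
    spec: ModelSpec, termset: TermSet, y, samples: pd.DataFrame
) -> FittedModel:
    """Ordinary-least-squares fit of a model spec; residuals retained."""
    y = np.asarray(y, float)
    X, names = termset.matrix_for(spec.terms)
    _check_full_rank(X, names)
    fitted = fit_ols_spec(spec, termset, y)
    beta = np.array([c for _, c in fitted.coefficients])
    resid = y - X @ beta
    coords = samples[["x_m", "y_m"]].to_numpy(float)
    return FittedModel(
        spec=fitted,
        scope=spec.scope,
        residuals=resid,
        coords=coords,
        cities=samples["city"].to_numpy(),
        training_hash=hash((y.tobytes(), X.tobytes())),
    )


def fit_uk(
    spec: ModelSpec,
    termset: TermSet,
    y,
    samples: pd.DataFrame,
    pooled_variogram: bool = False,
    min_points: int = 20,
) -> FittedModel:
    """Two-stage universal kriging: LUR plus kriged residuals.

    By default one variogram is fitted per city (residual spatial structure
    is a within-city phenomenon); ``pooled_variogram=True`` fits a single
    variogram to all residuals.
    """
    model = fit_lur(spec, termset, y, samples)
    if pooled_variogram:
        vg = fit_variogram(model.residuals, model.coords, min_points=min_points)
        model.variograms = {"__pooled__": vg}
    else:
        vgs = {}
        for city in np.unique(model.cities):
            m = model.cities == city
            vgs[str(city)] = fit_variogram(
                model.residuals[m], model.coords[m], min_points=min_points
            )
        model.variograms = vgs
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------
def _krige_residuals(
    vg: VariogramFit,
    train_coords: np.ndarray,
    train_resid: np.ndarray,
    new_coords: np.ndarray,
) -> np.ndarray:
    """Simple kriging (known mean zero) of regression residuals."""
    if vg.partial_sill == 0.0 or len(train_coords) == 0:
        return np.zeros(len(new_coords))
    n = len(train_coords)
    D = squareform(pdist(train_coords))
    K = vg.partial_sill * np.exp(-D / vg.range_m) + vg.nugget * np.eye(n)
    d_new = np.linalg.norm(
        new_coords[:, None, :] - train_coords[None, :, :], axis=-1
    )
    k_star = vg.partial_sill * np.exp(-d_new / vg.range_m)
    try:
        chol = np.linalg.cholesky(K)
        w = np.linalg.solve(chol.T, np.linalg.solve(chol, k_star.T))
    except np.linalg.LinAlgError:
        # exact duplicates at zero nugget (repeated site-seasons share
        # coordinates) make K singular; ridge-jitter and fall back to a
        # minimum-norm solve
        warnings.warn("singular kriging system; adding ridge jitter")
        K = K + 1e-8 * max(vg.sill, 1.0) * np.eye(n)
        w, *_ = np.linalg.lstsq(K, k_star.T, rcond=None)
    pred = w.T @ train_resid
    # a near-singular system can still slip through the factorisation: kriging
    # is an interpolator, so its output cannot legitimately exceed the span of
    # the training residuals — fall back to the ridge solve if it does
    bound = 2.0 * np.max(np.abs(train_resid)) + 1e-12
    if np.any(np.abs(pred) > bound):
        warnings.warn("ill-conditioned kriging system; using ridge solve")
        K = K + 1e-6 * max(vg.sill, 1.0) * np.eye(n)
        w, *_ = np.linalg.lstsq(K, k_star.T, rcond=None)
        pred = w.T @ train_resid
    return pred


def predict(
    model: FittedModel,
    new_termset: TermSet,
    new_samples: pd.DataFrame,
    mode: str = "lur",
) -> np.ndarray:
    """Predict at new locations.  ``mode`` is "lur" or "uk"."""
    X, _ = new_termset.matrix_for(model.spec.terms)
    beta = np.array([c for _, c in model.spec.coefficients])
    pred = X @ beta
    if mode == "lur":
        return pred
    if mode != "uk":
        raise ValueError("mode must be 'lur' or 'uk'")
    if not model.is_uk:
        raise ValueError("model has no fitted variogram; use fit_uk")
    new_coords = new_samples[["x_m", "y_m"]].to_numpy(float)
    if "__pooled__" in model.variograms:
        pred = pred + _krige_residuals(
            model.variograms["__pooled__"], model.coords, model.residuals, new_coords
        )
        return pred
    new_cities = new_samples["city"].to_numpy()
    for city, vg in model.variograms.items():
        m_new = new_cities == city
        if not m_new.any():
            continue
        m_tr = model.cities == city
        pred[m_new] = pred[m_new] + _krige_residuals(
            vg, model.coords[m_tr], model.residuals[m_tr], new_coords[m_new]
        )
    return pred


# ---------------------------------------------------------------------------
# prediction grid
# ---------------------------------------------------------------------------
def make_grid(
    layout,
    urban_spacing_m: float = 250.0,
    rural_spacing_m: float = 1000.0,
) -> pd.DataFrame:
    """Lattice over a city domain: dense inside the urban core, coarse outside."""
    dom, core = layout.domain, layout.urban_core
    gx, gy = np.meshgrid(
        np.arange(dom.xmin, dom.xmax + 1e-9, rural_spacing_m),
        np.arange(dom.ymin, dom.ymax + 1e-9, rural_spacing_m),
    )
    rx, ry = gx.ravel(), gy.ravel()
    rural = ~core.contains_points(rx, ry)
    ux, uy = np.meshgrid(
        np.arange(core.xmin, core.xmax + 1e-9, urban_spacing_m),
        np.arange(core.ymin, core.ymax + 1e-9, urban_spacing_m),
    )
    x = np.concatenate([rx[rural], ux.ravel()])
    y = np.concatenate([ry[rural], uy.ravel()])
    urban = np.concatenate([np.zeros(rural.sum(), bool), np.ones(ux.size, bool)])
    return pd.DataFrame(
        dict(x_m=x, y_m=y, city=layout.city_id, urban=urban)
    )


def export_grid_predictions(
    grid: pd.DataFrame,
    predictions: np.ndarray,
    mode: str,
    csv_path=None,
    geojson_path=None,
    clip_zero: bool = False,
) -> pd.DataFrame:
    """Tabular export of grid predictions (CSV and/or GeoJSON points)."""
    out = grid.copy()
    pred = np.asarray(predictions, float)
    if clip_zero:
        pred = np.clip(pred, 0.0, None)
    out["prediction"] = pred
    out["mode"] = mode
    if csv_path is not None:
        out[["x_m", "y_m", "city", "prediction", "mode"]].to_csv(csv_path, index=False)
    if geojson_path is not None:
        import json

        features = [
            dict(
                type="Feature",
                geometry=dict(type="Point", coordinates=[float(r.x_m), float(r.y_m)]),
                properties=dict(city=r.city, prediction=float(r.prediction), mode=mode),
            )
            for r in out.itertuples()
        ]
        payload = dict(type="FeatureCollection", features=features)
        with open(geojson_path, "w") as fh:
            json.dump(payload, fh)
    return out
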