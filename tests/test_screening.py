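"""Covariate screening cascade: variability, buffer choice, correlation pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coarselur as cl
from coarselur.covariates import CovariateMatrix, CovariateMeta
from coarselur.screening import (
    prune_correlated,
    screen_covariates,
    select_buffers,
    variability_filter,
)


def _cm(cols: dict[str, np.ndarray], meta: dict[str, CovariateMeta] | None = None):
    df = pd.DataFrame(cols)
    if meta is None:
        meta = {c: CovariateMeta(category=c) for c in df.columns}
    return CovariateMatrix(df, meta)


# ---------------------------------------------------------------------------
# variability filter
# ---------------------------------------------------------------------------
def test_variability_filter_drops_flat_columns():
    cm = _cm(
        dict(
            const=np.full(12, 3.0),
            nearly=np.array([0.0] * 11 + [1.0]),  # p15 == p85 == 0
            rising=np.arange(12, dtype=float),
        )
    )
    out = variability_filter(cm)
    assert out.columns == ["rising"]


def test_variability_filter_quantile_oracle():
    """The 85th/15th equality uses linear-interpolation quantiles, matching
    a direct numpy computation on each column."""
    rng = np.random.default_rng(4)
    cols = {f"c{i}": rng.choice([0.0, 0.0, 0.0, 1.0, 2.0], 20) for i in range(10)}
    cm = _cm(cols)
    out = variability_filter(cm)
    expected = [
        name
        for name, v in cols.items()
        if np.percentile(v, 15) != np.percentile(v, 85)
    ]
    assert out.columns == expected


# ---------------------------------------------------------------------------
# buffer selection
# ---------------------------------------------------------------------------
def _buffered_cm(radii, values, category="roads"):
    meta = {
        f"{category}_{r}m": CovariateMeta(category=category, buffer_radius_m=float(r))
        for r in radii
    }
    data = pd.DataFrame({f"{category}_{r}m": v for r, v in zip(radii, values)})
    return CovariateMatrix(data, meta)


def test_select_buffers_matches_brute_force_scan():
    """The kept buffer per range window is the |Pearson r| argmax, checked
    against a brute-force scan."""
    rng = np.random.default_rng(1)
    n = 80
    y = rng.normal(size=n)
    radii = [50, 150, 300, 750, 1500, 5000]
    values = [0.3 * k * y + rng.normal(size=n) for k in (1, 4, 3, 2, 5, 1)]
    cm = _buffered_cm(radii, values)
    out = select_buffers(cm, y)

    def absr(v):
        return abs(np.corrcoef(v, y)[0, 1])

    short = max((r for r in radii if 50 <= r <= 500), key=lambda r: absr(cm.data[f"roads_{r}m"]))
    long = max((r for r in radii if r > 500), key=lambda r: absr(cm.data[f"roads_{r}m"]))
    assert set(out.columns) == {f"roads_{short}m", f"roads_{long}m"}


def test_select_buffers_single_candidate_kept_and_unbuffered_pass():
    rng = np.random.default_rng(2)
    n = 40
    y = rng.normal(size=n)
    cm = _cm(
        dict(roads_300m=rng.normal(size=n), dist_a1=rng.normal(size=n)),
        meta=dict(
            roads_300m=CovariateMeta(category="roads", buffer_radius_m=300.0),
            dist_a1=CovariateMeta(category="dist_a1"),
        ),
    )
    out = select_buffers(cm, y)
    assert set(out.columns) == {"roads_300m", "dist_a1"}


def test_select_buffers_tie_breaks_to_smaller_radius():
    rng = np.random.default_rng(3)
    v = rng.normal(size=30)
    y = rng.normal(size=30)
    cm = _buffered_cm([100, 400], [v, v.copy()])  # identical columns, tied |r|
    out = select_buffers(cm, y)
    assert out.columns == ["roads_100m"]


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------
def test_prune_prefers_raster_over_aerial_for_identical_columns():
    rng = np.random.default_rng(5)
    v = rng.normal(size=50)
    y = rng.normal(size=50)
    cm = _cm(
        dict(lu_comm_aerial=v, lu_comm_raster=v.copy()),
        meta=dict(
            lu_comm_aerial=CovariateMeta(category="a", vintage="aerial197x"),
            lu_comm_raster=CovariateMeta(category="b", vintage="raster2000"),
        ),
    )
    out = prune_correlated(cm, y)
    assert out.columns == ["lu_comm_raster"]


def test_prune_positional_preferentially_excluded():
    rng = np.random.default_rng(6)
    v = rng.normal(size=50)
    y = v + 0.1 * rng.normal(size=50)
    cm = _cm(
        dict(pos_x=v, imperv=v + 0.01 * rng.normal(size=50)),
        meta=dict(
            pos_x=CovariateMeta(category="position", positional=True),
            imperv=CovariateMeta(category="imperv"),
        ),
    )
    out = prune_correlated(cm, y)
    assert out.columns == ["imperv"]


def test_prune_below_threshold_keeps_both():
    rng = np.random.default_rng(7)
    a = rng.normal(size=400)
    b = 0.8 * a + np.sqrt(1 - 0.8**2) * rng.normal(size=400)
    cm = _cm(dict(a=a, b=b))
    rho = abs(np.corrcoef(a, b)[0, 1])
    assert rho < 0.85  # construction check
    out = prune_correlated(cm, a + b)
    assert set(out.columns) == {"a", "b"}


def test_prune_clique_keeps_strongest_exposure_correlate():
    """In a 3-clique (|rho| > 0.85 pairwise), the member with the largest
    |r(x, y)| survives."""
    corr = np.array(
        [
            [1.0, 0.87, 0.87, 0.20],
            [0.87, 1.0, 0.87, 0.50],
            [0.87, 0.87, 1.0, 0.40],
            [0.20, 0.50, 0.40, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(8)
    z = rng.normal(size=(4, 5000))
    x1, x2, x3, y = chol @ z
    cm = _cm(dict(x1=x1, x2=x2, x3=x3))
    rho = np.corrcoef(np.vstack([x1, x2, x3]))
    assert (np.abs(rho[np.triu_indices(3, 1)]) > 0.85).all()  # construction check
    out = prune_correlated(cm, y)
    assert out.columns == ["x2"]


# ---------------------------------------------------------------------------
# cascade properties
# ---------------------------------------------------------------------------
def test_cascade_trace_accounts_for_every_column(campaign, valid_samples):
    cov = campaign.covariates.align_to(valid_samples)
    y = valid_samples["coarse"].to_numpy()
    out, trace = screen_covariates(cov, y)
    assert trace.accounted() == set(cov.columns)
    assert len(out.columns) <= len(cov.columns)
    assert trace.survivors == out.columns


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3), col=st.integers(0, 5))
def test_cascade_scale_invariance(campaign, valid_samples, scale, col):
    """Multiplying any column by a positive constant changes no decision."""
    cov = campaign.covariates.align_to(valid_samples)
    y = valid_samples["coarse"].to_numpy()
    base, _ = screen_covariates(cov, y)
    scaled = cov.data.copy()
    scaled[scaled.columns[col]] = scaled[scaled.columns[col]] * scale
    out, _ = screen_covariates(CovariateMatrix(scaled, dict(cov.meta)), y)
    assert out.columns == base.columns


def test_full_library_reduces_to_reported_order():
    """A full Table-1-patterned library (hundreds of columns) screens down to
    the order of magnitude the field reports (here asserted loosely)."""
    schema = cl.table1_schema()
    assert len(schema.names) > 200
    layouts = cl.default_layouts()
    truth = cl.default_truth(seed=21)
    campaigns = cl.generate_study(layouts, schema, truth)
    samples = pd.concat([c.samples for c in campaigns], ignore_index=True)
    valid, _ = cl.apply_qc(samples)
    cov_all = CovariateMatrix(
        pd.concat([c.covariates.data for c in campaigns]),
        dict(campaigns[0].covariates.meta),
    ).align_to(valid)
    out, _ = screen_covariates(cov_all, valid["coarse"].to_numpy())
    assert 30 <= len(out.columns) <= 150
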