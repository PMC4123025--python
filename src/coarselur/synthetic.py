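"""Synthetic snapshot-campaign generator with known ground truth.

Emulates a two-season, multi-city coarse-PM (PM10-2.5) monitoring campaign:
~30-60 residential sites per city sampled for two weeks per season with paired
PM10/PM2.5 impactors, a library of buffered geographic covariates, and the
quality-control defects such field campaigns accumulate (short sampling
durations, out-of-range pump flows, gross outliers, coarse-fraction sulfur
contamination).

Concentrations are generated as

    y(s, season) = b0 + sum_j beta_j z_j(s) + season effects + eta(s) + eps

where ``z_j`` are standardised covariates, ``eta`` is a Gaussian random field
with exponential covariance C(d) = sill * exp(-d / range) plus a nugget, and
``eps`` is measurement noise (lognormal-multiplicative by default).  Buffered
covariates are produced by averaging a shared latent surface over disks of
increasing radius, which yields the nested-buffer correlation structure seen
in real GIS extractions.  Every generated campaign carries a truth ledger
(true coefficients, variogram parameters, injected-defect list) so downstream
stages can be tested against a known answer.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .covariates import CovariateMatrix, CovariateMeta

SEASONS = ("winter", "summer")
SPECIES = ("copper", "zinc", "phosphorus", "silicon")  # Cu/Zn/P in ng/m3, Si in ug/m3


# ---------------------------------------------------------------------------
# layout / schema / truth
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Rect:
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError("degenerate rectangle")

    def contains(self, other: "Rect") -> bool:
        return (
            self.xmin <= other.xmin
            and self.ymin <= other.ymin
            and self.xmax >= other.xmax
            and self.ymax >= other.ymax
        )

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


@dataclass(frozen=True)
class CityLayout:
    """Spatial design of one city's campaign (projected meters)."""

    city_id: str
    domain: Rect
    n_sites: int
    urban_core: Rect
    seasons: tuple[str, str] = SEASONS

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        if not self.domain.contains(self.urban_core):
            raise ValueError("urban_core must lie inside domain")
        if len(self.seasons) != 2:
            raise ValueError("exactly two seasons required")


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    category: str
    buffer_radius_m: float | None = None
    positional: bool = False
    vintage: str = "raster2000"

    def meta(self) -> CovariateMeta:
        return CovariateMeta(
            category=self.category,
            buffer_radius_m=self.buffer_radius_m,
            positional=self.positional,
            vintage=self.vintage,
        )


@dataclass(frozen=True)
class CovariateSchema:
    entries: tuple[SchemaEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        if not self.entries:
            raise ValueError("schema must be nonempty")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def buffered_categories(self) -> dict[str, list[SchemaEntry]]:
        out: dict[str, list[SchemaEntry]] = {}
        for e in self.entries:
            if e.buffer_radius_m is not None:
                out.setdefault(e.category, []).append(e)
        return out


def _buffered(category: str, radii: Sequence[float], vintage: str = "raster2000"):
    return [
        SchemaEntry(f"{category}_{int(r)}m", category, float(r), vintage=vintage)
        for r in radii
    ]


#: buffer radii used by the satellite land-use / road-length variables
LU_RADII = (50, 100, 150, 300, 400, 500, 750, 1000, 1500, 3000, 5000)
AERIAL_RADII = (50, 100, 150)
TRUCK_RADII = (100, 150, 300, 400, 500, 750, 1000, 1500, 3000, 5000, 10000, 15000)
IMPERV_RADII = (50, 100, 150, 300, 400, 500, 750, 1000, 3000, 5000)
NDVI_RADII = (250, 500, 1000, 5000)
POP_RADII = (3000, 5000, 10000, 15000)
CALINE_RADII = (1500, 3000, 4500, 6000, 7500, 9000)
EMIS_RADII = (3000, 15000, 30000)

SATELLITE_CLASSES = (
    "lu_water", "lu_open", "lu_devlow", "lu_devmed", "lu_devhigh", "lu_barren",
    "lu_trees", "lu_shrub", "lu_grass", "lu_pasture", "lu_crops", "lu_wetland",
)
AERIAL_CLASSES = (
    "alu_resid", "alu_comm", "alu_indus", "alu_otherurban",
    "alu_mixedurban", "alu_mines", "alu_complex", "alu_transition",
)


def table1_schema() -> CovariateSchema:
    """Full covariate library patterned on the field study's GIS extraction."""
    entries: list[SchemaEntry] = []
    for c in SATELLITE_CLASSES:
        entries += _buffered(c, LU_RADII, vintage="raster2000")
    for c in AERIAL_CLASSES:
        entries += _buffered(c, AERIAL_RADII, vintage="aerial197x")
    for road in ("a1", "a2", "a3"):
        entries.append(SchemaEntry(f"dist_{road}", f"dist_{road}", vintage="na"))
        entries += _buffered(f"road_{road}", LU_RADII, vintage="na")
    for target in ("truckroute", "railroad", "railyard", "airport", "port"):
        entries.append(SchemaEntry(f"dist_{target}", f"dist_{target}", vintage="na"))
    entries += _buffered("truck_len", TRUCK_RADII, vintage="na")
    entries += _buffered("caline", CALINE_RADII, vintage="na")
    entries += _buffered("popdens", POP_RADII, vintage="na")
    entries += _buffered("imperv", IMPERV_RADII, vintage="na")
    entries += _buffered("ndvi_q25", NDVI_RADII, vintage="na")
    entries += _buffered("ndvi_q75", NDVI_RADII, vintage="na")
    entries += _buffered("emissions", EMIS_RADII, vintage="na")
    entries.append(SchemaEntry("pos_x", "position", positional=True, vintage="na"))
    entries.append(SchemaEntry("pos_y", "position", positional=True, vintage="na"))
    entries.append(SchemaEntry("dist_cityhall", "position", positional=True, vintage="na"))
    entries.append(SchemaEntry("dist_localhall", "position", positional=True, vintage="na"))
    return CovariateSchema(tuple(entries))


def compact_schema() -> CovariateSchema:
    """Small library for fast tests and the demo configuration."""
    entries: list[SchemaEntry] = []
    for c in ("lu_devhigh", "lu_trees", "lu_crops"):
        entries += _buffered(c, (50, 100, 300, 500, 1000, 5000))
    entries += _buffered("alu_indus", AERIAL_RADII, vintage="aerial197x")
    entries += _buffered("road_a1", (50, 100, 300, 500, 1000, 5000), vintage="na")
    entries += _buffered("imperv", (100, 300, 1000, 5000), vintage="na")
    entries += _buffered("ndvi_q75", NDVI_RADII, vintage="na")
    entries += _buffered("popdens", POP_RADII, vintage="na")
    entries.append(SchemaEntry("dist_a1", "dist_a1", vintage="na"))
    entries.append(SchemaEntry("pos_x", "position", positional=True, vintage="na"))
    entries.append(SchemaEntry("pos_y", "position", positional=True, vintage="na"))
    return CovariateSchema(tuple(entries))


@dataclass
class CampaignTruth:
    """Generator parameters: the ground truth a campaign is drawn from.

    ``beta`` maps covariate names to coefficients on the *standardised*
    (z-scored) covariate, so units are ug/m3 per covariate SD.  ``season_main``
    is the summer-minus-winter offset; ``season_interactions`` modify named
    covariate slopes in summer.  The spatial residual has exponential
    covariance with the stated range/sill plus a nugget drawn independently
    per sample.  Defect rates are per-sample injection probabilities.
    """

    beta: dict[str, float] = field(default_factory=dict)
    intercept: float = 4.5
    season_main: float = 0.8
    season_interactions: dict[str, float] = field(default_factory=dict)
    spatial_range_m: float = 3000.0
    spatial_sill: float = 0.5
    nugget: float = 0.3
    noise_sigma: float = 0.10
    noise_model: str = "lognormal"  # or "gaussian" (additive, sigma in ug/m3)
    outlier_rate: float = 0.0
    defect_rates: dict[str, float] = field(default_factory=dict)  # duration/flow/sulfur
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_range_m < 0 or self.spatial_sill < 0 or self.nugget < 0:
            raise ValueError("variogram parameters must be nonnegative")
        rates = dict(self.defect_rates)
        rates["outlier"] = self.outlier_rate
        for k, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"defect rate {k}={v} outside [0, 1]")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError("noise_model must be 'lognormal' or 'gaussian'")


def default_truth(seed: int = 0) -> CampaignTruth:
    """Study-condition defaults: a sparse signal on traffic, development and
    vegetation covariates, a modest seasonal offset, and residual spatial
    structure that is partly nugget."""
    return CampaignTruth(
        beta={
            "lu_devhigh_300m": 0.9,
            "road_a1_100m": 0.7,
            "imperv_1000m": 0.6,
            "lu_trees_500m": -0.5,
            "popdens_5000m": 0.4,
        },
        intercept=4.5,
        season_main=0.8,
        season_interactions={"lu_trees_500m": -0.4},
        spatial_range_m=3000.0,
        spatial_sill=0.4,
        nugget=0.4,
        noise_sigma=0.10,
        outlier_rate=0.02,
        defect_rates={"duration": 0.05, "flow": 0.05, "sulfur": 0.05},
        seed=seed,
    )


def default_layouts() -> list[CityLayout]:
    """Three cities, ~40 sites each, 30 km domains with a 10 km urban core."""
    out = []
    for i, city in enumerate(("chicago", "stpaul", "winstonsalem")):
        x0 = 1.0e5 * (i + 1)
        dom = Rect(x0, 0.0, x0 + 30_000.0, 30_000.0)
        core = Rect(x0 + 10_000.0, 10_000.0, x0 + 20_000.0, 20_000.0)
        out.append(CityLayout(city, dom, 40, core))
    return out


# ---------------------------------------------------------------------------
# latent surfaces and buffered aggregation
# ---------------------------------------------------------------------------
class BumpField:
    """Smooth latent surface: a mixture of Gaussian bumps over the domain."""

    def __init__(self, rng: np.random.Generator, domain: Rect, n_bumps: int = 25):
        w = domain.xmax - domain.xmin
        h = domain.ymax - domain.ymin
        self.cx = rng.uniform(domain.xmin - 0.1 * w, domain.xmax + 0.1 * w, n_bumps)
        self.cy = rng.uniform(domain.ymin - 0.1 * h, domain.ymax + 0.1 * h, n_bumps)
        self.sigma = rng.uniform(0.03, 0.25, n_bumps) * max(w, h)
        self.amp = rng.normal(0.0, 1.0, n_bumps)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)[:, None]
        y = np.asarray(y, float)[:, None]
        d2 = (x - self.cx[None, :]) ** 2 + (y - self.cy[None, :]) ** 2
        return (self.amp[None, :] * np.exp(-0.5 * d2 / self.sigma[None, :] ** 2)).sum(axis=1)


# fixed disk quadrature: centre + 3 rings x 8 angles, area-ish weighting
_QUAD_FRAC = np.array([0.0] + [f for f in (0.35, 0.7, 1.0) for _ in range(8)])
_QUAD_ANG = np.array([0.0] + [2 * math.pi * k / 8 for _ in range(3) for k in range(8)])
_QUAD_W = np.array([1.0] + [0.35] * 8 + [0.7] * 8 + [1.0] * 8)
_QUAD_W = _QUAD_W / _QUAD_W.sum()


def buffer_average(field: Callable, x: np.ndarray, y: np.ndarray, radius: float) -> np.ndarray:
    """Average of a latent surface over a disk, via fixed ring quadrature.

    Nested radii share the inner quadrature structure of the same surface,
    which is what makes 100 m and 300 m buffers of one category correlate
    more strongly than 100 m and 5000 m buffers.
    """
    qx = x[:, None] + radius * _QUAD_FRAC[None, :] * np.cos(_QUAD_ANG)[None, :]
    qy = y[:, None] + radius * _QUAD_FRAC[None, :] * np.sin(_QUAD_ANG)[None, :]
    flat = field(qx.ravel(), qy.ravel()).reshape(qx.shape)
    return flat @ _QUAD_W


def covariates_at(
    schema: CovariateSchema,
    fields: dict[str, BumpField],
    x: np.ndarray,
    y: np.ndarray,
    layout: CityLayout,
) -> pd.DataFrame:
    """Evaluate every schema covariate at arbitrary coordinates."""
    cx = 0.5 * (layout.urban_core.xmin + layout.urban_core.xmax)
    cy = 0.5 * (layout.urban_core.ymin + layout.urban_core.ymax)
    cols: dict[str, np.ndarray] = {}
    for e in schema.entries:
        if e.positional:
            if e.name == "pos_x":
                cols[e.name] = np.asarray(x, float)
            elif e.name == "pos_y":
                cols[e.name] = np.asarray(y, float)
            else:  # distance to (main/local) city hall
                jitter = 2000.0 if "local" in e.name else 0.0
                cols[e.name] = np.hypot(x - (cx + jitter), y - (cy + jitter))
        elif e.buffer_radius_m is None:
            # distance-like covariate: positive, right-skewed transform of
            # its category's latent surface
            lat = fields[e.category](np.asarray(x, float), np.asarray(y, float))
            cols[e.name] = 500.0 * np.exp(0.8 * lat)
        else:
            cols[e.name] = buffer_average(
                fields[e.category], np.asarray(x, float), np.asarray(y, float),
                e.buffer_radius_m,
            )
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# spatial residual field
# ---------------------------------------------------------------------------
def exponential_field(
    coords: np.ndarray, sill: float, range_m: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one realisation of a zero-mean GRF with C(d) = sill*exp(-d/range)."""
    n = len(coords)
    if sill <= 0 or n == 0:
        return np.zeros(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = sill * np.exp(-d / max(range_m, 1e-9))
    jitter = 0.0
    for _ in range(6):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            if jitter > 0:
                warnings.warn(f"covariance jittered by {jitter:g} for PD")
            return chol @ rng.standard_normal(n)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * sill if jitter == 0 else jitter * 100
    raise np.linalg.LinAlgError("covariance not positive definite after jitter")


# ---------------------------------------------------------------------------
# campaign generation
# ---------------------------------------------------------------------------
@dataclass
class Campaign:
    """One generated city campaign: sample table, covariates, truth ledger.

    The latent surfaces are retained so covariates can be evaluated on a
    prediction grid with ``covariates_at``.
    """

    samples: pd.DataFrame
    covariates: CovariateMatrix
    ledger: dict
    layout: CityLayout
    schema: CovariateSchema
    fields: dict[str, BumpField] = field(default_factory=dict, repr=False)

    def covariates_at(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        return covariates_at(self.schema, self.fields, x, y, self.layout)


_SPECIES_PARAMS = {
    # intercept (native units), scale on the mass linear predictor, noise sd
    "copper": dict(base=4.0, coupling=0.8, sigma=0.8),
    "zinc": dict(base=8.0, coupling=2.5, sigma=3.0),
    "phosphorus": dict(base=14.0, coupling=1.2, sigma=2.5),
    "silicon": dict(base=0.40, coupling=0.03, sigma=0.05),
}


def generate_campaign(
    layout: CityLayout,
    schema: CovariateSchema,
    truth: CampaignTruth,
    seed: int | None = None,
    repeat_fraction: float | None = None,
) -> Campaign:
    """Generate a two-season campaign for one city.

    By default every site is sampled in both seasons; ``repeat_fraction``
    thins to the field design where only that fraction of homes repeats.
    Thinning happens *before* QC-defect injection so the injected >5 SD
    outliers are judged against the strata the QC stage will actually see.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = layout.n_sites
    dom, core = layout.domain, layout.urban_core

    # site placement: half the sites in the urban core, half across the domain
    n_core = n // 2
    x = np.concatenate([
        rng.uniform(core.xmin, core.xmax, n_core),
        rng.uniform(dom.xmin, dom.xmax, n - n_core),
    ])
    y = np.concatenate([
        rng.uniform(core.ymin, core.ymax, n_core),
        rng.uniform(dom.ymin, dom.ymax, n - n_core),
    ])
    site_ids = [f"{layout.city_id}_{i:03d}" for i in range(n)]

    fields = {
        cat: BumpField(rng, dom)
        for cat in sorted({e.category for e in schema.entries if not e.positional})
    }
    cov_df = covariates_at(schema, fields, x, y, layout)
    cov_df.index = pd.Index(site_ids, name="site_id")
    covariates = CovariateMatrix(cov_df, {e.name: e.meta() for e in schema.entries})

    # standardisation constants for the linear predictor
    standardize = {}
    for name in truth.beta:
        if name not in cov_df.columns:
            raise KeyError(f"truth.beta names unknown covariate {name!r}")
    for name in set(truth.beta) | set(truth.season_interactions):
        col = cov_df[name].to_numpy()
        sd = col.std(ddof=1)
        standardize[name] = (float(col.mean()), float(sd if sd > 0 else 1.0))

    def zcol(name: str) -> np.ndarray:
        m, s = standardize[name]
        return (cov_df[name].to_numpy() - m) / s

    base_lp = np.full(n, truth.intercept) + sum(
        b * zcol(nm) for nm, b in truth.beta.items()
    )
    coords = np.column_stack([x, y])

    rows = []
    oracle = []
    for season in layout.seasons:
        summer = 1.0 if season == layout.seasons[1] else 0.0
        lp = base_lp + summer * truth.season_main
        for nm, b in truth.season_interactions.items():
            lp = lp + summer * b * zcol(nm)
        eta = exponential_field(coords, truth.spatial_sill, truth.spatial_range_m, rng)
        nug = (
            rng.normal(0.0, math.sqrt(truth.nugget), n) if truth.nugget > 0 else np.zeros(n)
        )
        signal = lp + eta + nug
        if truth.noise_sigma > 0:
            if truth.noise_model == "lognormal":
                mult = np.exp(
                    rng.normal(0.0, truth.noise_sigma, n) - 0.5 * truth.noise_sigma**2
                )
                obs = signal * mult
            else:
                obs = signal + rng.normal(0.0, truth.noise_sigma, n)
        else:
            obs = signal.copy()

        pm25 = rng.lognormal(math.log(10.0), 0.2, n)
        for i in range(n):
            rows.append(
                dict(
                    sample_id=f"{site_ids[i]}_{season}",
                    site_id=site_ids[i],
                    city=layout.city_id,
                    season=season,
                    x_m=x[i],
                    y_m=y[i],
                    pm25=pm25[i],
                    coarse=obs[i],
                    duration_days=rng.uniform(13.0, 14.0),
                    flow_deviation_fraction=float(
                        np.clip(rng.normal(0.0, 0.05), -0.15, 0.15)
                    ),
                    coarse_sulfur=float(np.clip(abs(rng.normal(0.05, 0.03)), 0.0, 0.15)),
                    damaged=False,
                    duplicate_flag=False,
                    species_valid=True,
                )
            )
            oracle.append(
                dict(
                    sample_id=f"{site_ids[i]}_{season}",
                    linear_predictor=float(lp[i]),
                    spatial=float(eta[i]),
                    nugget=float(nug[i]),
                )
            )

    samples = pd.DataFrame(rows)

    # physical non-negativity: truncate and count
    neg = samples["coarse"] < 0
    n_truncated = int(neg.sum())
    samples.loc[neg, "coarse"] = 0.0

    # species: same linear+spatial mechanism through a per-species coupling
    lp_all = np.array([o["linear_predictor"] + o["spatial"] for o in oracle])
    for sp, p in _SPECIES_PARAMS.items():
        v = p["base"] + p["coupling"] * (lp_all - truth.intercept) + rng.normal(
            0.0, p["sigma"], len(samples)
        )
        samples[sp] = np.clip(v, 0.0, None)

    # field design: only a fraction of homes repeats across seasons
    if repeat_fraction is not None and repeat_fraction < 1.0:
        keep_seed = int(rng.integers(0, 2**31 - 1))
        samples = repeat_subset(samples, repeat_fraction, seed=keep_seed)

    # ---- QC defect injection -------------------------------------------
    defects = _inject_defects(samples, truth, rng)
    samples["pm10"] = samples["pm25"] + samples["coarse"]

    lp_by_id = {o["sample_id"]: o["linear_predictor"] for o in oracle}
    clean = ~samples["sample_id"].isin([d["sample_id"] for d in defects])
    y_clean = samples.loc[clean, "coarse"].to_numpy()
    lp_clean = np.array([lp_by_id[i] for i in samples.loc[clean, "sample_id"]])
    var_y = y_clean.var(ddof=1)
    oracle_r2 = float(1.0 - np.mean((y_clean - lp_clean) ** 2) / var_y) if var_y > 0 else float("nan")

    ledger = dict(
        beta=dict(truth.beta),
        intercept=truth.intercept,
        season_main=truth.season_main,
        season_interactions=dict(truth.season_interactions),
        standardize=standardize,
        variogram=dict(
            range_m=truth.spatial_range_m, sill=truth.spatial_sill, nugget=truth.nugget
        ),
        defects=defects,
        n_truncated_negative=n_truncated,
        oracle=oracle,
        oracle_r2=oracle_r2,
        seed=int(truth.seed if seed is None else seed),
        city=layout.city_id,
    )
    return Campaign(samples, covariates, ledger, layout, schema, fields)


def _inject_defects(
    samples: pd.DataFrame, truth: CampaignTruth, rng: np.random.Generator
) -> list[dict]:
    """Inject QC defects in place; return the ledger's defect list.

    A sample receives at most one defect.  When several defect types fire for
    one sample, the one kept follows the QC voiding precedence
    (duration > flow > outlier > sulfur) so the ledger reason matches the
    report.  At most one >5 SD outlier is injected per city-season stratum,
    and only in strata with at least 30 otherwise-clean candidates: with a
    single-pass mean/SD the standardised deviation of one point is bounded by
    (n-1)/sqrt(n), so two extremes in a small stratum could not both be
    flagged.
    """
    n = len(samples)
    rates = truth.defect_rates
    draw = {
        kind: rng.random(n) < rates.get(kind, 0.0) for kind in ("duration", "flow", "sulfur")
    }
    outlier_draw = rng.random(n) < truth.outlier_rate

    defects: list[dict] = []
    assigned = np.zeros(n, dtype=bool)

    def assign(i: int, reason: str) -> None:
        assigned[i] = True
        defects.append(dict(sample_id=samples.at[i, "sample_id"], reason=reason))

    for i in range(n):
        if draw["duration"][i]:
            samples.at[i, "duration_days"] = rng.uniform(4.0, 8.5)
            assign(i, "duration")
        elif draw["flow"][i]:
            samples.at[i, "flow_deviation_fraction"] = float(
                rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 0.40)
            )
            assign(i, "flow")

    # outliers: per-stratum, on the candidate set that survives duration/flow
    for (_, _), idx in samples.groupby(["city", "season"]).indices.items():
        idx = np.asarray(idx)
        cand = idx[~assigned[idx]]
        if len(cand) < 30:
            continue
        hits = [i for i in cand if outlier_draw[i]]
        if not hits:
            continue
        i = hits[0]
        vals = samples.loc[cand, "coarse"].to_numpy()
        samples.at[i, "coarse"] = float(vals.mean() + 50.0 * vals.std(ddof=1))
        assign(i, "outlier")

    for i in range(n):
        if draw["sulfur"][i] and not assigned[i]:
            samples.at[i, "coarse_sulfur"] = float(rng.uniform(0.25, 0.60))
            assign(i, "sulfur")

    return defects


def repeat_subset(
    samples: pd.DataFrame, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Thin a both-season campaign to the field design: only ``fraction`` of
    sites (floor) keep both seasons; the rest keep one season at random."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = samples["site_id"].unique()
    n_rep = int(math.floor(fraction * len(sites)))
    repeated = set(rng.choice(sites, size=n_rep, replace=False))
    keep = np.ones(len(samples), dtype=bool)
    seasons = samples["season"].unique()
    for s in sites:
        if s in repeated:
            continue
        drop_season = seasons[rng.integers(0, len(seasons))]
        keep &= ~((samples["site_id"] == s) & (samples["season"] == drop_season)).to_numpy()
    return samples[keep].reset_index(drop=True)


def generate_study(
    layouts: Sequence[CityLayout],
    schema: CovariateSchema,
    truth: CampaignTruth,
    repeat_fraction: float | None = 1.0 / 3.0,
) -> list[Campaign]:
    """Generate the full multi-city study; per-city seeds derive from
    ``truth.seed`` by fixed offsets."""
    campaigns = []
    for k, layout in enumerate(layouts):
        c = generate_campaign(
            layout, schema, truth,
            seed=truth.seed + 1000 * (k + 1),
            repeat_fraction=repeat_fraction,
        )
        campaigns.append(c)
    return campaigns


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------
def write_samples_csv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ledger(ledger: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ledger, indent=1, default=float))


def read_ledger(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
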