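"""End-to-end orchestration: simulate -> qc -> screen -> fit -> cv -> predict.

A :class:`RunConfig` (YAML-loadable) fixes the campaign layouts, covariate
schema, generator truth, the scopes and outcomes to model, the sensitivity
switches, and a master seed.  Stage seeds derive from the master seed by
fixed offsets so partial reruns stay reproducible.  Rerunning an identical
config reproduces byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import CovariateMatrix
from .evaluation import cross_validate, report_table
from .qc import QcRules, apply_qc
from .screening import screen_covariates
from .selection import Standardizer, TermSet, select_model
from .spatial import export_grid_predictions, fit_lur, fit_uk, make_grid, predict
from .summaries import summary_table, write_summary_csv
from .synthetic import (
    Campaign,
    CityLayout,
    compact_schema,
    default_layouts,
    default_truth,
    generate_study,
    table1_schema,
    write_ledger,
    write_samples_csv,
)

# fixed per-stage offsets from the master seed
STAGE_OFFSETS = {"simulate": 11, "repeat": 13, "folds": 17}
LOG_FLOOR = 0.05  # ug/m3 floor before natural-log transform


@dataclass
class RunConfig:
    seed: int = 0
    schema: str = "compact"  # "compact" | "table1"
    n_sites: int | None = None
    repeat_fraction: float = 1.0 / 3.0
    truth: dict = field(default_factory=dict)  # CampaignTruth overrides
    scopes: tuple[str, ...] = ("city",)
    outcomes: tuple[str, ...] = ("coarse",)
    cities: tuple[str, ...] | None = None  # None = all layout cities
    k_folds: int = 10
    log_transform: bool = False
    drop_outliers_3sd: bool = False
    urban_spacing_m: float = 250.0
    rural_spacing_m: float = 1000.0
    write_grid: bool = True
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scopes", "outcomes", "cities"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_OFFSETS[stage]) % (2**31 - 1)


def _build_inputs(config: RunConfig):
    layouts = default_layouts()
    if config.cities:
        layouts = [l for l in layouts if l.city_id in config.cities]
    if config.n_sites:
        layouts = [
            CityLayout(l.city_id, l.domain, config.n_sites, l.urban_core, l.seasons)
            for l in layouts
        ]
    schema = table1_schema() if config.schema == "table1" else compact_schema()
    truth = default_truth(seed=config.stage_seed("simulate"))
    if config.truth:
        truth = dataclasses.replace(truth, **config.truth)
    return layouts, schema, truth


def prepare_outcome(
    samples: pd.DataFrame, outcome: str, config: RunConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply the modelling-time sensitivity switches to one outcome."""
    df = samples.reset_index(drop=True)
    if config.drop_outliers_3sd:
        keep = np.ones(len(df), bool)
        for city, grp in df.groupby("city"):
            v = grp[outcome].to_numpy(float)
            if len(v) > 2 and v.std(ddof=1) > 0:
                bad = np.abs(v - v.mean()) > 3.0 * v.std(ddof=1)
                keep[grp.index.to_numpy()[bad]] = False
        df = df[keep].reset_index(drop=True)
    y = df[outcome].to_numpy(float)
    if config.log_transform:
        y = np.log(np.clip(y, LOG_FLOOR, None))
    return df, y


def run(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    t0 = time.time()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:7.1f}s] {msg}")

    layouts, schema, truth = _build_inputs(config)
    campaigns = generate_study(
        layouts, schema, truth, repeat_fraction=config.repeat_fraction
    )
    all_samples = pd.concat([c.samples for c in campaigns], ignore_index=True)
    write_samples_csv(all_samples, out / "samples.csv")
    for c in campaigns:
        c.covariates.to_csv(out / f"covariates_{c.layout.city_id}.csv")
        write_ledger(c.ledger, out / f"truth_ledger_{c.layout.city_id}.json")
    log(f"simulated {len(all_samples)} samples in {len(campaigns)} cities")

    valid, qc_report = apply_qc(all_samples, QcRules())
    qc_report.to_json(out / "qc_report.json")
    write_samples_csv(valid, out / "samples_valid.csv")
    log(f"qc: {qc_report.n_valid}/{qc_report.n_input} valid")

    write_summary_csv(summary_table(valid), out / "table_summary.csv")

    cov_by_city = {c.layout.city_id: c.covariates for c in campaigns}
    campaigns_by_city = {c.layout.city_id: c for c in campaigns}
    reports = []
    for outcome in config.outcomes:
        for scope in config.scopes:
            if scope == "city":
                groups = [
                    (city, valid[valid["city"] == city])
                    for city in sorted(valid["city"].unique())
                ]
            else:
                groups = [("all", valid)]
            for label, sub in groups:
                sub, y = prepare_outcome(sub, outcome, config)
                cov = _align_covariates(cov_by_city, sub)
                screened, trace = screen_covariates(cov, y)
                trace.to_json(out / f"screening_{scope}_{label}_{outcome}.json")
                result, termset, std = select_model(
                    screened, sub, y,
                    outcome=outcome, scope=scope,
                    k=config.k_folds, seed=config.stage_seed("folds"),
                )
                result.to_json(out / f"selection_{scope}_{label}_{outcome}.json")
                for mode in ("lur", "uk"):
                    rep = cross_validate(
                        result.best, termset, y, sub,
                        k=config.k_folds, seed=config.stage_seed("folds"), mode=mode,
                    )
                    rep.to_json(out / f"eval_{scope}_{label}_{outcome}_{mode}.json")
                    reports.append(rep)
                log(
                    f"{scope}/{label}/{outcome}: terms={list(result.best.terms)} "
                    f"cv_rmse={result.cv_rmse:.3f} cv_r2={result.cv_r2:.3f}"
                )
                if config.write_grid:
                    _predict_grids(
                        config, campaigns_by_city, label, scope, outcome,
                        result, termset, std, screened, sub, y, out,
                    )

    report_table(reports).to_csv(out / "table_performance.csv", index=False)

    manifest = dict(
        config=dataclasses.asdict(config),
        stage_seeds={s: config.stage_seed(s) for s in STAGE_OFFSETS},
        package_version=__version__,
        numpy_version=np.__version__,
        artifacts=sorted(p.name for p in out.iterdir()),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _align_covariates(
    cov_by_city: dict[str, CovariateMatrix], samples: pd.DataFrame
) -> CovariateMatrix:
    parts = []
    meta = None
    for city in sorted(samples["city"].unique()):
        cm = cov_by_city[city]
        meta = cm.meta
        parts.append(cm.data)
    joined = CovariateMatrix(pd.concat(parts), dict(meta))
    return joined.align_to(samples)


def _predict_grids(
    config: RunConfig,
    campaigns_by_city: dict[str, Campaign],
    label: str,
    scope: str,
    outcome: str,
    result,
    termset: TermSet,
    std: Standardizer,
    screened,
    samples: pd.DataFrame,
    y: np.ndarray,
    out: Path,
) -> None:
    """Grid export: dense lattice in the urban core, coarse outside."""
    cities = (
        [label] if scope == "city" else sorted(samples["city"].unique())
    )
    lur = fit_lur(result.best, termset, y, samples)
    uk = fit_uk(result.best, termset, y, samples)
    grids = []
    for city in cities:
        camp = campaigns_by_city[city]
        grid = make_grid(
            camp.layout, config.urban_spacing_m, config.rural_spacing_m
        )
        grids.append((camp, grid))
    for mode, model in (("lur", lur), ("uk", uk)):
        frames = []
        for camp, grid in grids:
            for season in camp.layout.seasons:
                gcov = camp.covariates_at(grid["x_m"].to_numpy(), grid["y_m"].to_numpy())
                gcov = gcov[screened.columns]
                gz = std.transform(gcov)
                gmeta = pd.DataFrame(
                    dict(
                        season=season,
                        city=grid["city"],
                        x_m=grid["x_m"],
                        y_m=grid["y_m"],
                    )
                )
                # season dummy must reflect both levels seen in training
                gts = _grid_termset(gz, gmeta, samples, termset.scope)
                pred = predict(model, gts, gmeta, mode=mode)
                f = grid.copy()
                f["season"] = season
                f["prediction"] = pred
                f["mode"] = mode
                frames.append(f)
        export = pd.concat(frames, ignore_index=True)
        path = out / f"grid_{scope}_{label}_{outcome}_{mode}.csv"
        export[["x_m", "y_m", "city", "season", "prediction", "mode"]].to_csv(
            path, index=False
        )
        export_grid_predictions(
            export[["x_m", "y_m", "city"]],
            export["prediction"].to_numpy(),
            mode,
            geojson_path=out / f"grid_{scope}_{label}_{outcome}_{mode}.geojson",
        )


def _grid_termset(gz: pd.DataFrame, gmeta: pd.DataFrame, train: pd.DataFrame, scope: str):
    """Build a TermSet for grid rows whose season/city factor levels match
    the training encoding (prepend a throwaway row per missing level)."""
    seasons = sorted(train["season"].unique())
    cities = sorted(train["city"].unique())
    pad_rows = []
    for s in seasons:
        if s not in set(gmeta["season"]):
            pad_rows.append(dict(season=s, city=cities[0], x_m=0.0, y_m=0.0))
    if scope == "pooled":
        for c in cities:
            if c not in set(gmeta["city"]):
                pad_rows.append(dict(season=seasons[0], city=c, x_m=0.0, y_m=0.0))
    if pad_rows:
        pad_meta = pd.DataFrame(pad_rows)
        pad_z = pd.DataFrame(0.0, index=range(len(pad_rows)), columns=gz.columns)
        meta_all = pd.concat([pad_meta, gmeta], ignore_index=True)
        z_all = pd.concat([pad_z, gz.reset_index(drop=True)], ignore_index=True)
        full = TermSet(z_all, meta_all, scope)
        from .evaluation import _subset_termset

        mask = np.zeros(len(meta_all), bool)
        mask[len(pad_rows):] = True
        return _subset_termset(full, mask)
    return TermSet(gz.reset_index(drop=True), gmeta.reset_index(drop=True), scope)
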