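"""Cross-validated performance metrics.

CV R-squared follows the pooled-residual convention: held-out predictions are
assembled across all folds first, then R2 = 1 - SSE / SS around the mean is
computed once.  For models pooled across cities, a per-city R2 uses the sum
of squares around each city's own observed mean — this asks whether the
pooled model explains *within-city* variability, not just between-city level
differences — and negative values are reported as 0 (the raw value is kept
in the report).  The squared correlation between observations and
predictions is also reported as a separate diagnostic; it is not the primary
R2 definition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import ModelSpec, TermSet, make_folds
from .spatial import fit_lur, fit_uk, predict


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("obs and pred must be equal-length and nonempty")
    return math.sqrt(float(np.mean((obs - pred) ** 2)))


def r2_pooled(obs, pred) -> float:
    """1 - SSE/SS_mean on the pooled residuals (may be negative)."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    ss = float(np.sum((obs - obs.mean()) ** 2))
    if ss == 0:
        return float("nan")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss


def corr_r2(obs, pred) -> float:
    """Squared Pearson correlation between observations and predictions."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.std() == 0 or pred.std() == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def r2_city(obs, pred, cities) -> dict[str, dict]:
    """Per-city R2 of a pooled model, truncated at 0.

    R2_c = 1 - SSE_c / sum_c (obs - mean_c)^2 using each city's own observed
    mean.  Negative values are reported as 0; the raw value is retained.
    A city whose observations have zero variance gets R2 = None.
    """
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    cities = np.asarray(cities)
    out: dict[str, dict] = {}
    for city in sorted(np.unique(cities).tolist()):
        m = cities == city
        o, p = obs[m], pred[m]
        ss = float(np.sum((o - o.mean()) ** 2))
        entry: dict = {"n": int(m.sum()), "rmse": rmse(o, p)}
        if ss == 0:
            entry.update(r2=None, raw_r2=None)
        else:
            raw = 1.0 - float(np.sum((o - p) ** 2)) / ss
            entry.update(r2=max(raw, 0.0), raw_r2=raw)
        out[str(city)] = entry
    return out


@dataclass
class EvalReport:
    scope: str
    outcome: str
    mode: str  # "lur" or "uk"
    cv_rmse: float
    cv_r2: float
    cv_r2_raw: float
    cv_corr_r2: float
    per_city: dict[str, dict] = field(default_factory=dict)
    fold_seed: int = 0
    k: int = 10
    n: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def cross_validate(
    spec: ModelSpec,
    termset: TermSet,
    y,
    samples: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    mode: str = "lur",
    pooled_variogram: bool = False,
    min_vario_points: int = 20,
) -> EvalReport:
    """k-fold CV of a fixed model spec; held-out predictions pooled before
    metrics.  In UK mode the variogram is refitted within every training
    fold, so no held-out information leaks into the kriging weights."""
    y = np.asarray(y, float)
    samples = samples.reset_index(drop=True)
    folds = make_folds(len(y), k, seed)
    pred = np.empty_like(y)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        sub_ts = _subset_termset(termset, train)
        sub_samples = samples[train].reset_index(drop=True)
        if mode == "uk":
            model = fit_uk(
                spec, sub_ts, y[train], sub_samples,
                pooled_variogram=pooled_variogram, min_points=min_vario_points,
            )
        else:
            model = fit_lur(spec, sub_ts, y[train], sub_samples)
        test_ts = _subset_termset(termset, test)
        pred[test] = predict(
            model, test_ts, samples[test].reset_index(drop=True), mode=mode
        )

    raw = r2_pooled(y, pred)
    report = EvalReport(
        scope=spec.scope,
        outcome=spec.outcome,
        mode=mode,
        cv_rmse=rmse(y, pred),
        cv_r2=max(raw, 0.0) if not math.isnan(raw) else raw,
        cv_r2_raw=raw,
        cv_corr_r2=corr_r2(y, pred),
        per_city=(
            r2_city(y, pred, samples["city"].to_numpy())
            if spec.scope == "pooled"
            else {}
        ),
        fold_seed=seed,
        k=k,
        n=len(y),
    )
    return report


class _TermSetView:
    """Row-subset view of a TermSet (same terms/columns, fewer rows)."""

    def __init__(self, parent: TermSet, mask: np.ndarray):
        self.term_cols = parent.term_cols
        self.frame = parent.frame[mask].reset_index(drop=True)
        self.matrix = parent.matrix[mask]
        self._col_index = parent._col_index
        self.scope = parent.scope

    columns_for = TermSet.columns_for
    matrix_for = TermSet.matrix_for

    @property
    def terms(self):
        return list(self.term_cols)


def _subset_termset(termset: TermSet, mask: np.ndarray) -> _TermSetView:
    return _TermSetView(termset, mask)


def report_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Long-format performance table (one row per model x metric x city)."""
    rows = []
    for r in reports:
        rows.append(
            dict(scope=r.scope, outcome=r.outcome, mode=r.mode, city="all",
                 metric="cv_r2", value=r.cv_r2)
        )
        rows.append(
            dict(scope=r.scope, outcome=r.outcome, mode=r.mode, city="all",
                 metric="cv_rmse", value=r.cv_rmse)
        )
        for city, entry in r.per_city.items():
            rows.append(
                dict(scope=r.scope, outcome=r.outcome, mode=r.mode, city=city,
                     metric="cv_r2", value=entry["r2"])
            )
            rows.append(
                dict(scope=r.scope, outcome=r.outcome, mode=r.mode, city=city,
                     metric="cv_rmse", value=entry["rmse"])
            )
    return pd.DataFrame(rows)
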