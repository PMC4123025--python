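"""Covariate screening: variability filter, buffer selection, correlation pruning.

The raw covariate library (hundreds of buffered variables) is reduced to a
candidate set in three deterministic passes:

1. **Variability filter** — drop any column whose 85th percentile equals its
   15th percentile on the analysis rows (linear-interpolation quantiles).
2. **Buffer selection** — within each buffered category keep at most one
   short-range buffer (50-500 m) and one long-range buffer (> 500 m), the one
   with the largest absolute Pearson correlation with the outcome.
3. **Correlation pruning** — among columns correlated with each other at
   |rho| > 0.85 (connected components of the correlation graph), keep the
   member most correlated with the outcome, except that positional covariates
   (coordinates, distance to city hall) are preferentially excluded and
   raster-based land use (c. 2000) is preferred over aerial-photography land
   use (1970s).

Ties in |r| break toward the smaller buffer radius, then lexicographic name,
so the cascade is deterministic.  Every decision is recorded in a
:class:`ScreeningTrace`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariateMatrix

SHORT_RANGE = (50.0, 500.0)  # inclusive both ends
LONG_MIN = 500.0  # exclusive; no upper cap (libraries carry buffers past 5 km)
RHO_MAX_DEFAULT = 0.85


@dataclass
class ScreeningTrace:
    removed_low_variability: list[str] = field(default_factory=list)
    buffer_choices: list[dict] = field(default_factory=list)
    removed_by_buffer: list[str] = field(default_factory=list)
    pruned: list[dict] = field(default_factory=list)  # {dropped, kept, rho}
    dropped_categories: list[str] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def accounted(self) -> set[str]:
        return (
            set(self.removed_low_variability)
            | set(self.removed_by_buffer)
            | {p["dropped"] for p in self.pruned}
            | set(self.survivors)
        )


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def _tie_key(cm: CovariateMatrix, name: str, r: float):
    meta = cm.meta[name]
    radius = meta.buffer_radius_m if meta.buffer_radius_m is not None else np.inf
    return (-r, radius, name)


def variability_filter(
    cm: CovariateMatrix, trace: ScreeningTrace | None = None
) -> CovariateMatrix:
    """Drop columns whose 85th percentile equals their 15th percentile."""
    if len(cm) < 2:
        raise ValueError("need at least 2 rows")
    trace = trace if trace is not None else ScreeningTrace()
    keep = []
    for name in cm.columns:
        col = cm.data[name].to_numpy(float)
        p15, p85 = np.percentile(col, [15, 85], method="linear")
        if p15 == p85:
            trace.removed_low_variability.append(name)
        else:
            keep.append(name)
    return cm.select(keep)


def select_buffers(
    cm: CovariateMatrix, y, trace: ScreeningTrace | None = None
) -> CovariateMatrix:
    """Keep <=1 short-range and <=1 long-range buffer per buffered category."""
    trace = trace if trace is not None else ScreeningTrace()
    y = np.asarray(y, float)
    if len(y) != len(cm):
        raise ValueError("y must align with covariate rows")

    by_cat: dict[str, list[str]] = {}
    unbuffered: list[str] = []
    for name in cm.columns:
        if cm.meta[name].buffer_radius_m is None:
            unbuffered.append(name)
        else:
            by_cat.setdefault(cm.meta[name].category, []).append(name)

    keep = list(unbuffered)
    for cat in sorted(by_cat):
        names = by_cat[cat]
        chosen: list[str] = []
        for label, in_range in (
            ("short", lambda r: SHORT_RANGE[0] <= r <= SHORT_RANGE[1]),
            ("long", lambda r: r > LONG_MIN),
        ):
            cands = [n for n in names if in_range(cm.meta[n].buffer_radius_m)]
            cands = [n for n in cands if cm.data[n].to_numpy(float).std() > 0]
            if not cands:
                continue
            scored = sorted(
                cands,
                key=lambda n: _tie_key(cm, n, _abs_pearson(cm.data[n].to_numpy(float), y)),
            )
            best = scored[0]
            chosen.append(best)
            trace.buffer_choices.append(
                dict(
                    category=cat,
                    range=label,
                    kept=best,
                    abs_r=_abs_pearson(cm.data[best].to_numpy(float), y),
                )
            )
        if not chosen:
            trace.dropped_categories.append(cat)
        keep.extend(chosen)
        trace.removed_by_buffer.extend(n for n in names if n not in chosen)

    keep = [n for n in cm.columns if n in set(keep)]  # preserve column order
    return cm.select(keep)


def prune_correlated(
    cm: CovariateMatrix,
    y,
    rho_max: float = RHO_MAX_DEFAULT,
    trace: ScreeningTrace | None = None,
) -> CovariateMatrix:
    """Resolve groups of mutually correlated covariates (|rho| > rho_max).

    Each connected component of the |rho|-threshold graph is resolved
    greedily: pick the best member (preference class first — non-positional
    before positional, raster before aerial — then largest |r(x, y)|), keep
    it, drop its over-threshold neighbours, repeat on the remainder.
    """
    if not 0.0 < rho_max < 1.0:
        raise ValueError("rho_max must lie in (0, 1)")
    trace = trace if trace is not None else ScreeningTrace()
    y = np.asarray(y, float)
    names = cm.columns
    if len(names) <= 1:
        return cm

    X = cm.data.to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = (np.abs(corr) > rho_max) & ~np.eye(len(names), dtype=bool)

    r_y = {n: _abs_pearson(cm.data[n].to_numpy(float), y) for n in names}

    def pref_key(i: int):
        n = names[i]
        meta = cm.meta[n]
        return (
            1 if meta.positional else 0,
            1 if meta.vintage == "aerial197x" else 0,
        ) + _tie_key(cm, n, r_y[n])

    # connected components of the threshold graph
    unvisited = set(range(len(names)))
    kept: set[str] = set()
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(adj[i]):
                if j in unvisited:
                    unvisited.discard(int(j))
                    comp.add(int(j))
                    frontier.append(int(j))
        # greedy resolution inside the component
        remaining = set(comp)
        while remaining:
            best = min(remaining, key=pref_key)
            kept.add(names[best])
            remaining.discard(best)
            for j in sorted(remaining):
                if adj[best, j]:
                    trace.pruned.append(
                        dict(dropped=names[j], kept=names[best], rho=float(corr[best, j]))
                    )
                    remaining.discard(j)

    keep = [n for n in names if n in kept]
    return cm.select(keep)


def screen_covariates(
    cm: CovariateMatrix, y, rho_max: float = RHO_MAX_DEFAULT
) -> tuple[CovariateMatrix, ScreeningTrace]:
    """Full screening cascade; the trace accounts for every input column."""
    trace = ScreeningTrace()
    out = variability_filter(cm, trace)
    out = select_buffers(out, y, trace)
    out = prune_correlated(out, y, rho_max, trace)
    trace.survivors = out.columns
    return out, trace
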