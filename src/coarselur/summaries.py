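"""Campaign descriptive statistics: stratified and pooled summaries.

Means and SDs are reported by city-season stratum, and pooled across seasons
within a city using the exact two-stratum combination identity

    n = sum n_i
    m = sum n_i m_i / n
    s^2 = [ sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2 ] / (n - 1)

so that pooling per-stratum summaries reproduces the statistics of the
concatenated data exactly.  The coefficient of variation is SD over mean.
Species columns may carry their own validity flags (an XRF run can void a
species while the mass measurement stands), so per-outcome n can differ
within a stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MASS_OUTCOME = "coarse"
SPECIES_OUTCOMES = ("copper", "phosphorus", "silicon", "zinc")


@dataclass(frozen=True)
class StratumSummary:
    city: str
    season: str  # a season label or "pooled"
    outcome: str
    n: int
    mean: float
    sd: float

    @property
    def cv(self) -> float | None:
        if self.mean == 0:
            return None
        return self.sd / self.mean


def _valid_values(samples: pd.DataFrame, outcome: str) -> pd.DataFrame:
    flag_col = f"{outcome}_valid"
    if flag_col in samples.columns:
        samples = samples[samples[flag_col].astype(bool)]
    elif outcome != MASS_OUTCOME and "species_valid" in samples.columns:
        samples = samples[samples["species_valid"].astype(bool)]
    return samples


def stratum_stats(samples: pd.DataFrame, outcome: str) -> list[StratumSummary]:
    """Per city x season sample mean and SD (n-1 denominator)."""
    samples = _valid_values(samples, outcome)
    out: list[StratumSummary] = []
    for (city, season), grp in samples.groupby(["city", "season"], sort=True):
        vals = grp[outcome].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        out.append(
            StratumSummary(
                city=str(city), season=str(season), outcome=outcome,
                n=len(vals), mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            )
        )
    return out


def pooled_stats(strata: Sequence[tuple[int, float, float]]) -> tuple[int, float, float]:
    """Combine per-stratum (n, mean, sd) into pooled (n, mean, sd).

    Exact for the concatenation of the strata; requires every n >= 2 so the
    within-stratum sums of squares are defined.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    for n_i, _, _ in strata:
        if n_i < 2:
            raise ValueError("every stratum needs n >= 2 for a pooled SD")
    n = sum(n_i for n_i, _, _ in strata)
    mean = sum(n_i * m_i for n_i, m_i, _ in strata) / n
    within = sum((n_i - 1) * s_i**2 for n_i, _, s_i in strata)
    between = sum(n_i * (m_i - mean) ** 2 for n_i, m_i, _ in strata)
    sd = math.sqrt((within + between) / (n - 1))
    return n, mean, sd


def summary_table(
    samples: pd.DataFrame,
    outcomes: Sequence[str] = (MASS_OUTCOME,) + SPECIES_OUTCOMES,
    decimals: int | None = None,
) -> pd.DataFrame:
    """City x season (plus pooled) summary for each outcome.

    ``decimals`` rounds for display (the field convention is 2); internal
    computation is unrounded.
    """
    rows: dict[tuple[str, str], dict] = {}
    for outcome in outcomes:
        per = stratum_stats(samples, outcome)
        by_city: dict[str, list[StratumSummary]] = {}
        for s in per:
            by_city.setdefault(s.city, []).append(s)
            rows.setdefault((s.city, s.season), {})[f"{outcome}_n"] = s.n
            rows[(s.city, s.season)][f"{outcome}_mean"] = s.mean
            rows[(s.city, s.season)][f"{outcome}_sd"] = s.sd
        for city, strata in by_city.items():
            if all(s.n >= 2 for s in strata):
                n, m, sd = pooled_stats([(s.n, s.mean, s.sd) for s in strata])
                rows.setdefault((city, "pooled"), {})[f"{outcome}_n"] = n
                rows[(city, "pooled")][f"{outcome}_mean"] = m
                rows[(city, "pooled")][f"{outcome}_sd"] = sd
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["city", "season"])
    table = table.sort_index()
    if decimals is not None:
        value_cols = [c for c in table.columns if not c.endswith("_n")]
        table[value_cols] = table[value_cols].round(decimals)
    return table


def write_summary_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)
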