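"""Sample-validity screening and derivation of coarse concentrations.

Coarse PM is not measured directly: paired impactors collect PM10 and PM2.5
on separate filters and the coarse fraction (PM10-2.5) is the difference.
Field campaigns with two-week integrated sampling accumulate a standard set
of defects, and a sample pair is voided when any of these hold:

* sampling duration under 9 days,
* pump air flow outside +/-20% of nominal,
* a damaged filter (carried as an input flag),
* a gross concentration outlier, more than 5 SDs from the mean of its
  city-season stratum (mean/SD computed once, before any outlier removal),
* sulfur above 0.2 ug/m3 in the coarse fraction — sulfur belongs almost
  entirely to fine PM, so coarse-fraction sulfur indicates a sampling
  artifact.

Voiding reasons are assigned with a fixed precedence (duration, flow,
damage, outlier, sulfur) so reports are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REASON_ORDER = ("missing_pair", "duration", "flow", "damage", "outlier", "sulfur")


@dataclass(frozen=True)
class QcRules:
    min_duration_days: float = 9.0
    flow_tolerance_fraction: float = 0.20
    outlier_sd: float = 5.0
    coarse_sulfur_max: float = 0.2  # ug/m3
    outlier_on: tuple[str, ...] = ("coarse",)  # mass only by default

    def __post_init__(self) -> None:
        for f_ in ("min_duration_days", "flow_tolerance_fraction", "outlier_sd",
                   "coarse_sulfur_max"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")


@dataclass
class QcReport:
    status: pd.Series = field(repr=False)  # sample_id -> "valid" | "voided:<reason>"
    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_valid: int = 0
    valid_pair_count: int = 0
    unique_location_count: int = 0

    @property
    def voided(self) -> list[str]:
        return [sid for sid, s in self.status.items() if s != "valid"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(
            n_input=self.n_input,
            n_valid=self.n_valid,
            valid_pair_count=self.valid_pair_count,
            unique_location_count=self.unique_location_count,
            counts=self.counts,
            status=self.status.to_dict(),
        )
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_coarse(pm10, pm25):
    """PM10-2.5 by subtraction: returns (coarse, negative_pair_flag).

    A negative difference is retained (not clipped) but flagged; missing
    members make the pair non-computable (NaN coarse, flag True).
    """
    pm10 = np.asarray(pm10, float)
    pm25 = np.asarray(pm25, float)
    coarse = pm10 - pm25
    flag = np.isnan(coarse) | (coarse < 0)
    return coarse, flag


def apply_qc(
    samples: pd.DataFrame, rules: QcRules = QcRules()
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the validity rules; return (valid samples, report).

    The outlier screen standardises within each (city, season) stratum using
    the mean/SD of the candidate set that survived the earlier rules
    (duration, flow, damage), computed in a single pass — statistics are not
    recomputed after removals.
    """
    samples = samples.reset_index(drop=True).copy()
    n = len(samples)
    if n == 0:
        return samples, QcReport(status=pd.Series(dtype=object))

    if "coarse" not in samples.columns:
        coarse, _ = compute_coarse(samples["pm10"], samples["pm25"])
        samples["coarse"] = coarse

    reason = np.full(n, "", dtype=object)

    missing = samples["pm10"].isna() | samples["pm25"].isna()
    reason[missing.to_numpy() & (reason == "")] = "missing_pair"

    short = samples["duration_days"].to_numpy() < rules.min_duration_days
    reason[short & (reason == "")] = "duration"

    flow = np.abs(samples["flow_deviation_fraction"].to_numpy()) > rules.flow_tolerance_fraction
    reason[flow & (reason == "")] = "flow"

    if "damaged" in samples.columns:
        dmg = samples["damaged"].fillna(False).to_numpy(bool)
        reason[dmg & (reason == "")] = "damage"

    # single-pass stratum outlier screen on the surviving candidate set
    candidate = reason == ""
    for metric in rules.outlier_on:
        vals = samples[metric].to_numpy(float)
        for _, idx in samples.groupby(["city", "season"]).indices.items():
            idx = np.asarray(idx)
            cand = idx[candidate[idx]]
            if len(cand) < 3:
                continue
            m = vals[cand].mean()
            s = vals[cand].std(ddof=1)
            if s <= 0:
                continue
            out = cand[np.abs(vals[cand] - m) > rules.outlier_sd * s]
            reason[out] = np.where(reason[out] == "", "outlier", reason[out])

    sulfur = samples["coarse_sulfur"].to_numpy(float) > rules.coarse_sulfur_max
    reason[sulfur & (reason == "")] = "sulfur"

    status = pd.Series(
        ["valid" if r == "" else f"voided:{r}" for r in reason],
        index=samples["sample_id"].to_numpy(),
        name="qc_status",
    )
    valid = samples[reason == ""].reset_index(drop=True)
    counts = {r: int((reason == r).sum()) for r in REASON_ORDER if (reason == r).any()}
    report = QcReport(
        status=status,
        counts=counts,
        n_input=n,
        n_valid=len(valid),
        valid_pair_count=len(valid),
        unique_location_count=valid["site_id"].nunique() if len(valid) else 0,
    )
    return valid, report


def duplicate_precision(a, b) -> tuple[float, int]:
    """Precision of collocated duplicate pairs.

    Returns (median relative absolute difference |a-b| / pair mean, number of
    pairs skipped for zero mean).  Requires at least one usable pair.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length, nonempty duplicate arrays")
    mean = 0.5 * (a + b)
    usable = mean != 0
    n_skipped = int((~usable).sum())
    if not usable.any():
        raise ValueError("all duplicate pairs have zero mean")
    rel = np.abs(a[usable] - b[usable]) / mean[usable]
    return float(np.median(rel)), n_skipped
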