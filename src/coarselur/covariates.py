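"""Container for site-level geographic covariates with per-column metadata.

A covariate library for land-use regression is a plain site x variable table,
but the screening rules need to know, for every column, its source category
(e.g. satellite land use, road length, imperviousness), the buffer radius it
was summarised over, whether it is purely positional (latitude/longitude,
distance to city hall), and the vintage of the underlying data source.
``CovariateMatrix`` keeps a :class:`pandas.DataFrame` alongside that metadata
and round-trips through CSV + JSON sidecar so campaigns can be archived as
text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: recognised source vintages for land-use data
VINTAGES = ("raster2000", "aerial197x", "na")


@dataclass(frozen=True)
class CovariateMeta:
    """Metadata for a single covariate column."""

    category: str
    buffer_radius_m: float | None = None
    positional: bool = False
    vintage: str = "raster2000"

    def __post_init__(self) -> None:
        if self.vintage not in VINTAGES:
            raise ValueError(f"unknown vintage {self.vintage!r}")
        if self.buffer_radius_m is not None and self.buffer_radius_m <= 0:
            raise ValueError("buffer_radius_m must be positive")


@dataclass
class CovariateMatrix:
    """Site (or site-season) rows x named covariate columns, plus metadata.

    ``data`` is indexed by site id.  Every column must have an entry in
    ``meta``; extra metadata entries are not allowed so that the screening
    trace can account for every column exactly.
    """

    data: pd.DataFrame
    meta: dict[str, CovariateMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate covariate column names")
        missing = [c for c in cols if c not in self.meta]
        extra = [c for c in self.meta if c not in cols]
        if missing or extra:
            raise ValueError(
                f"metadata mismatch: missing={missing[:5]} extra={extra[:5]}"
            )

    # -- basic protocol ----------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, names: Iterable[str]) -> "CovariateMatrix":
        names = list(names)
        return CovariateMatrix(self.data[names].copy(), {n: self.meta[n] for n in names})

    def align_to(self, samples: pd.DataFrame, on: str = "site_id") -> "CovariateMatrix":
        """Repeat site rows so they align 1:1 with a sample table."""
        aligned = self.data.loc[samples[on].to_numpy()].reset_index(drop=True)
        return CovariateMatrix(aligned, dict(self.meta))

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path, index=True, index_label="site_id")
        if meta_path is None:
            meta_path = path.with_suffix(".meta.json")
        payload = {name: asdict(m) for name, m in self.meta.items()}
        Path(meta_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(
        cls, path: str | Path, meta_path: str | Path | None = None
    ) -> "CovariateMatrix":
        path = Path(path)
        data = pd.read_csv(path, index_col="site_id")
        if meta_path is None:
            meta_path = path.with_suffix(".meta.json")
        raw: Mapping[str, dict] = json.loads(Path(meta_path).read_text())
        meta = {name: CovariateMeta(**m) for name, m in raw.items()}
        return cls(data, meta)
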