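"""Shared study configuration for the numbered analysis scripts.

Three cities of 40 homes each, two seasons, repeats at a third of homes,
the compact covariate library, and default residual structure — rerunning
any script reproduces its outputs exactly.
"""

from pathlib import Path

import pandas as pd

import coarselur as cl

SEED = 20
OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def study_campaigns():
    layouts = cl.default_layouts()
    truth = cl.default_truth(seed=SEED)
    return cl.generate_study(layouts, cl.compact_schema(), truth, repeat_fraction=1 / 3)


def load_valid_samples() -> pd.DataFrame:
    path = OUTDIR / "samples_valid.csv"
    if not path.exists():
        raise SystemExit("run 01_simulate.py and 02_qc.py first")
    return pd.read_csv(path)


def load_covariates(samples: pd.DataFrame) -> cl.CovariateMatrix:
    parts, meta = [], None
    for city in sorted(samples["city"].unique()):
        cm = cl.CovariateMatrix.from_csv(OUTDIR / f"covariates_{city}.csv")
        parts.append(cm.data)
        meta = cm.meta
    return cl.CovariateMatrix(pd.concat(parts), dict(meta)).align_to(samples)
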