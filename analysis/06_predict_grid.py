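"""Export prediction grids: dense lattice in the urban core, coarse outside.

Regenerates the study deterministically (the latent covariate surfaces are
needed to evaluate covariates at grid nodes), refits the selected city
models, and writes per-season LUR and UK predictions at 500 m urban /
2000 m rural spacing as CSV and GeoJSON points.
"""

import json

import pandas as pd

import coarselur as cl
from coarselur.pipeline import RunConfig, _predict_grids
from coarselur.selection import ModelSpec
from common import OUTDIR, SEED, load_covariates, load_valid_samples, study_campaigns

valid = load_valid_samples()
campaigns = {c.layout.city_id: c for c in study_campaigns()}
config = RunConfig(urban_spacing_m=500.0, rural_spacing_m=2000.0)

for city in sorted(valid["city"].unique()):
    sub = valid[valid["city"] == city].reset_index(drop=True)
    y = sub["coarse"].to_numpy()
    cov = load_covariates(sub)
    screened, _ = cl.screen_covariates(cov, y)
    sel = json.loads((OUTDIR / f"selection_city_{city}.json").read_text())
    spec = ModelSpec("coarse", tuple(sel["best"]["terms"]), "city")
    std = cl.Standardizer()
    cov_z = std.fit_transform(screened.data.reset_index(drop=True))
    termset = cl.TermSet(cov_z, sub, "city")
    result, _, _ = cl.select_model(screened, sub, y, scope="city", seed=SEED)
    _predict_grids(
        config, campaigns, city, "city", "coarse",
        result, termset, std, screened, sub, y, OUTDIR,
    )
    grid = pd.read_csv(OUTDIR / f"grid_city_{city}_coarse_uk.csv")
    print(f"{city}: {len(grid)} grid predictions, "
          f"range {grid['prediction'].min():.1f}-{grid['prediction'].max():.1f} ug/m3")
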