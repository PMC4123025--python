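"""Screen the covariate library and select prediction models.

For each city (and pooled across cities) runs the full reduction:
variability filter -> buffer selection -> correlation pruning -> LASSO
shortlist -> exhaustive subset search under shared 10-fold CV.  Writes the
screening traces and selection results; prints the chosen terms with their
cross-validated performance and the generator's oracle R2 for comparison.
"""

import json

import numpy as np

import coarselur as cl
from common import OUTDIR, SEED, load_covariates, load_valid_samples

valid = load_valid_samples()

for scope, groups in (
    ("city", [(c, valid[valid["city"] == c]) for c in sorted(valid["city"].unique())]),
    ("pooled", [("all", valid)]),
):
    for label, sub in groups:
        sub = sub.reset_index(drop=True)
        y = sub["coarse"].to_numpy()
        cov = load_covariates(sub)
        screened, trace = cl.screen_covariates(cov, y)
        trace.to_json(OUTDIR / f"screening_{scope}_{label}.json")
        result, termset, _ = cl.select_model(
            screened, sub, y, scope=scope, seed=SEED
        )
        result.to_json(OUTDIR / f"selection_{scope}_{label}.json")
        ledger = json.loads((OUTDIR / f"truth_ledger_{label}.json").read_text()) \
            if scope == "city" else None
        oracle = ""
        if ledger:
            lp = {o["sample_id"]: o["linear_predictor"] for o in ledger["oracle"]}
            lpv = np.array([lp[i] for i in sub["sample_id"]])
            oracle = f" (oracle R2 {1 - np.mean((y - lpv) ** 2) / y.var(ddof=1):.2f})"
        print(f"{scope}/{label}: {len(cov.columns)} -> {len(screened.columns)} "
              f"screened; best {list(result.best.terms)}")
        print(f"   CV RMSE {result.cv_rmse:.2f} ug/m3, CV R2 {result.cv_r2:.2f}{oracle}")
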