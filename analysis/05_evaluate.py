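"""Cross-validate the selected models as LUR and as UK.

For every selected model, compares land-use regression against universal
kriging under the same 10-fold split (variogram refitted within each
training fold); pooled models additionally report per-city R2 around each
city's own mean, truncated at zero.  Writes the long-format performance
table.
"""

import json

import coarselur as cl
from coarselur.selection import ModelSpec
from common import OUTDIR, SEED, load_covariates, load_valid_samples

valid = load_valid_samples()
reports = []
for scope, groups in (
    ("city", [(c, valid[valid["city"] == c]) for c in sorted(valid["city"].unique())]),
    ("pooled", [("all", valid)]),
):
    for label, sub in groups:
        sub = sub.reset_index(drop=True)
        y = sub["coarse"].to_numpy()
        cov = load_covariates(sub)
        screened, _ = cl.screen_covariates(cov, y)
        sel = json.loads((OUTDIR / f"selection_{scope}_{label}.json").read_text())
        spec = ModelSpec("coarse", tuple(sel["best"]["terms"]), scope)
        std = cl.Standardizer()
        cov_z = std.fit_transform(screened.data.reset_index(drop=True))
        termset = cl.TermSet(cov_z, sub, scope)
        for mode in ("lur", "uk"):
            rep = cl.cross_validate(spec, termset, y, sub, seed=SEED, mode=mode)
            rep.to_json(OUTDIR / f"eval_{scope}_{label}_{mode}.json")
            reports.append(rep)
        lur, uk = reports[-2], reports[-1]
        print(f"{scope}/{label}: LUR CV R2 {lur.cv_r2:.2f} (RMSE {lur.cv_rmse:.2f}) | "
              f"UK CV R2 {uk.cv_r2:.2f} (RMSE {uk.cv_rmse:.2f})")
        if scope == "pooled":
            for city, entry in uk.per_city.items():
                print(f"   within-{city} UK R2: {entry['r2']:.2f}")

cl.evaluation.report_table(reports).to_csv(OUTDIR / "table_performance.csv", index=False)
print(f"\nperformance table -> {OUTDIR / 'table_performance.csv'}")
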