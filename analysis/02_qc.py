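"""Apply the sample-validity rules and derive coarse concentrations.

Voids samples with short durations (< 9 days), out-of-range flows (beyond
+/-20%), damaged filters, > 5 SD stratum outliers, or coarse-fraction sulfur
above 0.2 ug/m3, and writes the QC report plus the valid sample table.
"""

import pandas as pd

import coarselur as cl
from common import OUTDIR

samples = pd.read_csv(OUTDIR / "samples.csv")
valid, report = cl.apply_qc(samples)
report.to_json(OUTDIR / "qc_report.json")
cl.synthetic.write_samples_csv(valid, OUTDIR / "samples_valid.csv")

pct = 100.0 * report.n_valid / report.n_input
print(f"{report.n_valid} of {report.n_input} sample pairs valid ({pct:.0f}%) "
      f"at {report.unique_location_count} unique locations")
print("voiding reasons:", report.counts)
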