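"""How much scan do you need?  Window-vs-full-scan consistency of the
average-degree metric across a simulated cohort.

Uses the fast neural-level simulation (same statistics as full scans, no
wavelength mapping) to look at all 11 cumulative windows.
"""

import numpy as np

from nirsgraph.sims import consistency_curves
from nirsgraph.synth import CohortSpec

spec = CohortSpec(n_subjects=60, seed=0)
df = consistency_curves(spec, n_cohorts=5, seed=17)
mean = df.groupby("window_end_min")["r_vs_full"].mean()

print("window  partial r vs 30-min AD (controlling age, sex)")
for w, r in mean.items():
    bar = "#" * int(round(40 * max(r, 0)))
    print(f"{w:5.0f}    {r:+.3f}  {bar}")
# Interpretation: consistency rises steeply over the first minutes and is
# exactly 1 at the full window by construction; past ~5 minutes the metric
# is already a stable read-out of the full 30-minute value.
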