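"""Preprocess one synthetic scan: NaN repair, motion correction, band-pass,
and conversion to hemoglobin concentration changes.

Prints the per-stage quality summary and shows that the recovered HbO tracks
the generator's clean neural signal.
"""

import numpy as np

from nirsgraph import CohortSpec, generate_cohort, preprocess_scan
from nirsgraph.preprocess import bandpass_array

spec = CohortSpec(n_subjects=4, duration=600.0, seed=2,
                  artifact_rate=1.0, saturation_rate=1.0)
scans, _, truth = generate_cohort(spec, keep_clean_hbo=True)
scan = scans[0]

print(f"raw scan: {np.isnan(scan.intensity).sum()} saturated samples (NaN)")
hb, report = preprocess_scan(scan)
print(f"quality: max CV {np.nanmax(report.cv):.1f}% "
      f"(threshold 15%), {len(report.excluded_channels)} channel(s) excluded")
print(f"motion mask covers {100 * report.motion_fraction:.1f}% of samples")
print(f"HbO output: {hb.hbo.shape[0]} channels x {hb.hbo.shape[1]} samples, "
      f"micromolar; max |HbT - (HbO + HbR)| = "
      f"{np.abs(hb.hbt - hb.hbo - hb.hbr).max():.2e}")

clean = bandpass_array(truth.clean_hbo[0], scan.sampling_rate)
cors = [np.corrcoef(clean[k], hb.hbo[k])[0, 1] for k in range(18)]
print(f"per-channel corr with the planted neural HbO: "
      f"min {min(cors):.3f}, median {np.median(cors):.3f}")
# Interpretation: this scan is deliberately heavily corrupted (one motion
# event per minute plus a saturation dropout), and corrected segments trade
# local signal for artifact removal, so recovery is moderate here; on
# artifact-free scans the per-channel recovery correlation exceeds 0.95
# (that bound is asserted in the test suite).
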