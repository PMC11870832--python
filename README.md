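# nirsgraph

Graph-theoretical analysis of resting-state fNIRS connectivity over the
dorsolateral prefrontal cortex (DLPFC), and its association with fluid
intelligence, as a tested, reproducible Python library.

## The scientific problem

Functional near-infrared spectroscopy (fNIRS) measures cortical hemodynamics
through dual-wavelength light attenuation at the scalp. Resting-state
functional connectivity (FC) of prefrontal cortex carries information about
fluid intelligence (gF), conventionally measured with Raven's Advanced
Progressive Matrices (RAPM, set II, score 0–36). Two practical questions
drive this package:

1. **Do DLPFC network metrics track gF?** For each subject, the Pearson
   correlation matrix of the 18 DLPFC channels' oxyhemoglobin (HbO) signals
   is Fisher-transformed, `z = atanh(r)`, and summarized by

   - **average degree** `AD = (1/N) Σᵢ cᵢ` with `cᵢ` the mean connectivity of
     node *i* — algebraically the mean off-diagonal `z`, a network-density
     measure; and
   - **global efficiency** `E(G) = 1/(N(N−1)) Σ_{i≠j} 1/d_ij` of the graph
     binarized at thresholds τ ∈ {0.1, …, 0.5}, with `d_ij` the unweighted
     shortest-path length and `1/d_ij = 0` for unreachable pairs.

   Associations with the behavior score are partial correlations controlling
   for age and sex, with two-sided p-values from
   `t = r·√((n−k−2)/(1−r²))` on `n−k−2` degrees of freedom.

2. **How much scan is enough?** All metrics are recomputed over 11 cumulative
   windows [0, k] minutes, k ∈ {1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30}, and
   each window's metric is correlated (again partially, controlling age and
   sex) with the full 30-minute value across subjects.

Because cohort-scale resting-state recordings are rarely shareable, the
package includes a first-class **synthetic-cohort generator**: band-limited
"neural" HbO drawn from a planted per-subject 18×18 correlation structure,
physiological oscillations (cardiac ≈1.1 Hz, respiratory ≈0.3 Hz, Mayer
≈0.1 Hz), drift, noise, motion spikes/steps, saturation dropouts, and a
behavior score coupled to the planted connectivity density at a configurable
correlation. Every downstream claim is tested against this known ground
truth.

Preprocessing follows standard fNIRS practice: saturation-NaN spline repair →
optical density → motion-artifact detection (sliding-window peak-to-peak
criterion; thresholds tMotion = 0.5 s, tMask = 5 s, STDEVthresh = 15,
AMPthresh = 0.5) and hybrid spline + wavelet correction → 0.01–0.08 Hz
zero-phase band-pass → modified Beer–Lambert law conversion to HbO/HbR/HbT —
plus a raw-intensity quality screen excluding channels with coefficient of
variation above 15%.

## Worked example

```python
import numpy as np
from nirsgraph import (CohortSpec, generate_cohort, preprocess_scan,
                       compute_fc, WindowSpec, average_degree,
                       binarize, global_efficiency)

spec = CohortSpec(n_subjects=4, duration=600.0, seed=3)
scans, records, truth = generate_cohort(spec)
hb, report = preprocess_scan(scans[0])

fc = compute_fc(hb, WindowSpec(end=10.0))
print(round(average_degree(fc), 3))
for tau in (0.1, 0.3, 0.5):
    print(tau, round(global_efficiency(binarize(fc, tau)), 3))
```

prints (seed 3):

```
0.918
0.1 1.0
0.3 0.99
0.5 0.915
```

`AD = 0.918` is the mean off-diagonal Fisher z (this subject's mean pairwise
r is 0.68: a densely coupled resting DLPFC — and indeed the generator
planted a density of 0.684 for it). At τ = 0.1 every channel pair correlates
above threshold, so the binarized graph is complete and efficiency is
exactly 1; as the threshold rises, weaker pairs drop out and the mean
inverse shortest-path length falls to 0.99 and then 0.915.

The `examples/` directory holds one short script per capability (cohort
synthesis, preprocessing, connectivity/graph metrics, scan-length stability,
brain-behavior association); each prints the numbers it computes with a line
of interpretation. A thin CLI mirrors the stages
(`nirsgraph synth | preprocess | fc | graph | stability | associate |
report | run`); `nirsgraph run --config cfg.yaml` executes the whole chain
and writes CSV artifacts plus a checksum manifest.

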