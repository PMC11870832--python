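# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `nirsgraph`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A recording is dual-wavelength (760/850 nm) continuous-wave intensity over
an 18-channel bilateral DLPFC montage (8 sources, 8 detectors, 9 channels
per hemisphere). The device sampling rate is carried per file rather than
assumed; the synthetic generator defaults to 10 Hz. Saturated samples are
explicit NaNs, never sentinel values. On disk, scans use a minimal SNIRF
dialect (HDF5: `formatVersion`, `nirs/data1/dataTimeSeries`, `time`, one
`measurementList<k>` per column, `probe/wavelengths`) with a plain-CSV
fallback for small text fixtures; behavior tables are CSV with columns
`subject_id, age, sex, rapm` (RAPM set II: integer 0–36; age ≥ 18).
Auxiliary SNIRF channels, stimulus blocks and vendor raw formats are out of
scope.

## Preprocessing

Stage order (default): NaN repair → intensity→OD → motion detection and
correction on OD → 0.01–0.08 Hz band-pass on OD → modified Beer–Lambert law
(MBLL). Because the band-pass and the MBLL solve are both linear, filtering
before or after the conversion yields the same HbO up to the filter's
boundary-condition numerics (~1e-4 relative; asserted by a test). The
alternative order (convert, then filter concentrations) is available via
`filter_stage="hb"`.

* **NaN repair** — cubic-spline interpolation (not-a-knot, hence exact on
  cubic segments) across each gap, nearest-value extension at the edges.
  Channels with fewer than 4 valid samples are reported unrepairable and
  excluded rather than invented.
* **Motion detection** — per channel-wavelength on OD: a sample is flagged
  when the peak-to-peak excursion within a sliding window of `tMotion`
  = 0.5 s exceeds `STDEVthresh` = 15 × SD of the first differences, or
  `AMPthresh` = 0.5 absolutely; flags are dilated ±`tMask` = 5 s and OR-ed
  across wavelengths (an artifact is an optode-level event). A constant
  series has zero difference-SD; only the amplitude criterion applies then.
* **Motion correction** — two stages. (1) Within each masked segment the
  artifact is modelled by a smoothing spline (smoothing set from the clean
  signal's difference variance) and subtracted; the segment is re-anchored
  to the preceding baseline. If the segment exit level differs from its
  entry level by more than 5 × the natural level-change scale (MAD of
  adjacent 2-s block-mean differences), the artifact left a persistent step
  and the remainder of the series is re-levelled; transient spikes leave no
  step, and skipping the shift for them prevents estimation noise from
  accumulating into a baseline random walk over many corrections.
  (2) A whole-series `db5` wavelet decomposition (4 levels); detail
  coefficients outside 1.5 interquartile ranges are zeroed. Coefficients
  within one filter length of the boundary are exempt — they encode the
  symmetric signal extension, not motion — so smooth artifact-free series
  reconstruct unchanged (≤1e-10). A channel masked over >50% of the scan is
  reported low-quality.
* **Band-pass** — zero-phase forward-backward Butterworth, order 3,
  0.01–0.08 Hz, removing drift and the cardiac/respiratory/Mayer bands.
  With a 0.01 Hz corner the impulse response spans tens of seconds and
  standard edge padding leaks broadband edge transients an order of
  magnitude above the stopband floor; the implementation therefore uses
  Gustafsson's initial-condition matching (`irlen` capped at ~10 time
  constants). Measured response: ≤1% RMS at 1.1 Hz, ≤1% at 0.3 Hz (well
  beyond the 20 dB requirement), ≥99% at 0.04 Hz, ≥92% across 0.02–0.06 Hz.
* **MBLL** — `ΔOD_λ = d · DPF_λ · Σ_c ε_{c,λ} ΔC_c`, solved per sample as a
  2×2 system. Extinction coefficients for HbO/HbR at 760/850 nm are a
  fixed, versioned table in µM⁻¹cm⁻¹ (Prahl compilation) rather than a
  silent library default. DPF defaults to 6.0 at both wavelengths and
  source-detector separation to 3.0 cm — standard adult-forehead values;
  both scale concentrations linearly and cancel in correlation-based FC
  (asserted by tests).
* **Quality screen** — CV = 100·SD/mean of raw intensity per
  channel-wavelength; a channel is excluded if any wavelength exceeds 15%,
  and a subject with any excluded channel is flagged for cohort-level
  exclusion. Zero-mean or entirely-missing channels are excluded with a
  reason.

## Connectivity and graph metrics

FC is the Pearson correlation of HbO channels over cumulative windows
[0, k] minutes, k ∈ {1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30} (the final
window read as 0-to-30; sliding windows are out of scope), Fisher
transformed off-diagonal. Diagonals are excluded from every downstream
statistic, not zeroed-as-data. Off-diagonal |r| ≥ 1 (degenerate duplicated
channels) is clipped to 1−1e−7 with a warning.

* **AD** is computed on the Fisher-z matrix by default (`ad_on="r"`
  available); it equals the off-diagonal mean, and a naive double-loop
  oracle asserts that identity.
* **Binarization** applies `value ≥ τ` to the r matrix by default
  (`threshold_on="z"` available, recorded in outputs); values below τ —
  including all negative correlations — yield no edge; no absolute-value
  option by default.
* **Eglob** uses breadth-first shortest paths (scipy csgraph) with
  unreachable pairs contributing zero — the Brain Connectivity Toolbox
  `efficiency_bin` convention, making disconnected graphs well-defined
  (empty graph → 0, complete graph → 1). Equivalence with a hand-written
  Floyd–Warshall oracle to 1e−12 and with networkx is asserted over random
  graphs across the full density range. Efficiency is non-increasing in τ
  by edge-set nesting (property-tested).

Whether a study of this design thresholds r or z, and computes AD on r or
z, is genuinely underdetermined; both switches are exposed, logged in the
outputs, and default as above.

## Association statistics

Partial correlation is implemented by the residual method — least-squares
projection of both variables on `[1, covariates]`, Pearson correlation of
residuals — with two-sided p from `t = r√((n−k−2)/(1−r²))` on `n−k−2`
degrees of freedom. Tests assert exact agreement with the
inverse-correlation-matrix formulation, with an independent library
implementation, and with a hand-computed 6-point case. Sex is coded
female = 0 / male = 1; partial correlation is invariant to affine recoding
(asserted). The full design yields 11 AD cells and 55 Eglob cells (11
windows × 5 thresholds); all 66 raw p-values are reported with no
multiple-testing correction so users can apply their own procedure. A
metric that is constant across subjects (e.g., every graph complete at a
low threshold in a small, dense cohort) has no defined correlation; its
cell is reported as NaN rather than raising. Window-vs-30-min consistency
uses the same partial-correlation implementation; the full window
correlates exactly 1 with itself and is asserted as a pipeline sanity
check. Subjects missing a window are dropped listwise for that window with
per-window n reported.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 116
subjects, 30-minute scans, RAPM mean 25.24 / SD 4.00 (drawn Gaussian,
rounded, clipped to 0–36), age ≈ 20 ± 2, female:male ≈ 88:64, and a planted
density-behavior correlation of −0.33.

* **Planted connectivity** — per subject, a latent density u ~ N(0.70,
  0.10) (clipped to (0.05, 0.95)); the mean echoes a densely coupled
  resting DLPFC, while the per-subject dispersion is a free generator
  parameter (no empirical dispersion is available to emulate).
  The 18×18 correlation matrix is a single-factor (channel-loading) model:
  squared loadings `g_i ~ N(u, 0.25)` clipped to (0, 1), pairwise
  correlation `C_ij = √(g_i g_j)` — positive semi-definite by construction
  (rank one plus diagonal), unit diagonal, mean off-diagonal ≈ u, and a
  wide pair-level spread so the binarization thresholds 0.1–0.5 all fall
  inside the pair distribution, as they do for empirical FC matrices. The
  ground-truth density is the realized mean off-diagonal of C, and the
  behavior score is coupled to that realized density through a Gaussian
  copula, so parameter-recovery tests have an exact target aligned with
  what AD estimates.
* **Signals** — "neural" HbO: white noise band-passed to 0.01–0.08 Hz with
  the same filter the pipeline uses, spatially mixed by the Cholesky factor
  of C, scaled to 1 µM RMS. Physiology: cardiac 1.1 Hz at 3× neural RMS,
  respiratory 0.3 Hz at 1.5×, Mayer 0.1 Hz at 1×, each with per-channel
  phase/amplitude jitter — inside the bands the filter must remove, so
  filter tests are meaningful. Linear drift (±1 µM per scan), white HbO
  noise (0.3 µM), HbR = −0.4·HbO + 0.1 µM noise. The pair is mapped to
  intensity by the *forward* MBLL with the same extinction table the
  pipeline inverts (round-trip exact to float tolerance), detector noise
  0.005 OD, per-channel baseline gain ~U(0.8, 1.2).
* **Artifacts** — motion events as a Poisson process (default 0.5/min,
  70% spikes <1 s with decaying shape, 30% persistent baseline steps),
  amplitudes scaled to the channel's log-intensity SD, hitting all channels
  (head motion is optode-level); the exact injected-sample mask is returned
  for detector-sensitivity tests. Saturation: Poisson count per scan
  (default 0.3) of ~1 s single-channel NaN dropouts. Optionally, subjects
  with a slowly wandering detector gain (±0.4 log-intensity over the scan)
  for testing the CV screen.
* **Determinism** — all randomness flows from one integer seed through
  named `SeedSequence` sub-streams per subject; a fixed seed fixes every
  output bit.

What the generator does *not* emulate: biophysical hemodynamic forward
models (balloon / photon-transport), scalp and short-channel physiology,
channel-specific optode coupling drift, non-stationarity of the neural
covariance, or negative planted pair correlations (the factor model is
non-negative; empirical FC matrices occasionally have small negative
pairs). Passing tests therefore demonstrate correctness of the analysis
chain under a stationary, Gaussian, factor-structured world — not
robustness to everything real scalp data can do.

## Monte-Carlo studies at reduced fidelity

Calibration (type-I error of the association test under planted ρ = 0),
power/recovery (planted ρ = −0.33 at n = 116), and the window-consistency
trend require hundreds of simulated cohorts. These studies run on the
generator's ground-truth layer plus band-limited neural HbO simulated at
1 Hz — above twice the 0.08 Hz band edge — rather than full dual-wavelength
10 Hz scans. For band-limited signals, correlation-estimate statistics are
governed by duration × bandwidth, not by the sampling rate above Nyquist,
so the sampling behavior of AD and Eglob matches the full pipeline's; the
full-fidelity path is exercised by the pipeline-level tests and the
acceptance script's 116-subject replica. Problem sizes used: 500 cohorts
for calibration, 200 (tests) / 100 (acceptance script) for recovery, 20
cohorts of 60 subjects for the consistency trend.

## Numerical choices and edge cases

* Off-diagonal |r| ≥ 1 → clipped to 1−1e−7 before atanh, with a warning.
* |partial r| = 1 after residualization → p reported as 0 (t degenerate).
* Empty binarized graph → efficiency 0; complete → exactly 1.
* Zero-variance channel inside a window → explicit error naming the channel
  (impossible after preprocessing, which always leaves filtered noise).
* Windows shorter than 30 samples are refused.
* Thresholds and windows outside the canonical sets are config errors.
* The pipeline is single-process and deterministic; per-subject
  independence makes parallelism safe in principle but it is not
  implemented.

## Known limitations

* No short-channel regression or systemic-physiology removal (PCA/tCCA):
  superficial contamination is only attenuated by the band-pass.
* HbR/HbT are computed and carried but not statistically analyzed; the
  association analysis is HbO-only.
* The CV screen runs on raw intensity including injected artifacts, so
  extreme motion can push a clean-optics subject over the 15% line —
  mirroring how such screens behave in practice.
* p-values are reported raw (no multiplicity correction), by design.
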