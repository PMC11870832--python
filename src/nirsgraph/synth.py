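"""Synthetic resting-state fNIRS cohorts with known ground truth.

Each subject gets a latent connectivity *density* u (mean off-diagonal
correlation of the planted 18-channel covariance); a band-limited (< 0.08 Hz)
"neural" HbO component is drawn from that covariance, physiological
oscillations (cardiac ~1.1 Hz, respiratory ~0.3 Hz, Mayer ~0.1 Hz), linear
drift and white noise are added, HbR is set to a scaled anticorrelated copy,
and the pair is mapped to dual-wavelength intensity by the *forward* modified
Beer-Lambert law — the exact inverse of the preprocessing conversion, so the
two form a round-trippable pair.  Motion spikes, baseline shifts and
saturation-NaN segments are injected at configurable rates.  Behavior scores
are drawn so that corr(density, score) matches a target across the cohort
(Gaussian copula, then rounded and clipped to the 0-36 scale).

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams: fixed seed, bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import bandpass_array, hb_forward_od
from .probe import DLPFC_MONTAGE, N_CHANNELS, RawScan, SubjectRecord

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "inject_motion"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Defaults mirror the emulated study: 116 subjects, 30-minute scans, RAPM
    scores with mean 25.24 and SD 4.00, and a planted density-behavior
    correlation of -0.33.  ``density_mean`` echoes the high resting DLPFC
    coupling reported for full-length scans; ``density_sd`` (per-subject
    dispersion) is a free parameter of the generator.
    """

    n_subjects: int = 116
    duration: float = 1800.0          # seconds
    sampling_rate: float = 10.0       # Hz
    target_brain_behavior_rho: float = -0.33
    behavior_mean: float = 25.24
    behavior_sd: float = 4.00
    density_mean: float = 0.70
    density_sd: float = 0.10
    artifact_rate: float = 0.5        # motion events per minute
    saturation_rate: float = 0.3      # NaN segments per scan
    saturation_mean_s: float = 1.0    # mean NaN segment length, seconds
    neural_amp_um: float = 1.0        # RMS of the neural HbO component, uM
    cardiac_hz: float = 1.1
    cardiac_amp: float = 3.0          # x neural RMS
    respiration_hz: float = 0.3
    respiration_amp: float = 1.5
    mayer_hz: float = 0.1
    mayer_amp: float = 1.0
    drift_amp_um: float = 1.0         # linear drift over the scan
    noise_amp_um: float = 0.3         # white noise on HbO
    od_noise: float = 0.005           # detector noise on optical density
    hbr_scale: float = -0.4           # HbR = hbr_scale * HbO + noise
    heterogeneity: float = 0.25       # channel-loading spread (pair dispersion)
    n_unstable_gain: int = 0          # subjects with drifting detector gain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not abs(self.target_brain_behavior_rho) < 1:
            raise ValueError("|target_brain_behavior_rho| must be < 1")
        if self.target_brain_behavior_rho != 0 and self.behavior_sd == 0:
            raise ValueError("nonzero rho unattainable with behavior_sd = 0")
        for name in ("artifact_rate", "saturation_rate", "behavior_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration * self.sampling_rate < 60:
            raise ValueError("scan too short")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    density: np.ndarray                 # (n,) mean off-diagonal correlation
    covariance: list[np.ndarray]        # n matrices, 18x18, PSD, unit diagonal
    score: np.ndarray                   # (n,) behavior scores as emitted
    clean_hbo: list[np.ndarray] = field(default_factory=list)  # optional
    motion_masks: list[np.ndarray] = field(default_factory=list)
    unstable_gain_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ground-truth layer (shared with the fast simulation studies)
# ---------------------------------------------------------------------------

def draw_densities(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    u = rng.normal(spec.density_mean, spec.density_sd, spec.n_subjects)
    return np.clip(u, 0.05, 0.95)


def build_covariance(u: float, rng: np.random.Generator,
                     heterogeneity: float = 0.25,
                     n: int = N_CHANNELS) -> np.ndarray:
    """Unit-diagonal PSD correlation matrix with off-diagonal level ~ u.

    Single-factor (channel-loading) model: channel i couples to a common
    component with squared loading ``g_i ~ Normal(u, heterogeneity)`` (clipped
    to (0, 1)), giving pairwise correlations ``C_ij = sqrt(g_i g_j)``.  PSD by
    construction (rank-one plus diagonal), mean off-diagonal approximately u,
    and — like empirical FC matrices — a wide pair-level spread, so the
    binarization thresholds 0.1–0.5 all fall inside the pair distribution
    instead of below it.
    """
    g = np.clip(rng.normal(u, heterogeneity, n), 0.02, 0.98)
    v = np.sqrt(g)
    c = np.outer(v, v) + np.diag(1.0 - g)
    return c


def planted_density(c: np.ndarray) -> float:
    """The generator's density functional: mean off-diagonal of the planted
    correlation matrix."""
    iu = np.triu_indices(c.shape[0], k=1)
    return float(c[iu].mean())


def draw_scores(
    u: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Behavior scores with corr(density, score) ~ target (Gaussian copula)."""
    rho = spec.target_brain_behavior_rho
    zu = (u - u.mean()) / (u.std() if u.std() > 0 else 1.0)
    eps = rng.standard_normal(u.size)
    latent = rho * zu + np.sqrt(1.0 - rho**2) * eps
    raw = spec.behavior_mean + spec.behavior_sd * latent
    return np.clip(np.round(raw), 0, 36).astype(int)


def simulate_neural_hbo(
    cov: np.ndarray,
    n_samples: int,
    sampling_rate: float,
    rng: np.random.Generator,
    amp_um: float = 1.0,
    band: tuple[float, float] = (0.01, 0.08),
) -> np.ndarray:
    """Band-limited correlated 'neural' HbO, channels x samples, ~amp_um RMS.

    White noise is band-passed with the same Butterworth filter the pipeline
    uses, then spatially mixed by the Cholesky factor of the planted
    covariance — the same filter per channel preserves the correlations.
    """
    white = rng.standard_normal((cov.shape[0], n_samples))
    filt = bandpass_array(white, sampling_rate, *band)
    filt /= filt.std()
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))
    return amp_um * (chol @ filt)


# ---------------------------------------------------------------------------
# full-fidelity scans
# ---------------------------------------------------------------------------

def _physiology(
    spec: CohortSpec, t: np.ndarray, rng: np.random.Generator, n_ch: int
) -> np.ndarray:
    """Cardiac + respiratory + Mayer sinusoids with per-channel phase/amp jitter."""
    out = np.zeros((n_ch, t.size))
    comps = (
        (rng.normal(spec.cardiac_hz, 0.05), spec.cardiac_amp),
        (rng.normal(spec.respiration_hz, 0.02), spec.respiration_amp),
        (rng.normal(spec.mayer_hz, 0.005), spec.mayer_amp),
    )
    for freq, amp in comps:
        phase = rng.uniform(0, 2 * np.pi, n_ch)[:, None]
        gain = rng.uniform(0.8, 1.2, n_ch)[:, None]
        out += amp * spec.neural_amp_um * gain * np.sin(
            2 * np.pi * freq * t[None, :] + phase
        )
    return out


def inject_motion(
    scan: RawScan,
    rate: float,
    seed: int | np.random.Generator,
    spike_amp_sd: float = 15.0,
    shift_amp_sd: float = 2.0,
    p_spike: float = 0.7,
) -> tuple[RawScan, np.ndarray]:
    """Add motion spikes and baseline shifts to a scan's log-intensity.

    Events arrive as a Poisson process at ``rate`` per minute and hit every
    channel (head motion is an optode-level event); spikes last < 1 s with
    amplitude ``spike_amp_sd`` x the channel's log-intensity SD, shifts step
    the baseline by ``shift_amp_sd`` x SD for the rest of the scan.  Returns
    the corrupted scan and the exact boolean mask (channels x samples) of
    injected event samples, for detector-sensitivity tests.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = scan.copy()
    c, w, t = out.intensity.shape
    mask = np.zeros((c, t), dtype=bool)
    n_events = rng.poisson(rate * scan.duration / 60.0)
    if n_events == 0:
        return out, mask
    fs = scan.sampling_rate
    log_i = np.log(np.where(np.isfinite(out.intensity) & (out.intensity > 0),
                            out.intensity, np.nan))
    sd = np.nanstd(log_i, axis=2)  # (c, w)
    times = np.sort(rng.integers(0, t, n_events))
    for t0 in times:
        is_spike = rng.random() < p_spike
        sign = rng.choice([-1.0, 1.0])
        if is_spike:
            dur = max(1, int(round(rng.uniform(0.1, 0.9) * fs)))
            t1 = min(t, t0 + dur)
            shape = np.exp(-np.linspace(0, 3, t1 - t0))  # decaying transient
            for k in range(c):
                for j in range(w):
                    log_i[k, j, t0:t1] += sign * spike_amp_sd * sd[k, j] * shape
            mask[:, t0:t1] = True
        else:
            for k in range(c):
                for j in range(w):
                    log_i[k, j, t0:] += sign * shift_amp_sd * sd[k, j]
            t1 = min(t, t0 + max(1, int(round(0.5 * fs))))
            mask[:, t0:t1] = True  # the transition is the artifact
    nan_keep = ~np.isfinite(out.intensity)
    out.intensity = np.exp(log_i)
    out.intensity[nan_keep] = np.nan
    return out, mask


def _inject_saturation(
    intensity: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> int:
    """NaN-out random single-channel segments; returns the segment count."""
    c, w, t = intensity.shape
    n_seg = rng.poisson(spec.saturation_rate)
    fs = spec.sampling_rate
    for _ in range(n_seg):
        k = rng.integers(0, c)
        dur = max(2, int(round(rng.exponential(spec.saturation_mean_s) * fs)))
        t0 = rng.integers(0, max(1, t - dur))
        intensity[k, :, t0:t0 + dur] = np.nan
    return int(n_seg)


def generate_cohort(
    spec: CohortSpec, keep_clean_hbo: bool = False
) -> tuple[list[RawScan], list[SubjectRecord], GroundTruth]:
    """Generate scans, behavior records and ground truth for one cohort."""
    root = np.random.SeedSequence(spec.seed)
    ss_cohort, ss_subjects = root.spawn(2)
    rng = np.random.default_rng(ss_cohort)
    u = draw_densities(spec, rng)
    ages = np.clip(rng.normal(20.05, 2.01, spec.n_subjects), 18.0, None)
    sexes = rng.choice(["female", "male"], spec.n_subjects, p=[88 / 152, 64 / 152])
    unstable = set(
        rng.choice(spec.n_subjects, size=spec.n_unstable_gain, replace=False)
        if spec.n_unstable_gain else []
    )

    # build the planted covariances first: behavior is coupled to the
    # *realized* density (the quantity average degree estimates)
    srngs = [np.random.default_rng(ss) for ss in ss_subjects.spawn(spec.n_subjects)]
    covs = [build_covariance(u[i], srngs[i], spec.heterogeneity)
            for i in range(spec.n_subjects)]
    density = np.array([planted_density(c) for c in covs])
    scores = draw_scores(density, spec, rng)

    t_axis = np.arange(int(round(spec.duration * spec.sampling_rate))) / spec.sampling_rate
    scans, records = [], []
    truth = GroundTruth(
        density=density,
        covariance=covs,
        score=scores.astype(float),
    )
    for i in range(spec.n_subjects):
        srng = srngs[i]
        sid = f"sub-{i + 1:03d}"
        cov = covs[i]

        hbo = simulate_neural_hbo(
            cov, t_axis.size, spec.sampling_rate, srng, spec.neural_amp_um
        )
        if keep_clean_hbo:
            truth.clean_hbo.append(hbo.copy())
        hbo = hbo + _physiology(spec, t_axis, srng, N_CHANNELS)
        drift = srng.uniform(-1, 1, N_CHANNELS)[:, None] * spec.drift_amp_um
        hbo = hbo + drift * (t_axis[None, :] / spec.duration)
        hbo = hbo + spec.noise_amp_um * srng.standard_normal(hbo.shape)
        hbr = spec.hbr_scale * hbo + 0.1 * srng.standard_normal(hbo.shape)

        od = hb_forward_od(hbo, hbr)
        od += spec.od_noise * srng.standard_normal(od.shape)
        i0 = srng.uniform(0.8, 1.2, (N_CHANNELS, 2))[:, :, None]
        if i in unstable:
            # slow multiplicative detector-gain wander: one full swing per
            # scan, +-0.4 in log-intensity -> CV well above the 15% screen
            phase = srng.uniform(0, 2 * np.pi)
            gain = 0.4 * np.sin(2 * np.pi * t_axis / spec.duration + phase)
            od = od - gain[None, None, :]
            truth.unstable_gain_ids.append(sid)
        intensity = i0 * np.exp(-od)

        scan = RawScan(subject_id=sid, intensity=intensity,
                       sampling_rate=spec.sampling_rate, probe=DLPFC_MONTAGE)
        scan, mmask = inject_motion(scan, spec.artifact_rate, srng)
        truth.motion_masks.append(mmask)
        _inject_saturation(scan.intensity, spec, srng)

        scans.append(scan)
        records.append(
            SubjectRecord(subject_id=sid, age=float(ages[i]), sex=str(sexes[i]),
                          rapm=int(scores[i]))
        )
    return scans, records, truth
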