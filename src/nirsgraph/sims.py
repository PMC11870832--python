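"""Monte-Carlo studies of the analysis: calibration, recovery, stability.

These studies need hundreds of cohorts, so they run on the generator's
ground-truth layer plus band-limited neural HbO simulated at a reduced
sampling rate (default 1 Hz, comfortably above twice the 0.08 Hz band edge)
rather than full dual-wavelength scans.  Correlation estimates of
band-limited signals are governed by duration x bandwidth, not by the
sampling rate above Nyquist, so the sampling statistics of AD and Eglob match
the full pipeline's study conditions; the full-fidelity path is exercised by
the pipeline-level tests instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, WindowSpec, fisher_z
from .graphs import average_degree, binarize, global_efficiency
from .stats import partial_correlation
from .synth import (
    CohortSpec,
    build_covariance,
    draw_densities,
    draw_scores,
    planted_density,
    simulate_neural_hbo,
)

__all__ = [
    "simulate_cohort_metrics",
    "recovery_study",
    "null_calibration",
    "consistency_curves",
]


def _fc_from_hbo(hbo: np.ndarray, n: int, subject_id: str,
                 end_min: float) -> FCMatrix:
    r = np.corrcoef(hbo[:, :n])
    np.fill_diagonal(r, 1.0)
    fc = FCMatrix(r=r, z=np.zeros_like(r), window=WindowSpec(end=end_min),
                  subject_id=subject_id)
    return fisher_z(fc)


def simulate_cohort_metrics(
    spec: CohortSpec,
    rng: np.random.Generator,
    windows_min: tuple[float, ...] = (30.0,),
    eglob_threshold: float | None = None,
    fs_sim: float = 1.0,
) -> pd.DataFrame:
    """One cohort at neural-HbO fidelity; AD (and optionally Eglob) per window.

    Returns a DataFrame with one row per subject: planted density, behavior
    score, age, sex code, and ``ad_<w>`` / ``eglob_<w>`` columns per window.
    """
    u = draw_densities(spec, rng)
    ages = np.clip(rng.normal(20.05, 2.01, spec.n_subjects), 18.0, None)
    sex = rng.integers(0, 2, spec.n_subjects).astype(float)
    covs = [build_covariance(u[i], rng, spec.heterogeneity)
            for i in range(spec.n_subjects)]
    density = np.array([planted_density(c) for c in covs])
    scores = draw_scores(density, spec, rng)  # coupled to realized density
    t_total = int(round(spec.duration * fs_sim))
    rows = []
    for i in range(spec.n_subjects):
        cov = covs[i]
        hbo = simulate_neural_hbo(cov, t_total, fs_sim, rng, spec.neural_amp_um)
        row = {
            "density": float(density[i]),
            "score": float(scores[i]),
            "age": float(ages[i]),
            "sex": sex[i],
        }
        for w in windows_min:
            n = int(round(w * 60 * fs_sim))
            fc = _fc_from_hbo(hbo, n, f"sub-{i + 1:03d}", w)
            row[f"ad_{w:g}"] = average_degree(fc)
            if eglob_threshold is not None:
                row[f"eglob_{w:g}"] = global_efficiency(
                    binarize(fc, eglob_threshold)
                )
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_study(
    spec: CohortSpec,
    n_cohorts: int,
    seed: int,
    window_min: float = 30.0,
) -> pd.DataFrame:
    """Repeatedly estimate the density-behavior partial correlation via AD.

    For each cohort: simulate, compute the 30-min AD per subject, and take the
    partial correlation (controlling age and sex) between AD and the behavior
    score.  Returns one row per cohort with ``partial_r``, ``p`` and the
    cohort's realized planted correlation ``rho_planted``.
    """
    rows = []
    for ss in np.random.SeedSequence(seed).spawn(n_cohorts):
        rng = np.random.default_rng(ss)
        df = simulate_cohort_metrics(spec, rng, windows_min=(window_min,))
        cov = df[["age", "sex"]].to_numpy()
        pc = partial_correlation(df[f"ad_{window_min:g}"], df["score"], cov)
        rho_planted = float(np.corrcoef(df["density"], df["score"])[0, 1])
        rows.append({"partial_r": pc.r, "p": pc.p, "n": pc.n,
                     "rho_planted": rho_planted})
    return pd.DataFrame(rows)


def null_calibration(
    spec: CohortSpec,
    n_cohorts: int,
    seed: int,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the association test under a planted rho of zero."""
    null_spec = replace(spec, target_brain_behavior_rho=0.0)
    df = recovery_study(null_spec, n_cohorts, seed)
    rej = int((df["p"] < alpha).sum())
    return {
        "rejections": rej,
        "n_cohorts": n_cohorts,
        "type_i_error": rej / n_cohorts,
        "mean_partial_r": float(df["partial_r"].mean()),
    }


def consistency_curves(
    spec: CohortSpec,
    n_cohorts: int,
    seed: int,
    windows_min: tuple[float, ...] = (1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30),
) -> pd.DataFrame:
    """Window-vs-full-window AD consistency, averaged over cohorts.

    For each cohort and window w, the partial correlation across subjects
    between AD(w) and AD(full), controlling age and sex.  Returns one row per
    (cohort, window).
    """
    full = max(windows_min)
    rows = []
    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(n_cohorts)):
        rng = np.random.default_rng(ss)
        df = simulate_cohort_metrics(spec, rng, windows_min=tuple(windows_min))
        cov = df[["age", "sex"]].to_numpy()
        y = df[f"ad_{full:g}"].to_numpy()
        for w in windows_min:
            x = df[f"ad_{w:g}"].to_numpy()
            if w == full:
                r = 1.0
            else:
                r = partial_correlation(x, y, cov).r
            rows.append({"cohort": c, "window_end_min": float(w), "r_vs_full": r})
    return pd.DataFrame(rows)
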