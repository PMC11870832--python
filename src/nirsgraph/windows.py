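"""Scan-length stability of graph metrics.

Two questions about cumulative windows [0, k] minutes:

* where do cohort-mean AD / Eglob stabilize? (:func:`metric_trajectory`)
* how consistent is each window's metric with the full 30-minute value?
  (:func:`window_consistency` — partial correlation across subjects between
  metric(window) and metric(full), controlling for age and sex; by
  construction the full window correlates 1 with itself.)
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graphs import GraphMetrics
from .probe import SubjectRecord
from .stats import covariate_matrix, partial_correlation

__all__ = ["metric_trajectory", "window_consistency", "metric_vector"]


def metric_vector(m: GraphMetrics, metric: str, threshold: float | None) -> float:
    if metric == "AD":
        return m.ad
    if metric == "Eglob":
        if threshold is None:
            raise ValueError("Eglob requires a threshold")
        return m.eglob[float(threshold)]
    raise ValueError(f"unknown metric {metric!r}")


def _pivot(metrics: Iterable[GraphMetrics], metric: str,
           threshold: float | None) -> pd.DataFrame:
    """subjects x window-end table of one metric."""
    rows = [
        (m.subject_id, m.window.end, metric_vector(m, metric, threshold))
        for m in metrics
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "window", "value"])
    return df.pivot(index="subject_id", columns="window", values="value")


def metric_trajectory(
    metrics: Iterable[GraphMetrics], metric: str, threshold: float | None = None
) -> pd.DataFrame:
    """Cohort mean and SD of one metric at each window, ordered by window end."""
    wide = _pivot(metrics, metric, threshold)
    if wide.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 subjects")
    out = pd.DataFrame(
        {
            "window_end_min": wide.columns,
            "mean": wide.mean(axis=0).to_numpy(),
            "sd": wide.std(axis=0, ddof=1).to_numpy(),
            "n": wide.notna().sum(axis=0).to_numpy(),
        }
    )
    return out.sort_values("window_end_min", ignore_index=True)


def window_consistency(
    metrics: Iterable[GraphMetrics],
    behavior: Sequence[SubjectRecord],
    metric: str,
    threshold: float | None = None,
    full_window: float = 30.0,
) -> pd.DataFrame:
    """Window-vs-full-scan consistency of one metric across subjects.

    For each window w, the partial correlation (controlling age and sex)
    between metric(w) and metric(full_window) over subjects.  Subjects missing
    either window are dropped listwise for that window, with per-window n
    reported.  Returns columns
    ``window_end_min, r_vs_full, p, n, mean, sd``.
    """
    wide = _pivot(metrics, metric, threshold)
    if full_window not in wide.columns:
        raise ValueError(f"no subject has the {full_window}-min window")
    beh = {r.subject_id: r for r in behavior}
    subjects = [s for s in wide.index if s in beh]
    if len(subjects) <= 4:
        raise ValueError("insufficient sample: need n > 4")
    wide = wide.loc[subjects]
    cov = covariate_matrix([beh[s] for s in subjects])
    full = wide[full_window].to_numpy()
    rows = []
    for w in sorted(wide.columns):
        x = wide[w].to_numpy()
        keep = np.isfinite(x) & np.isfinite(full)
        if keep.sum() <= 4:
            rows.append((w, np.nan, np.nan, int(keep.sum()), np.nan, np.nan))
            continue
        if w == full_window:
            # self-consistency is exactly 1 regardless of covariates
            rows.append((w, 1.0, 0.0, int(keep.sum()),
                         float(np.mean(x[keep])), float(np.std(x[keep], ddof=1))))
            continue
        try:
            pc = partial_correlation(x[keep], full[keep], cov[keep])
            r, p, n = pc.r, pc.p, pc.n
        except ValueError:  # metric constant across subjects at this window
            r, p, n = np.nan, np.nan, int(keep.sum())
        rows.append((w, r, p, n,
                     float(np.mean(x[keep])), float(np.std(x[keep], ddof=1))))
    return pd.DataFrame(
        rows, columns=["window_end_min", "r_vs_full", "p", "n", "mean", "sd"]
    )
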