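"""Covariate-controlled association statistics.

The central statistic is the partial correlation between two variables given
covariates (here: age and sex), computed by the residual method: both
variables are least-squares projected on ``[1, covariates]`` and the Pearson
correlation of the residuals is taken.  The two-sided p-value uses
``t = r * sqrt((n - k - 2) / (1 - r^2))`` on ``n - k - 2`` degrees of freedom
(k covariates).  Sex is coded female = 0, male = 1; partial correlation is
invariant to any affine recoding, which the test suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import WindowSpec
from .graphs import GraphMetrics
from .probe import SubjectRecord

__all__ = [
    "PartialCorr",
    "partial_correlation",
    "AssociationResult",
    "brain_behavior_table",
    "encode_sex",
    "covariate_matrix",
]

SEX_CODING = {"female": 0.0, "male": 1.0}


@dataclass(frozen=True)
class PartialCorr:
    r: float
    p: float
    n: int
    dof: int


def encode_sex(records: Sequence[SubjectRecord]) -> np.ndarray:
    return np.array([SEX_CODING[r.sex] for r in records])


def covariate_matrix(records: Sequence[SubjectRecord]) -> np.ndarray:
    """(n, 2) matrix of [age, sex(0/1)] in record order."""
    return np.column_stack(
        [np.array([r.age for r in records]), encode_sex(records)]
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> PartialCorr:
    """Partial Pearson correlation of x and y controlling for covariates.

    ``covariates`` is (n, k) or None/empty for a plain correlation.  Requires
    ``n > k + 2`` and a full-rank covariate design.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match x length")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"insufficient sample: n={n} requires n > k+2={k + 2}")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    rx, ry = resid[:, 0], resid[:, 1]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant variable after residualization")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    dof = n - k - 2
    if 1.0 - r * r < 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorr(r=r, p=p, n=n, dof=dof)


@dataclass(frozen=True)
class AssociationResult:
    """One cell of the brain-behavior table."""

    metric: str                 # "AD" | "Eglob"
    threshold: float | None     # None for AD
    window_end_min: float
    partial_r: float
    p_value: float
    n: int
    covariates: tuple[str, ...] = ("age", "sex")


def brain_behavior_table(
    metrics: Iterable[GraphMetrics],
    behavior: Sequence[SubjectRecord],
    min_n: int = 10,
) -> pd.DataFrame:
    """Partial correlations between the behavior score and each graph metric.

    One row per (AD, window) and per (Eglob, window, threshold): 11 windows
    and 5 thresholds give 66 rows for the full design.  Subjects present in
    only one of the two inputs are dropped with a warning.

    Returns a DataFrame with columns
    ``metric, threshold, window_end_min, partial_r, p, n, covariates``.
    """
    metrics = list(metrics)
    beh = {r.subject_id: r for r in behavior}
    met_ids = {m.subject_id for m in metrics}
    matched = sorted(met_ids & set(beh))
    unmatched = sorted((met_ids | set(beh)) - set(matched))
    if unmatched:
        warnings.warn(
            f"excluding {len(unmatched)} unmatched subject id(s): "
            f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}",
            stacklevel=2,
        )
    if len(matched) < min_n:
        raise ValueError(
            f"only {len(matched)} matched subjects; need at least {min_n}"
        )
    records = [beh[s] for s in matched]
    cov = covariate_matrix(records)
    score = np.array([r.rapm for r in records], dtype=float)

    by_window: dict[float, dict[str, GraphMetrics]] = {}
    for m in metrics:
        if m.subject_id in beh:
            by_window.setdefault(m.window.end, {})[m.subject_id] = m

    rows = []
    thresholds = sorted({t for m in metrics for t in m.eglob})
    for wend in sorted(by_window):
        subj_map = by_window[wend]
        present = [s for s in matched if s in subj_map]
        if len(present) < min_n:
            continue
        idx = [matched.index(s) for s in present]
        c = cov[idx]
        y = score[idx]

        def _cell(x):
            # a metric constant across subjects (e.g. every graph complete at
            # a low threshold) has no defined correlation: report NaN
            try:
                pc = partial_correlation(x, y, c)
                return pc.r, pc.p, pc.n
            except ValueError:
                return np.nan, np.nan, len(x)

        r, p, n = _cell(np.array([subj_map[s].ad for s in present]))
        rows.append(("AD", np.nan, wend, r, p, n))
        for t in thresholds:
            r, p, n = _cell(np.array([subj_map[s].eglob[t] for s in present]))
            rows.append(("Eglob", t, wend, r, p, n))
    df = pd.DataFrame(
        rows, columns=["metric", "threshold", "window_end_min", "partial_r", "p", "n"]
    )
    df["covariates"] = "age+sex(female=0)"
    return df
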