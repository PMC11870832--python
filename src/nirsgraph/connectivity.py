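"""Windowed functional connectivity: Pearson correlation + Fisher r-to-z.

Connectivity is computed from HbO over cumulative windows anchored at t = 0;
the canonical window set ends at 1, 2, 3, 5, 8, 10, 12, 15, 20, 25 and 30
minutes.  The Fisher transform z = atanh(r) linearizes correlations for the
downstream graph statistics; diagonals are excluded from every statistic,
never treated as data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import HbSeries

__all__ = [
    "WindowSpec",
    "CANONICAL_WINDOW_MINUTES",
    "canonical_windows",
    "FCMatrix",
    "compute_fc",
    "fisher_z",
    "offdiag_values",
]

CANONICAL_WINDOW_MINUTES = (1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30)

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Cumulative analysis window [start, end) in minutes; start is always 0."""

    end: float
    start: float = 0.0

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window end must exceed start")
        if self.start != 0.0:
            raise ValueError("windows are cumulative: start must be 0")

    @property
    def n_samples_at(self) -> None:  # pragma: no cover - documentation aid
        raise AttributeError("use compute_fc; sample count depends on fs")


def canonical_windows() -> list[WindowSpec]:
    return [WindowSpec(end=float(m)) for m in CANONICAL_WINDOW_MINUTES]


@dataclass
class FCMatrix:
    """Pearson (r) and Fisher-z functional-connectivity matrices, 18x18."""

    r: np.ndarray
    z: np.ndarray
    window: WindowSpec
    subject_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.r.shape[0]


def offdiag_values(m: np.ndarray) -> np.ndarray:
    """Upper-triangle off-diagonal entries of a symmetric matrix."""
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def compute_fc(hb: HbSeries, window: WindowSpec) -> FCMatrix:
    """Pearson correlation of HbO channels over ``[0, window.end)`` minutes."""
    n = int(round(window.end * 60.0 * hb.sampling_rate))
    if n > hb.n_samples:
        raise ValueError(
            f"window end {window.end} min exceeds scan "
            f"({hb.n_samples / hb.sampling_rate / 60:.2f} min)"
        )
    if n < 30:
        raise ValueError("window too short: fewer than 30 samples")
    seg = hb.hbo[:, :n]
    sd = seg.std(axis=1)
    if (sd == 0).any():
        k = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance channel {k} in window [0, {window.end}) min")
    r = np.corrcoef(seg)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    fc = FCMatrix(r=r, z=np.zeros_like(r), window=window, subject_id=hb.subject_id)
    return fisher_z(fc)


def fisher_z(fc: FCMatrix) -> FCMatrix:
    """Fill ``fc.z`` with atanh(r) off-diagonal (diagonal kept at 0).

    Off-diagonal |r| >= 1 (possible only for degenerate, duplicated channels)
    is clipped to 1 - 1e-7 with a warning so z stays finite.
    """
    r = fc.r.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= 1.0).any():
        warnings.warn(
            "off-diagonal |r| >= 1 clipped before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r[off] = np.clip(r[off], -_CLIP, _CLIP)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    fc.z = z
    return fc
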