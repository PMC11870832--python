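"""Probe geometry and raw-data containers for continuous-wave NIRS recordings.

The montage modelled here is a bilateral dorsolateral-prefrontal (DLPFC) array:
8 LED sources and 8 avalanche-photodiode detectors forming 18 measurement
channels, sampled at two wavelengths (760 nm and 850 nm).  Channel order is
part of the contract: every downstream matrix (functional connectivity,
adjacency) indexes channels in the order listed in :class:`ProbeLayout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProbeLayout",
    "RawScan",
    "SubjectRecord",
    "DLPFC_MONTAGE",
    "N_CHANNELS",
    "WAVELENGTHS_NM",
    "MontageError",
]

N_CHANNELS = 18
WAVELENGTHS_NM = (760.0, 850.0)


class MontageError(ValueError):
    """Raised when data do not match the expected 18-channel DLPFC montage."""


@dataclass(frozen=True)
class ProbeLayout:
    """Optode montage: channel list plus wavelength pair.

    Parameters
    ----------
    channels
        Ordered tuple of ``(source_index, detector_index, hemisphere)`` with
        1-based optode indices and hemisphere label ``"L"`` or ``"R"``.
    wavelengths
        Strictly increasing pair of wavelengths in nm.
    """

    channels: tuple[tuple[int, int, str], ...]
    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    n_sources: int = 8
    n_detectors: int = 8

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise MontageError(
                f"expected {N_CHANNELS} channels, got {len(self.channels)}"
            )
        for k, (s, d, h) in enumerate(self.channels):
            if not (1 <= s <= self.n_sources):
                raise MontageError(f"channel {k}: source index {s} out of range")
            if not (1 <= d <= self.n_detectors):
                raise MontageError(f"channel {k}: detector index {d} out of range")
            if h not in ("L", "R"):
                raise MontageError(f"channel {k}: hemisphere {h!r} not in {{L, R}}")
        if not self.wavelengths[0] < self.wavelengths[1]:
            raise MontageError("wavelengths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_labels(self) -> list[str]:
        """Human-readable labels like ``CH01(S1-D1,L)``."""
        return [
            f"CH{k + 1:02d}(S{s}-D{d},{h})"
            for k, (s, d, h) in enumerate(self.channels)
        ]


#: Default bilateral DLPFC montage: 9 channels per hemisphere.
DLPFC_MONTAGE = ProbeLayout(
    channels=(
        (1, 1, "L"), (1, 2, "L"), (2, 1, "L"), (2, 2, "L"), (2, 3, "L"),
        (3, 2, "L"), (3, 3, "L"), (4, 3, "L"), (4, 4, "L"),
        (5, 5, "R"), (5, 6, "R"), (6, 5, "R"), (6, 6, "R"), (6, 7, "R"),
        (7, 6, "R"), (7, 7, "R"), (8, 7, "R"), (8, 8, "R"),
    )
)


@dataclass
class RawScan:
    """Raw dual-wavelength intensity recording for one subject.

    ``intensity`` has shape ``(n_channels, n_wavelengths, n_samples)`` in
    arbitrary detector units.  Saturated samples are stored as NaN — missing
    data are first-class, never sentinel numbers.
    """

    subject_id: str
    intensity: np.ndarray
    sampling_rate: float
    probe: ProbeLayout = field(default_factory=lambda: DLPFC_MONTAGE)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channel, wavelength, sample)")
        c, w, _ = self.intensity.shape
        if c != self.probe.n_channels:
            raise MontageError(
                f"intensity has {c} channels, montage has {self.probe.n_channels}"
            )
        if w != len(self.probe.wavelengths):
            raise MontageError(f"intensity has {w} wavelengths, expected 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        finite = self.intensity[np.isfinite(self.intensity)]
        if finite.size and finite.min() < 0:
            raise ValueError("intensity must be non-negative where not missing")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        """Scan duration in seconds."""
        return self.n_samples / self.sampling_rate

    def copy(self) -> "RawScan":
        return RawScan(
            subject_id=self.subject_id,
            intensity=self.intensity.copy(),
            sampling_rate=self.sampling_rate,
            probe=self.probe,
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Behavioral record: Raven's Advanced Progressive Matrices (set II) score
    plus the covariates controlled in the association analysis."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    rapm: int

    def __post_init__(self) -> None:
        if not (0 <= self.rapm <= 36):
            raise ValueError(
                f"subject {self.subject_id}: rapm={self.rapm} outside 0..36"
            )
        if self.age < 18:
            raise ValueError(f"subject {self.subject_id}: age {self.age} < 18")
        if self.sex not in ("female", "male"):
            raise ValueError(f"subject {self.subject_id}: sex {self.sex!r}")


def behavior_frame(records: Sequence[SubjectRecord]):
    """Convenience: records -> pandas DataFrame (subject_id, age, sex, rapm)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "rapm": [r.rapm for r in records],
        }
    )
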