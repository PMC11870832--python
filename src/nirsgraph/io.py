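"""Reading and writing scans and behavior tables.

Two on-disk dialects are supported for scans:

* a minimal SNIRF dialect (``.snirf``, HDF5): ``/formatVersion``,
  ``/nirs/data1/dataTimeSeries`` (samples x measurements), ``/nirs/data1/time``,
  one ``measurementList<k>`` group per column with source/detector/wavelength
  indices, and ``/nirs/probe/wavelengths``.  Auxiliary channels and stimulus
  blocks are out of scope.
* a CSV fallback (``.csv``) with one column per channel-wavelength and a
  comment header carrying subject id and sampling rate — handy for small
  text fixtures.

Behavior tables are CSV with a required header
``subject_id,age,sex,rapm``.
"""

from __future__ import annotations

import os
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .probe import (
    DLPFC_MONTAGE,
    MontageError,
    N_CHANNELS,
    ProbeLayout,
    RawScan,
    SubjectRecord,
)

__all__ = [
    "read_scan",
    "write_scan",
    "read_behavior",
    "write_behavior",
    "FormatError",
]

SNIRF_VERSION = "1.0"


class FormatError(ValueError):
    """Raised when a file does not conform to the supported dialect."""


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def write_scan(scan: RawScan, path: str | os.PathLike) -> str:
    """Write a scan; dialect chosen by extension (.snirf -> HDF5, .csv -> CSV)."""
    path = str(path)
    if path.endswith(".csv"):
        _write_scan_csv(scan, path)
    else:
        _write_scan_snirf(scan, path)
    return path


def read_scan(path: str | os.PathLike) -> RawScan:
    """Read a scan written by :func:`write_scan` (round-trip identity)."""
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".csv"):
        return _read_scan_csv(path)
    return _read_scan_snirf(path)


def _write_scan_snirf(scan: RawScan, path: str) -> None:
    c, w, t = scan.intensity.shape
    data = np.empty((t, c * w))
    for k in range(c):
        for j in range(w):
            data[:, k * w + j] = scan.intensity[k, j]
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=SNIRF_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=scan.subject_id)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(t) / scan.sampling_rate)
        for k in range(c):
            s, d, hemi = scan.probe.channels[k]
            for j in range(w):
                ml = d1.create_group(f"measurementList{k * w + j + 1}")
                ml.create_dataset("sourceIndex", data=s)
                ml.create_dataset("detectorIndex", data=d)
                ml.create_dataset("wavelengthIndex", data=j + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("hemisphere", data=hemi)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(scan.probe.wavelengths))


def _read_scan_snirf(path: str) -> RawScan:
    with h5py.File(path, "r") as f:
        try:
            d1 = f["nirs/data1"]
            data = np.asarray(d1["dataTimeSeries"])
            time = np.asarray(d1["time"])
            wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]))
        except KeyError as e:
            raise FormatError(f"{path}: missing required field {e}") from e
        subject_id = _h5_str(f, "nirs/metaDataTags/SubjectID", default="unknown")
        n_meas = data.shape[1]
        if n_meas % len(wavelengths):
            raise FormatError(
                f"{path}: {n_meas} measurement columns not divisible by "
                f"{len(wavelengths)} wavelengths"
            )
        n_ch = n_meas // len(wavelengths)
        if n_ch != N_CHANNELS:
            raise MontageError(
                f"{path}: {n_ch} channels, montage requires {N_CHANNELS}"
            )
        channels: list[tuple[int, int, str] | None] = [None] * n_ch
        cols = np.empty((n_ch, len(wavelengths)), dtype=int)
        for m in range(n_meas):
            ml = d1[f"measurementList{m + 1}"]
            s = int(np.asarray(ml["sourceIndex"]))
            d = int(np.asarray(ml["detectorIndex"]))
            wi = int(np.asarray(ml["wavelengthIndex"])) - 1
            hemi = _h5_str(d1, f"measurementList{m + 1}/hemisphere", default="L")
            k = m // len(wavelengths)
            channels[k] = (s, d, hemi)
            cols[k, wi] = m
        if len(time) > 1:
            fs = 1.0 / float(np.median(np.diff(time)))
        else:
            raise FormatError(f"{path}: time vector too short")
    probe = ProbeLayout(channels=tuple(channels), wavelengths=(float(wavelengths[0]), float(wavelengths[1])))  # type: ignore[arg-type]
    intensity = np.empty((n_ch, len(wavelengths), data.shape[0]))
    for k in range(n_ch):
        for j in range(len(wavelengths)):
            intensity[k, j] = data[:, cols[k, j]]
    return RawScan(subject_id=subject_id, intensity=intensity,
                   sampling_rate=fs, probe=probe)


def _h5_str(f, key: str, default: str) -> str:
    if key not in f:
        return default
    v = np.asarray(f[key])
    s = v.item() if v.shape == () else v[0]
    return s.decode() if isinstance(s, bytes) else str(s)


def _write_scan_csv(scan: RawScan, path: str) -> None:
    c, w, t = scan.intensity.shape
    cols = {}
    for k in range(c):
        for j in range(w):
            wl = int(scan.probe.wavelengths[j])
            cols[f"ch{k + 1:02d}_{wl}"] = scan.intensity[k, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={scan.subject_id}\n")
        fh.write(f"# sampling_rate={scan.sampling_rate!r}\n")
        df.to_csv(fh, index=False)  # shortest round-trip float repr


def _read_scan_csv(path: str) -> RawScan:
    subject_id, fs = "unknown", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "subject_id":
                subject_id = val.strip()
            elif key.strip() == "sampling_rate":
                fs = float(val)
    if fs is None:
        raise FormatError(f"{path}: missing '# sampling_rate=' header")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    n_ch = len(df.columns) // 2
    if n_ch != N_CHANNELS:
        raise MontageError(f"{path}: {n_ch} channels, montage requires {N_CHANNELS}")
    intensity = np.empty((n_ch, 2, len(df)))
    wls = [int(w) for w in DLPFC_MONTAGE.wavelengths]
    for k in range(n_ch):
        for j, wl in enumerate(wls):
            col = f"ch{k + 1:02d}_{wl}"
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col}")
            intensity[k, j] = df[col].to_numpy()
    return RawScan(subject_id=subject_id, intensity=intensity, sampling_rate=fs)


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------

_SEX_ALIASES = {
    "f": "female", "female": "female", "0": "female",
    "m": "male", "male": "male", "1": "male",
}


def read_behavior(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a behavior CSV; invalid rows raise with their row numbers."""
    df = pd.read_csv(path)
    required = {"subject_id", "age", "sex", "rapm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records, bad = [], []
    for i, row in df.iterrows():
        try:
            sex = _SEX_ALIASES[str(row["sex"]).strip().lower()]
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    sex=sex,
                    rapm=int(row["rapm"]),
                )
            )
        except (KeyError, ValueError) as e:
            bad.append(f"row {i + 2}: {e}")  # +2: header + 1-based
    if bad:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(bad))
    return records


def write_behavior(records: Sequence[SubjectRecord], path: str | os.PathLike) -> str:
    from .probe import behavior_frame

    behavior_frame(records).to_csv(path, index=False)
    return str(path)
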