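"""End-to-end run: synthesis (optional) -> preprocessing -> connectivity ->
graph metrics -> stability -> associations, with a checksum manifest.

All artifacts are CSV (plus a JSON manifest); the full configuration and a
per-stage log are echoed so a run can be audited and reproduced.  Everything
is deterministic under a fixed seed: rerunning a config yields bit-identical
CSV payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as ngio
from .connectivity import CANONICAL_WINDOW_MINUTES, WindowSpec, compute_fc
from .graphs import DEFAULT_THRESHOLDS, metrics_for_subject
from .preprocess import MotionParams, preprocess_scan
from .probe import RawScan, SubjectRecord, behavior_frame
from .stats import brain_behavior_table
from .synth import CohortSpec, generate_cohort
from .windows import metric_trajectory, window_consistency

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; serializable to/from YAML."""

    output_dir: str = "nirsgraph_out"
    input_dir: str | None = None        # None: synthesize a cohort instead
    seed: int = 0
    # synthesis (used when input_dir is None)
    n_subjects: int = 24
    duration: float = 1800.0
    sampling_rate: float = 10.0
    target_brain_behavior_rho: float = -0.33
    artifact_rate: float = 0.5
    saturation_rate: float = 0.3
    # preprocessing
    t_motion: float = 0.5
    t_mask: float = 5.0
    stdev_thresh: float = 15.0
    amp_thresh: float = 0.5
    band_low: float = 0.01
    band_high: float = 0.08
    filter_order: int = 3
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0
    wavelet: str = "db5"
    wavelet_level: int = 4
    iqr_factor: float = 1.5
    cv_threshold: float = 15.0
    filter_stage: str = "od"
    # graph analysis
    windows_min: tuple[float, ...] = tuple(float(m) for m in CANONICAL_WINDOW_MINUTES)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    threshold_on: str = "r"
    ad_on: str = "z"
    covariates: tuple[str, ...] = ("age", "sex")
    write_scans: bool = False
    exclude_flagged_subjects: bool = True

    def __post_init__(self) -> None:
        canon = set(float(m) for m in CANONICAL_WINDOW_MINUTES)
        if not set(self.windows_min) <= canon:
            raise ValueError(f"windows must be a subset of {sorted(canon)}")
        if not set(round(t, 10) for t in self.thresholds) <= {0.1, 0.2, 0.3, 0.4, 0.5}:
            raise ValueError("thresholds must be a subset of {0.1..0.5}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dpf", "windows_min", "thresholds", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.input_dir is None:
        spec = CohortSpec(
            n_subjects=cfg.n_subjects,
            duration=cfg.duration,
            sampling_rate=cfg.sampling_rate,
            target_brain_behavior_rho=cfg.target_brain_behavior_rho,
            artifact_rate=cfg.artifact_rate,
            saturation_rate=cfg.saturation_rate,
            seed=cfg.seed,
        )
        scans, records, _ = generate_cohort(spec)
        return scans, records
    beh = ngio.read_behavior(os.path.join(cfg.input_dir, "behavior.csv"))
    scans = []
    for r in beh:
        for ext in (".snirf", ".csv"):
            p = os.path.join(cfg.input_dir, f"{r.subject_id}{ext}")
            if os.path.exists(p):
                scans.append(ngio.read_scan(p))
                break
        else:
            raise FileNotFoundError(f"no scan found for subject {r.subject_id}")
    return scans, beh


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    log: list[str] = []

    def stage(name: str, **params):
        log.append(json.dumps({"stage": name, **params}, default=str))

    scans, records = _load_inputs(cfg)
    stage("inputs", n_subjects=len(scans),
          source="synthetic" if cfg.input_dir is None else cfg.input_dir,
          seed=cfg.seed)
    beh_path = os.path.join(cfg.output_dir, "behavior.csv")
    behavior_frame(records).to_csv(beh_path, index=False)
    if cfg.write_scans:
        for s in scans:
            ngio.write_scan(s, os.path.join(cfg.output_dir, f"{s.subject_id}.snirf"))

    mp = MotionParams(t_motion=cfg.t_motion, t_mask=cfg.t_mask,
                      stdev_thresh=cfg.stdev_thresh, amp_thresh=cfg.amp_thresh)
    quality_rows, all_metrics, kept = [], [], []
    failed = None
    for scan in scans:
        try:
            hb, report = preprocess_scan(
                scan, motion_params=mp,
                band=(cfg.band_low, cfg.band_high), filter_order=cfg.filter_order,
                dpf=cfg.dpf, distance_cm=cfg.distance_cm,
                wavelet=cfg.wavelet, wavelet_level=cfg.wavelet_level,
                iqr_factor=cfg.iqr_factor, cv_threshold=cfg.cv_threshold,
                filter_stage=cfg.filter_stage,
            )
        except Exception as e:
            failed = (scan.subject_id, "preprocess", str(e))
            break
        quality_rows.append(
            {
                "subject_id": scan.subject_id,
                "max_cv_percent": float(np.nanmax(report.cv)),
                "n_excluded_channels": len(report.excluded_channels),
                "nan_segment_count": report.nan_segment_count,
                "motion_fraction": report.motion_fraction,
                "flagged": report.subject_flagged,
            }
        )
        if cfg.exclude_flagged_subjects and report.subject_flagged:
            continue
        fcs = [compute_fc(hb, WindowSpec(end=w)) for w in cfg.windows_min]
        all_metrics.extend(
            metrics_for_subject(fcs, thresholds=cfg.thresholds,
                                threshold_on=cfg.threshold_on, ad_on=cfg.ad_on)
        )
        kept.append(scan.subject_id)
    stage("preprocess", params=dataclasses.asdict(mp) if hasattr(mp, "__dict__") else str(mp),
          kept=len(kept), flagged=len(scans) - len(kept))

    pd.DataFrame(quality_rows).to_csv(
        os.path.join(cfg.output_dir, "quality.csv"), index=False
    )
    met_rows = []
    for m in all_metrics:
        met_rows.append({"subject_id": m.subject_id,
                         "window_end_min": m.window.end,
                         "metric": "AD", "threshold": np.nan, "value": m.ad})
        for t, v in sorted(m.eglob.items()):
            met_rows.append({"subject_id": m.subject_id,
                             "window_end_min": m.window.end,
                             "metric": "Eglob", "threshold": t, "value": v})
    pd.DataFrame(met_rows).to_csv(
        os.path.join(cfg.output_dir, "metrics_long.csv"), index=False
    )

    if failed is None and kept:
        records_kept = [r for r in records if r.subject_id in set(kept)]
        traj = []
        consist = []
        for metric, thr_list in (("AD", [None]), ("Eglob", list(cfg.thresholds))):
            for t in thr_list:
                tr = metric_trajectory(all_metrics, metric, t)
                tr.insert(0, "metric", metric)
                tr.insert(1, "threshold", np.nan if t is None else t)
                traj.append(tr)
                if len(records_kept) > 4:
                    cs = window_consistency(all_metrics, records_kept, metric, t,
                                            full_window=max(cfg.windows_min))
                    cs.insert(0, "metric", metric)
                    cs.insert(1, "threshold", np.nan if t is None else t)
                    consist.append(cs)
        pd.concat(traj, ignore_index=True).to_csv(
            os.path.join(cfg.output_dir, "trajectory.csv"), index=False
        )
        if consist:
            pd.concat(consist, ignore_index=True).to_csv(
                os.path.join(cfg.output_dir, "consistency.csv"), index=False
            )
        if len(records_kept) >= 10:
            assoc = brain_behavior_table(all_metrics, records_kept)
            assoc.to_csv(os.path.join(cfg.output_dir, "associations.csv"),
                         index=False)
            stage("associate", rows=len(assoc))
    cfg_path = os.path.join(cfg.output_dir, "config.yaml")
    cfg.to_yaml(cfg_path)
    with open(os.path.join(cfg.output_dir, "run_log.jsonl"), "w") as fh:
        fh.write("\n".join(log) + "\n")

    files = sorted(
        f for f in os.listdir(cfg.output_dir)
        if f not in ("manifest.json",) and os.path.isfile(os.path.join(cfg.output_dir, f))
    )
    manifest = {
        "config": cfg_path,
        "failed": failed,
        "files": {f: _sha256(os.path.join(cfg.output_dir, f)) for f in files},
    }
    if failed is not None:
        open(os.path.join(cfg.output_dir, "FAILED"), "w").write(
            json.dumps(failed)
        )
        manifest["files"]["FAILED"] = _sha256(os.path.join(cfg.output_dir, "FAILED"))
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failed is not None:
        raise RuntimeError(
            f"stage {failed[1]} failed for subject {failed[0]}: {failed[2]}"
        )
    return manifest
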