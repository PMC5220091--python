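"""Delimited-text I/O: subject recordings, cohort manifests, kernel tables.

Raw schema: one CSV per subject per condition with columns
``time_s, bp_mmHg, mcav_cm_s, petco2_mmHg``; a manifest CSV maps each file
to ``subject_id, group, condition``.  The synthetic path writes the same
schema the real-data path reads, so the two are interchangeable at the
manifest level.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import EventSeries, SubjectRecording, UniformSeries

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_cohort",
    "read_cohort",
    "write_first_order_kernel_csv",
    "write_second_order_kernel_csv",
    "write_pdms_csv",
    "write_run_summary",
]

RAW_COLUMNS = ["time_s", "bp_mmHg", "mcav_cm_s", "petco2_mmHg"]


def write_recording_csv(path, rec: SubjectRecording) -> None:
    df = pd.DataFrame({
        "time_s": rec.bp.times,
        "bp_mmHg": rec.bp.values,
        "mcav_cm_s": rec.flow.values,
        "petco2_mmHg": rec.co2.values,
    })
    df.to_csv(path, index=False)


def read_recording_csv(path, subject_id: str, group: str, condition: str,
                       as_events: bool = False) -> SubjectRecording | dict:
    """Read one raw recording.

    With ``as_events=True`` returns a dict of :class:`EventSeries` (for the
    resampling front-end); otherwise the time column must be uniform and a
    :class:`SubjectRecording` is returned.
    """
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    if as_events:
        return {
            "bp": EventSeries(t, df["bp_mmHg"].to_numpy(float), "bp", "mmHg"),
            "co2": EventSeries(t, df["petco2_mmHg"].to_numpy(float), "co2",
                               "mmHg"),
            "flow": EventSeries(t, df["mcav_cm_s"].to_numpy(float), "flow",
                                "cm/s"),
        }
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0]):
        raise ValueError(f"{path}: time grid not uniform; read as events "
                         "and resample")
    fs = 1.0 / dt[0]
    return SubjectRecording(
        subject_id=subject_id, group=group, condition=condition,
        bp=UniformSeries(df["bp_mmHg"].to_numpy(float), fs, "bp", "mmHg"),
        co2=UniformSeries(df["petco2_mmHg"].to_numpy(float), fs, "co2",
                          "mmHg"),
        flow=UniformSeries(df["mcav_cm_s"].to_numpy(float), fs, "flow",
                           "cm/s"))


def write_cohort(out_dir, cohort) -> Path:
    """Write every recording, the manifest and the ground-truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        fname = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording_csv(out / fname, rec)
        rows.append({"file": fname, "subject_id": rec.subject_id,
                     "group": rec.group, "condition": rec.condition})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    ledger = {
        "seed": cohort.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cohort.config).items()
                   if not hasattr(v, "__dataclass_fields__")},
        "effect": vars(cohort.config.effect),
        "systems": {
            "|".join(key): {
                "beta": system.beta_true.to_flat().tolist(),
                "anf_gains_true_bp": system.anf_gains_true_bp.tolist(),
                "anf_gains_true_co2": system.anf_gains_true_co2.tolist(),
                "noise_sd": system.noise_sd,
            } for key, system in cohort.systems.items()},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
    return out


def read_cohort(in_dir) -> list[SubjectRecording]:
    """Read all recordings listed in a cohort manifest."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    return [read_recording_csv(in_dir / row.file, row.subject_id, row.group,
                               row.condition)
            for row in manifest.itertuples()]


def write_first_order_kernel_csv(path, kernel, fs: float = 1.0) -> None:
    k = np.asarray(kernel, float)
    pd.DataFrame({"lag_s": np.arange(k.size) / fs, "value": k}).to_csv(
        path, index=False)


def write_second_order_kernel_csv(path, kernel2, fs: float = 1.0) -> None:
    k2 = np.asarray(kernel2, float)
    m1, m2 = np.meshgrid(np.arange(k2.shape[0]) / fs,
                         np.arange(k2.shape[1]) / fs, indexing="ij")
    pd.DataFrame({"m1_s": m1.ravel(), "m2_s": m2.ravel(),
                  "value": k2.ravel()}).to_csv(path, index=False)


def write_pdms_csv(path, pdm_set, fs: float = 1.0) -> None:
    cols = {"lag_s": np.arange(pdm_set.M) / fs}
    for i in range(pdm_set.H):
        cols[f"g_{i + 1}"] = pdm_set.pdms[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_run_summary(path, **fields) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (tuple, set)):
            return list(o)
        raise TypeError(f"unserializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=1, default=_default)
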