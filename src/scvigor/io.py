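"""Session-bundle readers and writers (plain CSV/JSON on disk).

A session directory contains::

    manifest.json   session id, subject, sampling rate
    trials.csv      trial_id, condition, object_id, fix_on_ms, target_on_ms,
                    target_x_deg, target_y_deg, outcome
    spikes.csv      unit_id, channel, spike_ms
    eye.csv         t_ms, x_deg, y_deg
    truth.json      (synthetic sessions only) ground-truth labels/params

Times are serialized as ms with 0.1 ms precision; angles as degrees.
Readers validate the schema and raise :class:`DataFormatError` naming
the offending file (and unit or row where possible).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .synth import SessionBundle, TrialRecord, UnitRecord

_TRIAL_COLS = ["trial_id", "condition", "object_id", "fix_on_ms", "target_on_ms",
               "target_x_deg", "target_y_deg", "outcome"]
_CONDITIONS = {"good", "bad"}


def write_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write a session bundle to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2,
                                                  sort_keys=True) + "\n")
    trials = pd.DataFrame([{
        "trial_id": tr.trial_id, "condition": tr.condition,
        "object_id": tr.object_id,
        "fix_on_ms": round(tr.fix_on_ms, 1), "target_on_ms": round(tr.target_on_ms, 1),
        "target_x_deg": round(tr.target_x_deg, 4),
        "target_y_deg": round(tr.target_y_deg, 4),
        "outcome": tr.outcome,
    } for tr in bundle.trials], columns=_TRIAL_COLS)
    trials.to_csv(out / "trials.csv", index=False, float_format="%.4f")

    rows = []
    for u in bundle.units:
        for s in u.spike_ms:
            rows.append((u.unit_id, u.channel, round(float(s), 1)))
    spikes = pd.DataFrame(rows, columns=["unit_id", "channel", "spike_ms"])
    spikes.to_csv(out / "spikes.csv", index=False, float_format="%.1f")

    eye = pd.DataFrame({"t_ms": bundle.eye_t,
                        "x_deg": np.round(bundle.eye_x, 4),
                        "y_deg": np.round(bundle.eye_y, 4)})
    eye.to_csv(out / "eye.csv", index=False, float_format="%.4f")

    if bundle.truth is not None:
        (out / "truth.json").write_text(json.dumps(bundle.truth, indent=1,
                                                   sort_keys=True) + "\n")
    return out


def read_session(session_dir: str | Path) -> SessionBundle:
    """Read and validate a session bundle from a directory."""
    d = Path(session_dir)
    for fname in ("manifest.json", "trials.csv", "spikes.csv", "eye.csv"):
        if not (d / fname).exists():
            raise DataFormatError(f"missing session file: {d / fname}")
    manifest = json.loads((d / "manifest.json").read_text())
    if int(manifest.get("sampling_rate_hz", 0)) != 1000:
        raise DataFormatError(f"{d / 'manifest.json'}: sampling rate must be 1000 Hz")

    trials_df = pd.read_csv(d / "trials.csv")
    missing = [c for c in _TRIAL_COLS if c not in trials_df.columns]
    if missing:
        raise DataFormatError(f"{d / 'trials.csv'}: missing columns {missing}")
    trials = []
    for i, row in trials_df.iterrows():
        if row["condition"] not in _CONDITIONS:
            raise DataFormatError(
                f"{d / 'trials.csv'} row {i}: unknown condition {row['condition']!r}")
        if row["target_on_ms"] < row["fix_on_ms"] + 300.0 - 1e-6:
            raise DataFormatError(
                f"{d / 'trials.csv'} row {i}: target onset before fixation + 300 ms")
        trials.append(TrialRecord(
            trial_id=int(row["trial_id"]), condition=str(row["condition"]),
            object_id=int(row["object_id"]),
            fix_on_ms=float(row["fix_on_ms"]), target_on_ms=float(row["target_on_ms"]),
            target_x_deg=float(row["target_x_deg"]),
            target_y_deg=float(row["target_y_deg"]), outcome=str(row["outcome"])))

    spikes_df = pd.read_csv(d / "spikes.csv")
    units = []
    for unit_id, grp in spikes_df.groupby("unit_id", sort=False):
        st = grp["spike_ms"].to_numpy(dtype=float)
        if np.any(np.diff(st) < 0):
            raise DataFormatError(
                f"{d / 'spikes.csv'}: non-monotone spike times for unit {unit_id}")
        if st.size and st[0] < 0:
            raise DataFormatError(
                f"{d / 'spikes.csv'}: negative spike time for unit {unit_id}")
        units.append(UnitRecord(unit_id=str(unit_id),
                                channel=int(grp["channel"].iloc[0]), spike_ms=st))

    eye_df = pd.read_csv(d / "eye.csv")
    t = eye_df["t_ms"].to_numpy(dtype=float)
    if t.size < 2 or not np.allclose(np.diff(t), 1.0, atol=1e-6):
        raise DataFormatError(f"{d / 'eye.csv'}: eye sampling must be uniform 1 kHz")

    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())

    return SessionBundle(manifest=manifest, trials=trials, units=units,
                         eye_t=t, eye_x=eye_df["x_deg"].to_numpy(dtype=float),
                         eye_y=eye_df["y_deg"].to_numpy(dtype=float), truth=truth)
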