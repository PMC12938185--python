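"""Readers and writers for recordings, montages, templates and tables.

Recordings travel as plain CSV matrices (rows = channels, first column
the channel id, remaining columns samples) next to a channel-location
CSV (id, x, y, z); EDF files are read through MNE when present.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import TemplateSet
from .montage import Montage
from .recording import EEGRecording

__all__ = [
    "read_montage_csv",
    "write_montage_csv",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "read_recording",
    "write_templates",
    "read_templates",
]


def read_montage_csv(path: str | Path) -> Montage:
    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(float)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(df["id"].astype(str)), pos)


def write_montage_csv(montage: Montage, path: str | Path) -> None:
    pd.DataFrame(
        {"id": montage.channel_ids, "x": montage.positions[:, 0],
         "y": montage.positions[:, 1], "z": montage.positions[:, 2]}
    ).to_csv(path, index=False)


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.data, index=list(rec.montage.channel_ids))
    df.index.name = "channel"
    df.to_csv(path)
    meta = {"sampling_rate": rec.sampling_rate, "subject_id": rec.subject_id, "group": rec.group}
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def read_recording_csv(path: str | Path, montage: Montage, sampling_rate: Optional[float] = None) -> EEGRecording:
    df = pd.read_csv(path, index_col=0)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fs = sampling_rate if sampling_rate is not None else meta.get("sampling_rate")
    if fs is None:
        raise ValueError("sampling rate not given and no JSON sidecar found")
    order = [df.index.get_loc(ch) for ch in montage.channel_ids]
    return EEGRecording(
        df.to_numpy(float)[order], float(fs), montage,
        subject_id=meta.get("subject_id", Path(path).stem), group=meta.get("group", "synthetic"),
    )


def read_recording_edf(path: str | Path, montage: Montage) -> EEGRecording:
    """Read an EDF file (channels matched to the montage by name)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [raw.ch_names.index(ch) for ch in montage.channel_ids]
    data = raw.get_data()[picks] * 1e6  # volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), montage, subject_id=Path(path).stem)


def read_recording(path: str | Path, montage: Montage, **kwargs) -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, montage)
    return read_recording_csv(path, montage, **kwargs)


def write_templates(ts: TemplateSet, montage: Montage, path: str | Path) -> None:
    """Templates as CSV (rows = states, columns = channels) + JSON sidecar."""
    df = pd.DataFrame(ts.maps, index=list(ts.labels), columns=list(montage.channel_ids))
    df.index.name = "state"
    df.to_csv(path)
    sidecar = {"band": ts.band, "gev_total": ts.gev_total, "cv_criterion": ts.cv_criterion,
               "k_profile": ts.k_profile}
    Path(path).with_suffix(".json").write_text(json.dumps(sidecar, default=float))


def read_templates(path: str | Path) -> TemplateSet:
    df = pd.read_csv(path, index_col=0)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ts = TemplateSet(df.to_numpy(float), tuple(df.index.astype(str)), band=meta.get("band", ""))
    ts.gev_total = meta.get("gev_total", float("nan"))
    ts.cv_criterion = meta.get("cv_criterion", float("nan"))
    ts.k_profile = meta.get("k_profile")
    return ts
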