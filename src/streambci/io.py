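"""Serialization: HDF5 containers for recordings/epochs and decoder models.

Recordings are stored as ``/data`` (channels x samples) with ``fs_hz`` and
``channel_labels`` attributes, an ``/events`` table, per-trial labels, and a
JSON sidecar mirroring the metadata for audit without an HDF5 reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decode import AttentionDecoderResults, Whitener
from .synthgen import Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_model",
    "load_model",
]

_EVENT_COLS = ["trial_id", "stream", "index", "kind", "onset_sample"]


def save_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["fs_hz"] = recording.fs_hz
        f.attrs["channel_labels"] = list(recording.channel_labels)
        f.attrs["attended"] = list(recording.attended)
        ev = f.create_group("events")
        for col in _EVENT_COLS:
            vals = recording.events[col].to_numpy()
            if vals.dtype.kind in "OU":
                vals = vals.astype("S")
            ev.create_dataset(col, data=vals)
    sidecar = {
        "fs_hz": recording.fs_hz,
        "channel_labels": list(recording.channel_labels),
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "n_trials": len(recording.attended),
        "n_events": len(recording.events),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs_hz = float(f.attrs["fs_hz"])
        labels = tuple(str(x) for x in f.attrs["channel_labels"])
        attended = tuple(str(x) for x in f.attrs["attended"])
        cols = {}
        for col in _EVENT_COLS:
            vals = f["events"][col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
    return Recording(
        data=data, fs_hz=fs_hz, channel_labels=labels,
        events=pd.DataFrame(cols), attended=attended,
    )


def save_model(results: AttentionDecoderResults, path: str | Path,
               montage: tuple[str, ...] = (), extra_meta: dict | None = None) -> None:
    """Persist a fitted decoder (whitener, weights, bias, lambda) with metadata."""
    path = Path(path)
    meta = {
        "lambda": results.lam,
        "ridge": results.whitener.ridge,
        "scale": results.scale,
        "montage": list(montage),
        **(extra_meta or {}),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("whitening_matrix", data=results.whitener.matrix)
        f.create_dataset("weights", data=results.weights)
        f.attrs["bias"] = results.bias
        f.attrs["meta_json"] = json.dumps(meta, sort_keys=True)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> dict:
    """Load a persisted decoder as a dict (whitener, weights, bias, metadata)."""
    with h5py.File(path, "r") as f:
        out = {
            "whitener": Whitener(
                matrix=f["whitening_matrix"][()],
                ridge=float(json.loads(f.attrs["meta_json"])["ridge"]),
            ),
            "weights": f["weights"][()],
            "bias": float(f.attrs["bias"]),
            "meta": json.loads(f.attrs["meta_json"]),
        }
    return out
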