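"""Epoch container I/O.

The native container is a single HDF5 file::

    /data    float32, trials x channels x samples (microvolt)
    /labels  int16, one class code per trial
    attrs    fs (float), channel_names (string list), format_version (int)

Data is stored float32: EEG amplifiers do not resolve beyond single
precision, and the files halve in size. A delimited-text alternative (one
CSV per trial plus a JSON manifest) exists for hand-built fixtures, and an
optional adapter imports BCI Competition IV-2a GDF sessions through MNE.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .containers import ContinuousRecording, EpochSet
from .exceptions import FormatError

__all__ = [
    "write_container",
    "read_container",
    "write_csv_dir",
    "read_csv_dir",
    "read_gdf_session",
]

FORMAT_VERSION = 1


def write_container(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int16))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["channel_names"] = [str(n) for n in epochs.channel_names]
        f.attrs["format_version"] = FORMAT_VERSION


def read_container(path: str | Path) -> EpochSet:
    """Read an epoch container written by :func:`write_container`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise FormatError(f"unknown container format version {version!r}")
        if "data" not in f or "labels" not in f:
            missing = [k for k in ("data", "labels") if k not in f]
            raise FormatError(f"container missing dataset(s): {missing}")
        data = np.asarray(f["data"], dtype=np.float64)
        labels = np.asarray(f["labels"], dtype=np.int64)
        if data.ndim != 3:
            raise FormatError(f"/data must be 3-dimensional, got shape {data.shape}")
        if labels.shape[0] != data.shape[0]:
            raise FormatError(
                f"/labels length {labels.shape[0]} != {data.shape[0]} trials"
            )
        fs = float(f.attrs["fs"])
        names = [str(n) for n in f.attrs.get("channel_names", [])]
    return EpochSet(data=data, labels=labels, fs=fs, channel_names=names)


def write_csv_dir(epochs: EpochSet, directory: str | Path) -> None:
    """Text fixture format: ``trial_XXX.csv`` (channels x samples) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
        "trials": [],
    }
    for i in range(epochs.n_trials):
        name = f"trial_{i:03d}.csv"
        np.savetxt(directory / name, epochs.data[i], delimiter=",")
        manifest["trials"].append({"file": name, "label": int(epochs.labels[i])})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_csv_dir(directory: str | Path) -> EpochSet:
    """Read the delimited-text fixture written by :func:`write_csv_dir`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    data, labels = [], []
    for entry in manifest["trials"]:
        trial = np.loadtxt(directory / entry["file"], delimiter=",", ndmin=2)
        data.append(trial)
        labels.append(entry["label"])
    if not data:
        raise FormatError("manifest lists no trials")
    return EpochSet(
        data=np.stack(data),
        labels=np.asarray(labels),
        fs=float(manifest["fs"]),
        channel_names=list(manifest.get("channel_names", [])),
    )


#: BCI Competition IV-2a cue annotation codes -> class labels
#: (left hand, right hand, feet, tongue).
_GDF_CUE_CODES = {"769": 0, "770": 1, "771": 2, "772": 3}


def read_gdf_session(path: str | Path) -> ContinuousRecording:
    """Import a BCI Competition IV-2a GDF session (A0xT/A0xE) via MNE.

    Returns the continuous EEG (the 22 scalp channels; EOG dropped) with
    cue events mapped to class codes 0-3. Requires the optional ``mne``
    dependency; the core pipeline never depends on this adapter.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading GDF sessions requires mne (pip install ssafbcsp[gdf])"
        ) from exc

    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if eog:
        raw.drop_channels(eog)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_map = {
        event_id[k]: cls for k, cls in _GDF_CUE_CODES.items() if k in event_id
    }
    marked = [(int(s), code_map[c]) for s, _, c in events if c in code_map]
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return ContinuousRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        events=marked,
        channel_names=list(raw.ch_names),
    )
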