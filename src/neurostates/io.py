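"""Reading and writing recordings, connectivity matrices, and metric tables.

Canonical on-disk form of a recording: a CSV with one row per sample and
one column per channel (header = channel labels), plus a JSON sidecar
(same stem, ``.json``) holding the sampling rate, condition, subject id,
and generator seed if any. EDF files are read through :mod:`mne` when it
is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PLIMatrix
from .montage import MontageSpec, standard_30_channel_montage
from .recording import EEGRecording
from .signal import BandDefinition

__all__ = [
    "write_recording",
    "read_recording",
    "write_pli_matrix",
    "read_pli_matrix",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: EEGRecording, path: str | Path, seed: int | None = None) -> Path:
    """Write a recording as samples x channels CSV plus JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        recording.data.T.astype(np.float32), columns=list(recording.channel_names)
    )
    frame.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "fs": recording.fs,
        "condition": recording.condition,
        "subject_id": recording.subject_id,
        "seed": seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_csv_recording(path: Path, montage: MontageSpec) -> EEGRecording:
    frame = pd.read_csv(path)
    unknown = [c for c in frame.columns if c not in montage.channel_names]
    if unknown:
        raise ValueError(
            f"{path.name}: unknown channel label(s) {unknown}; montage "
            f"defines {list(montage.channel_names)}"
        )
    missing = [c for c in montage.channel_names if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing montage channel(s) {missing}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{path.name}: JSON sidecar {sidecar.name} with the sampling "
            "rate is required for CSV recordings"
        )
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta or meta["fs"] is None:
        raise ValueError(f"{sidecar.name}: sampling rate 'fs' missing")
    data = frame[list(montage.channel_names)].to_numpy(dtype=np.float64).T
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        montage=montage,
        condition=meta.get("condition"),
        subject_id=meta.get("subject_id"),
    )


def _read_edf_recording(path: Path, montage: MontageSpec) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF requires the optional dependency mne "
            "(pip install neurostates[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    unknown = [c for c in raw.ch_names if c not in montage.channel_names]
    if unknown:
        raise ValueError(f"{path.name}: unknown channel label(s) {unknown}")
    raw.reorder_channels([c for c in montage.channel_names if c in raw.ch_names])
    if list(raw.ch_names) != list(montage.channel_names):
        missing = [c for c in montage.channel_names if c not in raw.ch_names]
        raise ValueError(f"{path.name}: missing montage channel(s) {missing}")
    data = raw.get_data() * 1e6  # mne uses volts; recordings are in uV
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]), montage=montage)


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    montage: MontageSpec | None = None,
) -> EEGRecording:
    """Load a recording from CSV (+ JSON sidecar) or EDF.

    Channels are matched to the montage by label; the format defaults to
    the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file {path} does not exist")
    if montage is None:
        montage = standard_30_channel_montage()
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv_recording(path, montage)
    if fmt == "edf":
        return _read_edf_recording(path, montage)
    raise ValueError(f"unknown recording format {fmt!r} (expected csv or edf)")


def write_pli_matrix(matrix: PLIMatrix, path: str | Path) -> Path:
    """Write a PLI matrix as N x N CSV with channel-name header + metadata."""
    path = Path(path)
    names = list(matrix.channel_names) or [
        f"ch{i}" for i in range(matrix.n_channels)
    ]
    pd.DataFrame(matrix.values, index=names, columns=names).to_csv(path)
    meta = {
        "band": {"name": matrix.band.name, "f_lo": matrix.band.f_lo, "f_hi": matrix.band.f_hi},
        "condition": matrix.condition,
        "n_epochs": matrix.n_epochs,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_pli_matrix(path: str | Path) -> PLIMatrix:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar_path(path).read_text())
    band = BandDefinition(**meta["band"])
    return PLIMatrix(
        values=frame.to_numpy(dtype=np.float64),
        band=band,
        condition=meta.get("condition"),
        n_epochs=int(meta.get("n_epochs", 1)),
        channel_names=tuple(frame.columns),
    )
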