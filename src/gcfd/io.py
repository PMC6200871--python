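"""Reading and writing multichannel signal matrices.

On disk a recording is a channels-by-samples matrix — either tab-delimited
text (``.tsv``) or a flat float64 binary dump (``.f64``) — accompanied by a
JSON sidecar with the sampling rate and channel names.  In memory the
package works with ``(n_samples, n_channels)`` arrays; orientation is
swapped on the way through.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_signal_matrix", "load_signal_matrix", "load_eeg_container"]


def save_signal_matrix(
    prefix: str | Path,
    X: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
    fmt: str = "tsv",
) -> Path:
    """Write ``X`` (n_samples, n_channels) as channels x samples plus a
    JSON sidecar; returns the data path."""
    prefix = Path(prefix)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mat = X.T  # channels x samples on disk
    if fmt == "tsv":
        data_path = prefix.with_suffix(".tsv")
        np.savetxt(data_path, mat, delimiter="\t")
    elif fmt == "f64":
        data_path = prefix.with_suffix(".f64")
        mat.astype("<f8").tofile(data_path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    names = channel_names or [f"ch{i}" for i in range(mat.shape[0])]
    if len(names) != mat.shape[0]:
        raise ValueError("channel_names length mismatch")
    sidecar = {
        "fs": float(fs),
        "n_channels": int(mat.shape[0]),
        "n_samples": int(mat.shape[1]),
        "channel_names": names,
        "format": fmt,
        "orientation": "channels_x_samples",
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return data_path


def load_signal_matrix(prefix: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Load a matrix saved by :func:`save_signal_matrix` (or a bare ``.tsv``
    without sidecar, in which case fs must be encoded elsewhere and 1.0 is
    returned).  Returns ``(X (n_samples, n_channels), fs, channel_names)``."""
    prefix = Path(prefix)
    if prefix.suffix in {".tsv", ".f64", ".json"}:
        prefix = prefix.with_suffix("")
    sidecar_path = prefix.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fmt = meta.get("format", "tsv")
        names = meta.get("channel_names")
        fs = float(meta.get("fs", 1.0))
        if fmt == "f64":
            mat = np.fromfile(prefix.with_suffix(".f64"), dtype="<f8")
            mat = mat.reshape(meta["n_channels"], meta["n_samples"])
        else:
            mat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    else:
        mat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        fs = 1.0
        names = None
    names = names or [f"ch{i}" for i in range(mat.shape[0])]
    return mat.T, fs, names


def load_eeg_container(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Thin adapter for standard EEG containers (EDF/BDF/FIF) via MNE.

    Returns the same ``(X (n_samples, n_channels), fs, channel_names)``
    triple as :func:`load_signal_matrix`.  Requires ``mne`` to be
    installed; it is not a dependency of this package.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF/FIF containers requires the optional 'mne' package") from exc
    path = Path(path)
    if path.suffix.lower() == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw(path, preload=True, verbose="error")
    return raw.get_data().T, float(raw.info["sfreq"]), list(raw.ch_names)
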