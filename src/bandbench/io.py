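"""File adapters: the native delimited TimeSeries dialect plus optional
EEGLAB ``.set`` and MATLAB ``.mat`` readers for external datasets."""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError
from .timeseries import TimeSeries

__all__ = ["read_timeseries", "write_timeseries"]


def write_timeseries(x: TimeSeries, path) -> None:
    """Native dialect: ``# fs=<value>`` header, one column per channel."""
    header = [f"# fs={x.fs!r}"]
    if x.labels is not None:
        header.append("# channels=" + ",".join(x.labels))
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, x.samples, delimiter="\t", fmt="%.17g")


def _read_delimited(path) -> TimeSeries:
    fs = None
    labels = None
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("fs="):
                try:
                    fs = float(body[3:])
                except ValueError as exc:
                    raise FormatError(f"unparseable fs header: {line!r}") from exc
            elif body.startswith("channels="):
                labels = tuple(body[len("channels="):].split(","))
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=<value>' header line")
    try:
        data = np.loadtxt(path, skiprows=n_header, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return TimeSeries(data, fs, labels)


def _read_matlab(path, fs_field: str = "samplingRate") -> TimeSeries:
    from scipy.io import loadmat

    try:
        contents = loadmat(path, squeeze_me=True)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: not a readable MATLAB file ({exc})") from exc
    if fs_field not in contents:
        raise FormatError(f"{path}: missing sampling-rate field {fs_field!r}")
    fs = float(np.squeeze(contents[fs_field]))
    data = None
    for key, value in contents.items():
        if key.startswith("__") or key == fs_field:
            continue
        arr = np.asarray(value)
        if arr.ndim in (1, 2) and np.issubdtype(arr.dtype, np.number):
            data = arr
            break
    if data is None:
        raise FormatError(f"{path}: no numeric data array found")
    if data.ndim == 2 and data.shape[0] < data.shape[1]:
        data = data.T  # channels-by-samples convention
    return TimeSeries(data.astype(float), fs)


def _read_eeglab(path) -> TimeSeries:
    """EEGLAB ``.set`` adapter.

    Tries MNE first when available, else falls back to reading the
    underlying MATLAB structure directly.
    """
    try:
        import mne  # optional dependency

        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
        return TimeSeries(raw.get_data().T, float(raw.info["sfreq"]),
                          tuple(raw.ch_names))
    except ImportError:
        pass
    from scipy.io import loadmat

    try:
        contents = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: not a readable .set file ({exc})") from exc
    eeg = contents.get("EEG", None)
    if eeg is None:
        # flat .set files store fields at top level
        if "srate" not in contents or "data" not in contents:
            raise FormatError(f"{path}: no EEG structure / srate field")
        fs, data = float(contents["srate"]), np.asarray(contents["data"])
    else:
        fs, data = float(eeg.srate), np.asarray(eeg.data)
    if data.ndim == 2 and data.shape[0] < data.shape[1]:
        data = data.T
    return TimeSeries(data.astype(float), fs)


def read_timeseries(path, format: str = "delimited") -> TimeSeries:
    """Load a TimeSeries from disk.

    ``format`` is one of ``delimited`` (native dialect), ``matlab_mat``
    (requires a ``samplingRate`` field) or ``eeglab_set``.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if format == "delimited":
        return _read_delimited(path)
    if format == "matlab_mat":
        return _read_matlab(path)
    if format == "eeglab_set":
        return _read_eeglab(path)
    raise FormatError(f"unknown format {format!r}")
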