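"""Readers and writers for the package's array containers.

Real multichannel time series travel as CSV (channels as columns, header row
with labels) or HDF5 (datasets ``/data`` (channels x samples), ``/fs``,
``/labels``).  Complex arrays use paired ``<label>_re`` / ``<label>_im``
columns in CSV and native complex datasets in HDF5.  Reading back a written
file reproduces the values exactly (CSV uses full float repr).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import TFCoefficients, TimeSeriesSet

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_timeseries_hdf5",
    "write_timeseries_hdf5",
    "read_complex_csv",
    "write_complex_csv",
    "read_complex_hdf5",
    "write_complex_hdf5",
    "write_matrix_csv",
    "read_matrix_csv",
]


def write_timeseries_csv(path, ts: TimeSeriesSet) -> None:
    df = pd.DataFrame(ts.data.T, columns=ts.labels)
    with open(path, "w") as fh:
        fh.write(f"# fs={ts.fs!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries_csv(path, fs: float | None = None) -> TimeSeriesSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            fs = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            if fs is None:
                raise ValueError("sampling rate not in file header; pass fs")
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    return TimeSeriesSet(data=df.to_numpy().T, fs=fs, labels=list(df.columns))


def write_timeseries_hdf5(path, ts: TimeSeriesSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("fs", data=ts.fs)
        f.create_dataset("labels", data=np.array(ts.labels, dtype="S"))


def read_timeseries_hdf5(path) -> TimeSeriesSet:
    with h5py.File(path, "r") as f:
        return TimeSeriesSet(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            labels=[s.decode() for s in f["labels"][()]],
        )


def write_complex_csv(path, coeffs: np.ndarray, labels=None) -> None:
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=complex))
    labels = labels or [f"ch{i}" for i in range(coeffs.shape[0])]
    cols = {}
    for lab, row in zip(labels, coeffs):
        cols[f"{lab}_re"] = row.real
        cols[f"{lab}_im"] = row.imag
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_complex_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels = [c[:-3] for c in df.columns if c.endswith("_re")]
    rows = [df[f"{lab}_re"].to_numpy() + 1j * df[f"{lab}_im"].to_numpy() for lab in labels]
    return np.array(rows), labels


def write_complex_hdf5(path, tf: TFCoefficients) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs", data=tf.coeffs)
        f.create_dataset("frequency", data=tf.frequency)
        f.create_dataset("fs", data=tf.fs)
        f.create_dataset("labels", data=np.array(tf.labels, dtype="S"))


def read_complex_hdf5(path) -> TFCoefficients:
    with h5py.File(path, "r") as f:
        return TFCoefficients(
            coeffs=f["coeffs"][()],
            frequency=float(f["frequency"][()]),
            fs=float(f["fs"][()]),
            labels=[s.decode() for s in f["labels"][()]],
        )


def write_matrix_csv(path, matrix: np.ndarray, labels=None, col_labels=None) -> None:
    m = np.atleast_2d(np.asarray(matrix))
    labels = labels or [f"r{i}" for i in range(m.shape[0])]
    if col_labels is None:
        col_labels = labels if len(labels) == m.shape[1] else [f"c{j}" for j in range(m.shape[1])]
    pd.DataFrame(m, index=labels, columns=col_labels).to_csv(path, float_format="%.17g")


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(), list(df.index)
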