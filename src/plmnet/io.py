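"""File I/O: signals, cohort tables, partitions, connectivity matrices.

Two interchangeable signal formats, auto-detected by extension:

* delimited text (``.csv`` / ``.tsv``), one file per subject, one row per
  region, first column the region label, remaining columns samples; the
  sampling rate is stored in a ``# fs=<Hz>`` comment on the first line;
* a single HDF5 container (``.h5`` / ``.hdf5``) holding one dataset per
  subject under ``/signals/<subject_id>`` with ``fs`` and
  ``region_labels`` attributes.

All result CSVs are comma-separated UTF-8 with a header row and ``%.12g``
floats, so reruns of identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signal import SourceTimeSeries

__all__ = ["write_signals_csv", "read_signals_csv", "write_signals_h5",
           "read_signals_h5", "read_subject_signals", "write_cohort_csv",
           "read_cohort_csv", "write_matrix_csv", "read_matrix_csv",
           "write_result_csv", "file_digest"]

FLOAT_FMT = "%.12g"


def write_signals_csv(ts: SourceTimeSeries, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(f"# fs={ts.fs:.12g}\n")
        for lab, row in zip(ts.region_labels, ts.data):
            f.write(lab + "," + ",".join(FLOAT_FMT % v for v in row) + "\n")


def read_signals_csv(path) -> SourceTimeSeries:
    path = Path(path)
    with open(path, encoding="utf-8") as f:
        header = f.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        labels, rows = [], []
        for line in f:
            parts = line.rstrip("\n").split(",")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    return SourceTimeSeries(labels, fs, np.vstack(rows))


def write_signals_h5(signals: dict[str, SourceTimeSeries], path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("signals")
        for sid, ts in signals.items():
            d = grp.create_dataset(sid, data=ts.data)
            d.attrs["fs"] = ts.fs
            d.attrs["region_labels"] = [s.encode() for s in ts.region_labels]


def read_signals_h5(path, subject_id: str | None = None):
    with h5py.File(path, "r") as f:
        grp = f["signals"]
        ids = [subject_id] if subject_id else list(grp)
        out = {}
        for sid in ids:
            d = grp[sid]
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in d.attrs["region_labels"]]
            out[sid] = SourceTimeSeries(labels, float(d.attrs["fs"]), d[()])
    return out[subject_id] if subject_id else out


def read_subject_signals(path, subject_id: str | None = None):
    """Auto-detect the signal format by extension."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_signals_h5(path, subject_id)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        return read_signals_csv(path)
    raise ValueError(f"unrecognized signal file extension: {path.suffix!r}")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cols = ["subject_id", "group", "sex", "age", "updrs3", "disease_duration"]
    cohort[[c for c in cols if c in cohort.columns]].to_csv(
        path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_matrix_csv(labels: list[str], values: np.ndarray, path) -> None:
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, float_format=FLOAT_FMT, lineterminator="\n")


def read_matrix_csv(path):
    df = pd.read_csv(path, index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def write_result_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
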