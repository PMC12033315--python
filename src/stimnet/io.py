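"""File formats: spiral CSV, recording matrices, lead-field TSV, result tables.

Long-format TSV is the universal inter-stage contract; JSON sidecars carry
scalar metadata. Recordings are stored either as plain CSV or as raw
little-endian float64 matrices with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LeadField, MultichannelRecording, SpiralTrace

__all__ = [
    "write_spiral_csv",
    "read_spiral_csv",
    "write_recording",
    "read_recording",
    "write_leadfield_tsv",
    "read_leadfield_tsv",
]

_SPIRAL_COLUMNS = ["t_s", "x_cm", "y_cm"]


def write_spiral_csv(trace: SpiralTrace, path: str | Path) -> None:
    """Write a trace as t_s,x_cm,y_cm CSV plus a .json metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"t_s": trace.t, "x_cm": trace.x, "y_cm": trace.y})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"task": trace.task, "level": trace.level,
            "repeat": trace.repeat, "subject": trace.subject}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_spiral_csv(path: str | Path) -> SpiralTrace:
    """Read a spiral CSV; metadata from the sidecar when present.

    Units cm and seconds are enforced through the header names; non-monotone
    timestamps or non-finite values are reported with their row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:3]) != _SPIRAL_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_SPIRAL_COLUMNS)}, "
            f"got {','.join(map(str, df.columns[:3]))}")
    t = df["t_s"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(df[_SPIRAL_COLUMNS].to_numpy(float)).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-finite value at data row {bad[0] + 1}")
    non_mono = np.flatnonzero(np.diff(t) <= 0)
    if non_mono.size:
        raise ValueError(
            f"{path}: time not strictly increasing at data row {non_mono[0] + 2}")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SpiralTrace(t=t, x=df["x_cm"].to_numpy(float),
                       y=df["y_cm"].to_numpy(float),
                       task=meta.get("task", "self_paced"),
                       level=int(meta.get("level", 0)),
                       repeat=int(meta.get("repeat", 1)),
                       subject=meta.get("subject", "s01"))


def write_recording(rec: MultichannelRecording, path: str | Path,
                    fmt: str = "raw") -> None:
    """Write a recording as raw float64 (+ JSON sidecar) or CSV."""
    path = Path(path)
    if fmt == "raw":
        rec.data.astype("<f8").tofile(path)
        sidecar = {"fs_hz": rec.fs_hz, "labels": list(rec.labels),
                   "n_samples": rec.n_samples, "space": rec.space,
                   "dtype": "<f8"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    elif fmt == "csv":
        df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
        df.insert(0, "fs_hz", [rec.fs_hz] + [np.nan] * (rec.n_samples - 1))
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a raw float64 recording through its JSON sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar.get("dtype", "<f8"))
    labels = tuple(sidecar["labels"])
    data = data.reshape(len(labels), int(sidecar["n_samples"]))
    return MultichannelRecording(data=data, fs_hz=float(sidecar["fs_hz"]),
                                 labels=labels,
                                 space=sidecar.get("space", "sensor"))


def write_leadfield_tsv(lf: LeadField, path: str | Path) -> None:
    df = pd.DataFrame(lf.matrix, index=list(lf.sensor_labels),
                      columns=list(lf.source_labels))
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_leadfield_tsv(path: str | Path) -> LeadField:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LeadField(matrix=df.to_numpy(float),
                     sensor_labels=tuple(df.index.astype(str)),
                     source_labels=tuple(df.columns.astype(str)))
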