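"""Recording container (HDF5) and CSV feature / ECG-finding tables.

The recording container is a single HDF5 file with three groups:

    /grid     channel_ids (string dataset), positions ((n, 2) metres)
    /samples  channels x time Bz matrix in tesla
    /meta     attrs: sampling_rate, id, age, sex, label

Feature tables are plain UTF-8 CSV with "." decimals; angles in degrees,
QRSd in ms, polar distances in pixels — the reporting units of the nine
parameters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .containers import (
    FEATURE_NAMES,
    FormatError,
    MCGFeatures,
    MCGRecording,
    SensorGrid,
    SubjectMeta,
    SubjectRecord,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
    "records_to_frame",
    "frame_to_records",
    "read_ecg_table",
    "write_ecg_table",
]

REQUIRED_COLUMNS = ["id", "age", "sex", "label", *FEATURE_NAMES]


def write_recording(recording: MCGRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grid = f.create_group("grid")
        grid.create_dataset("channel_ids", data=np.array(recording.grid.channel_ids, dtype="S"))
        grid.create_dataset("positions", data=recording.grid.positions)
        f.create_dataset("samples", data=recording.samples)
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = recording.sampling_rate
        meta.attrs["id"] = recording.subject_meta.id
        meta.attrs["age"] = recording.subject_meta.age
        meta.attrs["sex"] = recording.subject_meta.sex
        meta.attrs["label"] = recording.subject_meta.label


def read_recording(path: str | Path) -> MCGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "grid" not in f or "positions" not in f["grid"] or "channel_ids" not in f["grid"]:
            raise FormatError("grid: missing sensor geometry group")
        if "samples" not in f:
            raise FormatError("samples: missing dataset")
        if "meta" not in f or "sampling_rate" not in f["meta"].attrs:
            raise FormatError("sampling_rate: missing from /meta")
        ids = [c.decode() for c in f["grid/channel_ids"][()]]
        grid = SensorGrid(channel_ids=ids, positions=f["grid/positions"][()])
        meta_attrs = f["meta"].attrs
        meta = SubjectMeta(
            id=str(meta_attrs.get("id", "unknown")),
            age=float(meta_attrs.get("age", np.nan)),
            sex=str(meta_attrs.get("sex", "unknown")),
            label=str(meta_attrs.get("label", "unknown")),
        )
        sampling_rate = float(meta_attrs["sampling_rate"])
        samples = f["samples"][()]
    if samples.ndim != 2 or samples.shape[0] != grid.n_channels:
        raise FormatError(
            "samples: shape %s does not match %d channels" % (samples.shape, grid.n_channels)
        )
    return MCGRecording(grid=grid, sampling_rate=sampling_rate, samples=samples, subject_meta=meta)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = [r.as_row() for r in records]
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"feature table missing required columns: {missing}")
    extras_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        try:
            features = MCGFeatures.from_dict({k: float(row[k]) for k in FEATURE_NAMES})
        except (TypeError, ValueError) as exc:
            raise FormatError(f"row id={row['id']!r}: non-numeric or invalid feature ({exc})") from exc
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                label=str(row["label"]),
                features=features,
                extras={c: row[c] for c in extras_cols},
            )
        )
    return records


def write_feature_table(records: Iterable[SubjectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    return frame_to_records(frame)


def export_raster(map_obj, path: str | Path) -> None:
    """Write a FieldMap or PCDMap raster as CSV with an extent header comment.

    FieldMap exports ``pixels``; PCDMap exports the magnitude raster.
    """
    pixels = getattr(map_obj, "pixels", None)
    if pixels is None:
        pixels = map_obj.magnitude
    header = "extent_m=%r instant=%d" % (tuple(map_obj.extent), map_obj.instant)
    np.savetxt(path, pixels, delimiter=",", header=header)


def write_ecg_table(findings: pd.DataFrame, path: str | Path) -> None:
    findings.to_csv(path, index=False)


def read_ecg_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("id", "label"):
        if col not in frame.columns:
            raise FormatError(f"ECG table missing required column: {col}")
    finding_cols = [c for c in frame.columns if c not in ("id", "label")]
    for col in finding_cols:
        vals = set(pd.unique(frame[col].dropna()))
        if not vals <= {0, 1, True, False}:
            raise FormatError(f"ECG finding column {col!r} must be binary 0/1")
    return frame
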