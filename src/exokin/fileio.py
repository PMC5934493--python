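"""TRC marker files and joint-angle CSV files.

TRC is the tab-delimited motion-capture interchange dialect: a
``PathFileType`` row, a metadata key row + value row
(DataRate/CameraRate/NumFrames/NumMarkers/Units/...), a marker-name row
and an ``X#/Y#/Z#`` component row, followed by ``Frame# Time`` data rows.
Files store millimeters; the in-memory containers use meters.
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS


class TRCParseError(SchemaError):
    """Malformed TRC header or data row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_trc(traj: MarkerTrajectory, path) -> None:
    """Write a marker trajectory as a TRC file (Units=mm)."""
    labels = traj.labels
    n = traj.n
    rate = traj.rate if n > 1 else 100.0
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(labels)}\tmm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        comps = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(labels) + 1))
        fh.write("\t\t" + comps + "\n")
        for i in range(n):
            row = [str(i + 1), f"{traj.time[i]:.8f}"]
            for label in labels:
                xyz = traj.data[label][i] * 1000.0  # m -> mm
                row.extend(f"{v:.8f}" for v in xyz)
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> MarkerTrajectory:
    """Read a TRC file into a marker trajectory (meters)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise TRCParseError("file too short for a TRC header", len(lines) + 1)
    if not lines[0].startswith("PathFileType"):
        raise TRCParseError("expected 'PathFileType' row", 1)
    keys = lines[1].split("\t")
    values = lines[2].split("\t")
    if len(values) < len(keys):
        raise TRCParseError("metadata value row shorter than key row", 3)
    meta = dict(zip(keys, values))
    for required in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if required not in meta:
            raise TRCParseError(f"missing metadata field {required!r}", 2)
    units = meta["Units"].strip().lower()
    if units == "mm":
        to_m = 1e-3
    elif units == "m":
        to_m = 1.0
    else:
        raise TRCParseError(f"unsupported Units {meta['Units']!r}", 3)
    n_frames = int(meta["NumFrames"])
    n_markers = int(meta["NumMarkers"])
    name_row = lines[3].split("\t")
    if name_row[0] != "Frame#" or (len(name_row) < 2 or name_row[1] != "Time"):
        raise TRCParseError("expected 'Frame#\\tTime\\t<marker names>' row", 4)
    labels = [c for c in name_row[2:] if c.strip()]
    if len(labels) != n_markers:
        raise TRCParseError(
            f"NumMarkers={n_markers} inconsistent with {len(labels)} label columns", 4
        )
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise TRCParseError(
            f"NumFrames={n_frames} inconsistent with {len(data_lines)} data rows", 6
        )
    time = np.empty(n_frames)
    arrays = {label: np.empty((n_frames, 3)) for label in labels}
    expected_cols = 2 + 3 * n_markers
    for i, line in enumerate(data_lines):
        cells = line.split("\t")
        if len(cells) < expected_cols:
            raise TRCParseError(
                f"expected {expected_cols} columns, found {len(cells)}", 6 + i
            )
        time[i] = float(cells[1])
        for k, label in enumerate(labels):
            arrays[label][i] = [float(c) if c.strip() else np.nan for c in cells[2 + 3 * k : 5 + 3 * k]]
    return MarkerTrajectory(time, {l: a * to_m for l, a in arrays.items()})


def write_angles_csv(traj: JointTrajectory, path, required: bool = True) -> None:
    """Write joint angles (degrees) as ``time,hip_flexion,knee_flexion,ankle_flexion,...``."""
    if required:
        for ch in SAGITTAL_CHANNELS:
            if ch not in traj.channels:
                raise SchemaError(f"missing required channel {ch!r}")
    ordered: List[str] = [c for c in SAGITTAL_CHANNELS if c in traj.channels]
    ordered += [c for c in traj.channels if c not in ordered]
    frame = pd.DataFrame({"time": traj.time, **{c: traj.channels[c] for c in ordered}})
    frame.to_csv(path, index=False)


def read_angles_csv(path, required: bool = True) -> JointTrajectory:
    """Read a joint-angle CSV; validates the required sagittal channels."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse angle CSV {path}: {exc}") from exc
    if "time" not in frame.columns:
        raise SchemaError("angle CSV is missing the 'time' column")
    if required:
        for ch in SAGITTAL_CHANNELS:
            if ch not in frame.columns:
                raise SchemaError(f"angle CSV is missing required column {ch!r}")
    time = frame["time"].to_numpy(dtype=float)
    channels = {c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "time"}
    try:
        return JointTrajectory(time, channels)
    except ValidationError as exc:
        raise ValidationError(f"angle CSV {path}: {exc}") from exc
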