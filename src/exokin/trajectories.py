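"""Time-series containers: joint-angle channels and labeled marker clouds.

Both containers carry a uniformly sampled time base (default 100 Hz).
Angles are degrees; marker coordinates are meters internally (TRC files
on disk use millimeters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np

from .errors import MissingMarkerError, SchemaError, ValidationError

SAGITTAL_CHANNELS = ("hip_flexion", "knee_flexion", "ankle_flexion")

_UNIFORM_TOL = 1e-9


def _check_time(time: np.ndarray) -> np.ndarray:
    time = np.asarray(time, dtype=float).reshape(-1)
    if time.size == 0:
        raise ValidationError("time vector is empty")
    if time.size > 1:
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _UNIFORM_TOL:
            raise ValidationError("time sampling must be uniform within 1e-9 s")
    return time


@dataclass
class JointTrajectory:
    """Named joint-angle channels (degrees) over a uniform time base (s)."""

    time: np.ndarray
    channels: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _check_time(self.time)
        clean: Dict[str, np.ndarray] = {}
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float).reshape(-1)
            if arr.size != self.time.size:
                raise SchemaError(f"channel {name!r} length {arr.size} != time length {self.time.size}")
            clean[name] = arr
        self.channels = clean

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def rate(self) -> float:
        if self.time.size < 2:
            raise ValidationError("rate undefined for a single-sample trajectory")
        return 1.0 / (self.time[1] - self.time[0])

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise SchemaError(f"missing channel {name!r}")
        return self.channels[name]

    def frame(self, i: int) -> Dict[str, float]:
        return {name: float(values[i]) for name, values in self.channels.items()}

    def with_channels(self, extra: Mapping[str, np.ndarray]) -> "JointTrajectory":
        merged = dict(self.channels)
        merged.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
        return JointTrajectory(self.time.copy(), merged)

    def copy(self) -> "JointTrajectory":
        return JointTrajectory(self.time.copy(), {k: v.copy() for k, v in self.channels.items()})


@dataclass
class MarkerTrajectory:
    """Labeled 3D marker positions (m) over a uniform time base (s).

    Every label is present in every frame; occluded samples are NaN and
    are dropped from IK costs frame by frame.
    """

    time: np.ndarray
    data: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _check_time(self.time)
        clean: Dict[str, np.ndarray] = {}
        for label, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(1, 3)
            if arr.shape != (self.time.size, 3):
                raise SchemaError(
                    f"marker {label!r} has shape {arr.shape}, expected ({self.time.size}, 3)"
                )
            clean[label] = arr
        self.data = clean

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def rate(self) -> float:
        if self.time.size < 2:
            raise ValidationError("rate undefined for a single-sample trajectory")
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def labels(self) -> list:
        return list(self.data)

    def marker(self, label: str) -> np.ndarray:
        if label not in self.data:
            raise MissingMarkerError(f"marker {label!r} not in trajectory")
        return self.data[label]

    def frame(self, i: int) -> Dict[str, np.ndarray]:
        return {label: values[i] for label, values in self.data.items()}

    def static_frame(self) -> Dict[str, np.ndarray]:
        """First frame as a plain label -> (3,) mapping (for static trials)."""
        return self.frame(0)

    def subset(self, labels: Iterable[str]) -> "MarkerTrajectory":
        labels = list(labels)
        for label in labels:
            if label not in self.data:
                raise MissingMarkerError(f"marker {label!r} not in trajectory")
        return MarkerTrajectory(self.time.copy(), {l: self.data[l].copy() for l in labels})

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(self.time.copy(), {k: v.copy() for k, v in self.data.items()})


def static_markers_from_mapping(frame: Mapping[str, np.ndarray]) -> MarkerTrajectory:
    """Wrap a single label -> position mapping as a one-frame trajectory."""
    return MarkerTrajectory(np.array([0.0]), {k: np.asarray(v, dtype=float).reshape(1, 3) for k, v in frame.items()})
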