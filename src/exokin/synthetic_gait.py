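"""Synthetic gait, human-exoskeleton relative motion, and marker capture.

No public data accompany the study conditions this package targets, so
this module is the test harness that stands in for the motion-capture
laboratory: it generates smooth periodic sagittal joint-angle profiles
for slow treadmill walking (defaults: 10 s at 100 Hz, one stride every
2 s, ranges typical of 1 km/h gait), derives the exoskeleton motion
from the human motion through a per-joint affine + lag + smooth-noise
soft-tissue surrogate, and synthesizes the corresponding labeled marker
trajectories (12 human skin markers + 5 exoskeleton markers) by forward
kinematics, with seeded attachment jitter and measurement noise.

The soft-tissue surrogate is deliberately phenomenological: real
relative motion arises from strap compliance and skin sliding, which
are measured, not parameterized, in gait laboratories.  The affine
offsets reproduce the calibration-recoverable part of the misalignment;
gains, lags and smooth noise produce the residual part no constant
constraint set can undo.  The default preset places the largest
relative motion at the knee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .body_models import (
    EXO_MARKER_LABELS,
    HUMAN_MARKER_LABELS,
    CoupledModel,
    ScaleFactors,
    apply_scaling,
    build_exo_model,
    build_generic_human,
    couple_models,
)
from .errors import SchemaError, ValidationError
from .fileio import read_angles_csv, read_trc, write_angles_csv, write_trc  # noqa: F401
from .kinematics_core import KinematicModel
from .trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS

#: markers removed before walking with the exoskeleton (occluded by the frame)
MARKERS_REMOVED_WITH_EXO = ("Mk3", "Mk7", "Mk11")

#: per-joint Fourier coefficients: mean (deg) and (amplitude deg, phase rad)
#: harmonics of the stride frequency; shaped for slow (1 km/h) treadmill gait
DEFAULT_FOURIER: Dict[str, Tuple[float, Tuple[Tuple[float, float], ...]]] = {
    "hip_flexion": (7.5, ((16.5, 0.25), (1.5, 1.2))),
    "knee_flexion": (27.0, ((19.0, -2.1), (12.5, 1.3))),
    "ankle_flexion": (-2.5, ((8.0, 0.9), (5.0, 2.4))),
}


@dataclass
class GaitProfileParams:
    """Ground-truth gait profile: duration (s), rate (Hz), cadence (strides/s)."""

    duration: float = 10.0
    rate: float = 100.0
    cadence: float = 0.5
    fourier: Dict[str, Tuple[float, Tuple[Tuple[float, float], ...]]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_FOURIER.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration > 0 and self.rate > 0 and self.cadence > 0):
            raise ValidationError("duration, rate and cadence must all be > 0")


@dataclass
class SoftTissueParams:
    """Per-joint human-to-exoskeleton relative-motion surrogate.

    ``offsets`` (deg) model strap-donning bias, ``gains`` amplitude
    attenuation through compliant fixations, ``lags`` (s) transmission
    delay.  ``attachment_jitter`` (m) drives both the smooth angular
    noise of the exoskeleton motion (through a nominal 0.4 m lever arm)
    and the smooth skin-marker artifact; ``marker_noise`` (m) is white
    measurement noise on every marker sample.
    """

    offsets: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(SAGITTAL_CHANNELS, 0.0))
    gains: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(SAGITTAL_CHANNELS, 1.0))
    lags: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(SAGITTAL_CHANNELS, 0.0))
    attachment_jitter: float = 0.0
    marker_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gains.values()):
            raise ValidationError("gains must be > 0")
        if self.attachment_jitter < 0 or self.marker_noise < 0:
            raise ValidationError("noise standard deviations must be >= 0")


def soft_tissue_preset(name: str, seed: int = 0) -> SoftTissueParams:
    """Named presets: ``none`` (perfect alignment) and ``paper-like``.

    The ``paper-like`` preset puts the largest relative motion at the
    knee, so that the rigid baseline errs most there.
    """
    if name == "none":
        return SoftTissueParams(seed=seed)
    if name == "paper-like":
        # donning bias is a coherent extension settle: the frame rests
        # under-flexed relative to the skeleton at every joint, largest
        # at the knee — which is also what makes the knee the rigid
        # baseline's worst joint
        return SoftTissueParams(
            offsets={"hip_flexion": -1.0, "knee_flexion": -3.0, "ankle_flexion": -2.0},
            gains={"hip_flexion": 0.97, "knee_flexion": 0.92, "ankle_flexion": 0.94},
            lags={"hip_flexion": 0.02, "knee_flexion": 0.03, "ankle_flexion": 0.04},
            attachment_jitter=0.0015,
            marker_noise=0.0005,
            seed=seed,
        )
    raise ValidationError(f"unknown soft-tissue preset {name!r}")


def generate_gait_profile(p: GaitProfileParams) -> JointTrajectory:
    """Smooth periodic sagittal joint angles; deterministic given params."""
    n = int(round(p.duration * p.rate))
    t = np.arange(n) / p.rate
    omega = 2.0 * np.pi * p.cadence
    channels: Dict[str, np.ndarray] = {}
    for name in SAGITTAL_CHANNELS:
        mean, harmonics = p.fourier[name]
        signal = np.full(n, float(mean))
        for k, (amp, phase) in enumerate(harmonics, start=1):
            signal = signal + amp * np.cos(k * omega * t + phase)
        channels[name] = signal
    return JointTrajectory(t, channels)


def _smooth_noise(n: int, rate: float, std: float, rng: np.random.Generator,
                  correlation_s: float = 0.15) -> np.ndarray:
    """Zero-mean band-limited noise with the requested standard deviation."""
    if std == 0.0 or n < 2:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    smooth = gaussian_filter1d(raw, sigma=correlation_s * rate, mode="wrap")
    scale = smooth.std()
    if scale == 0.0:
        return np.zeros(n)
    return std * (smooth - smooth.mean()) / scale


def derive_exo_motion(v_H: JointTrajectory, s: SoftTissueParams) -> JointTrajectory:
    """Exoskeleton joint angles from human angles through the surrogate.

    Per joint ``j``: ``v_R_j(t) = gain_j * v_H_j(t - lag_j) + offset_j +
    smooth noise``; the lag is applied as a periodic shift (the default
    profile holds a whole number of strides).
    """
    rng = np.random.default_rng(s.seed)
    t = v_H.time
    period = t.size * (t[1] - t[0]) if t.size > 1 else 1.0
    noise_std = np.degrees(s.attachment_jitter / 0.4)
    channels: Dict[str, np.ndarray] = {}
    for name in SAGITTAL_CHANNELS:
        v = v_H.channel(name)
        lag = s.lags.get(name, 0.0)
        shifted = v if lag == 0.0 else np.interp(t - lag, t, v, period=period)
        out = s.gains.get(name, 1.0) * shifted + s.offsets.get(name, 0.0)
        if noise_std > 0:
            out = out + _smooth_noise(t.size, v_H.rate if t.size > 1 else 1.0, noise_std, rng)
        channels[name] = out
    return JointTrajectory(t.copy(), channels)


# ----------------------------------------------------------------------
# marker synthesis
# ----------------------------------------------------------------------

def _coupled_q_frame(
    coupled: CoupledModel, v_H: JointTrajectory, v_R: JointTrajectory, i: int
) -> Dict[str, float]:
    q = {name: coupled.static_posture.get(name, 0.0) for name in coupled.base_coords}
    for coord, channel in zip(coupled.human_coords, SAGITTAL_CHANNELS):
        q[coord] = float(v_H.channel(channel)[i])
    for coord, channel in zip(coupled.exo_coords, SAGITTAL_CHANNELS):
        q[coord] = float(v_R.channel(channel)[i])
    return q


def synthesize_marker_data(
    coupled: CoupledModel,
    v_H: JointTrajectory,
    v_R: JointTrajectory,
    s: SoftTissueParams,
    labels: Optional[Sequence[str]] = None,
) -> MarkerTrajectory:
    """Marker capture of the coupled chain: human under ``v_H``, exo under ``v_R``.

    Both chains share the (static) base pose — the treadmill keeps the
    pelvis quasi-stationary.  Human skin markers receive smooth
    attachment jitter; all markers receive white measurement noise.
    """
    if v_H.n != v_R.n:
        raise SchemaError(f"trajectory lengths differ: {v_H.n} vs {v_R.n}")
    if v_H.n > 1 and abs(v_H.rate - v_R.rate) > 1e-9:
        raise SchemaError("trajectory rates differ")
    wanted = list(labels) if labels is not None else list(HUMAN_MARKER_LABELS) + list(EXO_MARKER_LABELS)
    rng = np.random.default_rng(s.seed + 1)  # distinct stream from the angle noise
    n = v_H.n
    rate = v_H.rate if n > 1 else 100.0
    arrays = {label: np.empty((n, 3)) for label in wanted}
    model = coupled.model
    for i in range(n):
        pos = model.marker_positions(_coupled_q_frame(coupled, v_H, v_R, i))
        for label in wanted:
            arrays[label][i] = pos[label]
    human_set = set(HUMAN_MARKER_LABELS)
    for label in wanted:
        if s.attachment_jitter > 0 and label in human_set:
            for axis in range(3):
                arrays[label][:, axis] += _smooth_noise(n, rate, s.attachment_jitter, rng)
        if s.marker_noise > 0:
            arrays[label] += rng.normal(0.0, s.marker_noise, size=(n, 3))
    return MarkerTrajectory(v_H.time.copy(), arrays)


def synthesize_human_walk(
    human: KinematicModel,
    v_H: JointTrajectory,
    base: Mapping[str, float],
    s: SoftTissueParams,
) -> MarkerTrajectory:
    """Marker capture of the human model alone (no device) under ``v_H``.

    ``base`` maps the pelvis free-joint coordinates (e.g.
    ``pelvis_free_ty``) held fixed over the trial.  Skin markers receive
    the same attachment jitter and measurement noise as the coupled
    capture.
    """
    rng = np.random.default_rng(s.seed + 2)
    n = v_H.n
    rate = v_H.rate if n > 1 else 100.0
    labels = [l for seg in human.segments.values() for l in seg.local_markers]
    arrays = {label: np.empty((n, 3)) for label in labels}
    for i in range(n):
        q = dict(base)
        for channel in SAGITTAL_CHANNELS:
            q[channel] = float(v_H.channel(channel)[i])
        pos = human.marker_positions(q)
        for label in labels:
            arrays[label][i] = pos[label]
    for label in labels:
        if s.attachment_jitter > 0:
            for axis in range(3):
                arrays[label][:, axis] += _smooth_noise(n, rate, s.attachment_jitter, rng)
        if s.marker_noise > 0:
            arrays[label] += rng.normal(0.0, s.marker_noise, size=(n, 3))
    return MarkerTrajectory(v_H.time.copy(), arrays)


def synthesize_static_frame(
    model: KinematicModel,
    q: Mapping[str, float],
    labels: Optional[Sequence[str]] = None,
    marker_noise: float = 0.0,
    seed: int = 0,
) -> MarkerTrajectory:
    """One-frame static capture of any model at posture ``q``."""
    pos = model.marker_positions(dict(q))
    wanted = list(labels) if labels is not None else list(pos)
    rng = np.random.default_rng(seed)
    data = {}
    for label in wanted:
        p = pos[label].reshape(1, 3).copy()
        if marker_noise > 0:
            p = p + rng.normal(0.0, marker_noise, size=(1, 3))
        data[label] = p
    return MarkerTrajectory(np.array([0.0]), data)


# ----------------------------------------------------------------------
# full synthetic subject
# ----------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """Everything the laboratory would have produced for one subject."""

    seed: int
    scale: ScaleFactors
    human: KinematicModel
    exo: KinematicModel
    coupled: CoupledModel
    static_no_exo: MarkerTrajectory
    static_with_exo: MarkerTrajectory
    walk_markers: MarkerTrajectory
    v_H: JointTrajectory
    v_R: JointTrajectory
    walk_no_exo: Optional[MarkerTrajectory] = None


def generate_subject(
    seed: int = 0,
    scale_factors: Optional[ScaleFactors] = None,
    gait: Optional[GaitProfileParams] = None,
    soft: Optional[SoftTissueParams] = None,
    drop_removed_markers: bool = True,
) -> SyntheticSubject:
    """Generate one complete synthetic subject recording session.

    Produces the static trial without the exoskeleton (all 12 human
    markers, used for scaling), the static trial wearing it (12 + 5
    markers, used for link adjustment and coupling calibration), and the
    treadmill walk wearing it.  During the walk the trochanter, knee and
    malleolus markers are occluded by the frame and dropped, as in the
    marker protocol the generator emulates.
    """
    rng = np.random.default_rng(seed)
    gait = gait or GaitProfileParams()
    soft = soft or SoftTissueParams(seed=int(rng.integers(0, 2**31 - 1)))
    if scale_factors is None:
        f = rng.uniform(0.92, 1.08, size=3)
        scale_factors = ScaleFactors(femur=f[0], tibia=f[1], foot=f[2])

    human = apply_scaling(build_generic_human(), scale_factors)
    lf = human.segments["femur"].length
    lt = human.segments["tibia"].length
    exo = build_exo_model(thigh=lf, shank=lt)

    hip_y = lf + lt + 0.10  # hip height over ground in upright standing
    base = {"ty": hip_y + 0.07}

    # static trial without the exoskeleton: human model standing upright
    q_static_human = {f"pelvis_free_{k}": v for k, v in base.items()}
    static_no_exo = synthesize_static_frame(
        human, q_static_human, marker_noise=soft.marker_noise, seed=seed + 101
    )

    # coupled truth model; exoskeleton rests at the strap-donning offsets
    static_posture = {f"corset_free_{k}": v for k, v in base.items()}
    for coord, channel in zip(
        ("exo_hip_flexion", "exo_knee_flexion", "exo_ankle_flexion"), SAGITTAL_CHANNELS
    ):
        static_posture[coord] = soft.offsets.get(channel, 0.0)
    coupled = couple_models(human, exo, static_posture=static_posture)

    static_with_exo = synthesize_static_frame(
        coupled.model,
        coupled.static_posture,
        labels=list(HUMAN_MARKER_LABELS) + list(EXO_MARKER_LABELS),
        marker_noise=soft.marker_noise,
        seed=seed + 202,
    )

    v_H = generate_gait_profile(gait)
    v_R = derive_exo_motion(v_H, soft)
    walk = synthesize_marker_data(coupled, v_H, v_R, soft)
    if drop_removed_markers:
        walk = walk.subset([l for l in walk.labels if l not in MARKERS_REMOVED_WITH_EXO])
    walk_no_exo = synthesize_human_walk(human, v_H, q_static_human, soft)
    return SyntheticSubject(
        seed=seed,
        scale=scale_factors,
        human=human,
        exo=exo,
        coupled=coupled,
        static_no_exo=static_no_exo,
        static_with_exo=static_with_exo,
        walk_markers=walk,
        v_H=v_H,
        v_R=v_R,
        walk_no_exo=walk_no_exo,
    )
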