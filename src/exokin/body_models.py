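"""Human and exoskeleton model construction, subject scaling and coupling.

The human lower limb is a four-segment chain (pelvis, femur, tibia,
foot) with a 6-DOF base joint at the pelvis and sagittal revolute
flexion joints at the hip, knee and ankle.  Hip internal/external
rotation and ab-adduction are carried as frozen constants on the hip
joint: they are solved once at the static calibration posture and enter
the forward kinematics as fixed rotations, never as coordinates.  The
exoskeleton is a sagittal-plane device: corset (trunk attachment), thigh
bar, shank bar and sole, with three parallel-axis revolute joints whose
link lengths are adjustable.

The 12-marker human protocol (three foot markers on the calcaneus and
the fifth/first metatarsals, the lateral malleolus, a three-marker shank
cluster, the lateral knee, a three-marker thigh cluster, and the greater
trochanter) and the 5-marker exoskeleton set (hip/knee/ankle motor
centers plus thigh/shank bar midpoints) are attached in segment-local
frames.  Only the right limb is modeled and scaled.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    ImplausibleStaticPoseError,
    MissingMarkerError,
    ModelDefinitionError,
    ValidationError,
)
from .kinematics_core import (
    Joint,
    KinematicModel,
    RigidTransform,
    Segment,
    set_frozen_hip_angles,
)
from .trajectories import MarkerTrajectory

#: default anthropometry (m): round mid-range adult values, all overridable
DEFAULT_SEGMENT_LENGTHS: Dict[str, float] = {
    "pelvis": 0.20,
    "femur": 0.40,
    "tibia": 0.38,
    "foot": 0.25,
}

#: right hip center in the pelvis frame (m): below and lateral of the origin
HIP_OFFSET_PELVIS = np.array([0.0, -0.07, 0.09])
#: exoskeleton hip axis in the corset frame (m): lateral of the human hip
EXO_HIP_OFFSET_CORSET = np.array([0.0, -0.07, 0.14])

HUMAN_MARKER_LABELS = tuple(f"Mk{i}" for i in range(12))
EXO_MARKER_LABELS = ("ExoHip", "ExoKnee", "ExoAnkle", "ExoThighMid", "ExoShankMid")

#: marker-pair definitions for longitudinal scaling (measured over model)
SCALE_PAIRS: Dict[str, Tuple[str, str]] = {
    "femur": ("Mk11", "Mk7"),
    "tibia": ("Mk7", "Mk3"),
    "foot": ("Mk2", "Mk1"),
}


def default_marker_layout(lengths: Mapping[str, float]) -> Dict[str, Dict[str, np.ndarray]]:
    """Segment-local marker coordinates (m) for the 12-marker protocol.

    Scaling pairs (trochanter-knee, knee-malleolus, metatarsal pair) are
    laid out so that each pair spans exactly the longitudinal axis of
    its segment; cluster markers sit at plausible skin positions.
    """
    lf, lt = lengths["femur"], lengths["tibia"]
    return {
        "pelvis": {},
        "femur": {
            "Mk11": np.array([0.0, 0.0, 0.06]),       # greater trochanter
            "Mk8": np.array([0.02, -0.14, 0.055]),    # thigh cluster
            "Mk9": np.array([-0.015, -0.20, 0.065]),
            "Mk10": np.array([0.02, -0.26, 0.05]),
            "Mk7": np.array([0.0, -lf, 0.06]),        # lateral knee
        },
        "tibia": {
            "Mk4": np.array([0.015, -0.11, 0.05]),    # shank cluster
            "Mk5": np.array([-0.015, -0.17, 0.055]),
            "Mk6": np.array([0.01, -0.23, 0.045]),
            "Mk3": np.array([0.0, -lt, 0.06]),        # lateral malleolus
        },
        "foot": {
            "Mk0": np.array([-0.06, -0.07, 0.01]),    # calcaneus
            "Mk1": np.array([0.10, -0.07, 0.03]),     # fifth metatarsal
            "Mk2": np.array([0.22, -0.07, 0.03]),     # first metatarsal
        },
    }


GenericHumanModel = KinematicModel
ExoModel = KinematicModel


def build_generic_human(
    lengths: Optional[Mapping[str, float]] = None,
    marker_layout: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None,
    frozen_hip_rotation: float = 0.0,
    frozen_hip_adduction: float = 0.0,
) -> GenericHumanModel:
    """Generic human right-lower-limb model with the 12-marker set.

    Three estimable sagittal DOFs (hip/knee/ankle flexion) plus the
    6-DOF pelvis base; hip rotation/ab-adduction enter as constants.
    """
    L = dict(DEFAULT_SEGMENT_LENGTHS)
    if lengths:
        L.update(lengths)
    for name, val in L.items():
        if not val > 0:
            raise ModelDefinitionError(f"length {name!r} must be > 0")
    layout = marker_layout if marker_layout is not None else default_marker_layout(L)
    present = {label for seg in layout.values() for label in seg}
    missing = [m for m in HUMAN_MARKER_LABELS if m not in present]
    if missing:
        raise ModelDefinitionError(f"marker layout is missing {missing}")

    segments = [
        Segment("pelvis", L["pelvis"], dict(layout.get("pelvis", {}))),
        Segment("femur", L["femur"], dict(layout.get("femur", {}))),
        Segment("tibia", L["tibia"], dict(layout.get("tibia", {}))),
        Segment("foot", L["foot"], dict(layout.get("foot", {})), longitudinal_axis=0),
    ]
    hip = Joint(
        "hip_flexion",
        "revolute_z",
        "pelvis",
        "femur",
        parent_attach=RigidTransform.from_translation(HIP_OFFSET_PELVIS),
        limits=(-30.0, 140.0),
    )
    set_frozen_hip_angles(hip, frozen_hip_rotation, frozen_hip_adduction)
    joints = [
        Joint("pelvis_free", "free6", "ground", "pelvis"),
        hip,
        Joint(
            "knee_flexion",
            "revolute_z",
            "femur",
            "tibia",
            parent_attach=RigidTransform.from_translation([0.0, -L["femur"], 0.0]),
            limits=(-10.0, 150.0),
        ),
        Joint(
            "ankle_flexion",
            "revolute_z",
            "tibia",
            "foot",
            parent_attach=RigidTransform.from_translation([0.0, -L["tibia"], 0.0]),
            limits=(-60.0, 60.0),
        ),
    ]
    return KinematicModel(segments, joints)


# ----------------------------------------------------------------------
# subject scaling
# ----------------------------------------------------------------------

@dataclass
class ScaleFactors:
    """Longitudinal scaling factors (measured/model marker-pair distance)."""

    femur: float
    tibia: float
    foot: float
    manual_overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("femur", "tibia", "foot"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"scale factor {name!r} must be finite and > 0")
        for name, v in self.manual_overrides.items():
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"manual override {name!r} must be finite and > 0")

    def factor(self, segment: str) -> float:
        """Effective factor for a segment; manual overrides take precedence."""
        if segment in self.manual_overrides:
            return self.manual_overrides[segment]
        return getattr(self, segment)


StaticFrame = Union[MarkerTrajectory, Mapping[str, np.ndarray]]


def _as_frame(static_markers: StaticFrame) -> Dict[str, np.ndarray]:
    if isinstance(static_markers, MarkerTrajectory):
        return static_markers.static_frame()
    return {k: np.asarray(v, dtype=float).reshape(3) for k, v in static_markers.items()}


def compute_scale_factors(
    static_markers: StaticFrame, model: GenericHumanModel
) -> ScaleFactors:
    """Marker-pair scaling factors from a static (no exoskeleton) trial.

    femur from trochanter-knee (Mk11-Mk7), tibia from knee-malleolus
    (Mk7-Mk3), foot from the metatarsal pair (Mk2-Mk1); each factor is
    the measured distance divided by the model distance at neutral pose.
    """
    frame = _as_frame(static_markers)
    model_pos = model.marker_positions(model.zero_coordinates())
    out: Dict[str, float] = {}
    for segment, (a, b) in SCALE_PAIRS.items():
        for label in (a, b):
            if label not in frame:
                raise MissingMarkerError(f"static frame is missing marker {label!r}")
        d_meas = float(np.linalg.norm(frame[a] - frame[b]))
        d_model = float(np.linalg.norm(model_pos[a] - model_pos[b]))
        if d_model <= 0:
            raise ModelDefinitionError(f"degenerate model distance for pair {a}-{b}")
        out[segment] = d_meas / d_model
    return ScaleFactors(**out)


def apply_scaling(model: GenericHumanModel, f: ScaleFactors) -> GenericHumanModel:
    """Scale segments along their longitudinal axes.

    For each of femur/tibia/foot the segment length, the longitudinal
    component of its local marker offsets and the longitudinal component
    of its child-joint attachment are multiplied by the factor;
    non-longitudinal offsets are untouched.  Topology and marker labels
    are preserved.
    """
    scaled = copy.deepcopy(model)
    for name in ("femur", "tibia", "foot"):
        factor = f.factor(name)
        seg = scaled.segments[name]
        axis = seg.longitudinal_axis
        seg.length *= factor
        for local in seg.local_markers.values():
            local[axis] *= factor
        for joint in scaled.joints:
            if joint.parent == name:
                t = joint.parent_attach.translation.copy()
                t[axis] *= factor
                joint.parent_attach = RigidTransform(joint.parent_attach.rotation, t)
    return KinematicModel(list(scaled.segments.values()), scaled.joints)


# ----------------------------------------------------------------------
# exoskeleton
# ----------------------------------------------------------------------

def build_exo_model(
    thigh: float = 0.40, shank: float = 0.38, sole: float = 0.25
) -> ExoModel:
    """Sagittal three-revolute exoskeleton leg with its 5-marker set.

    All revolute axes are parallel (Z).  The hip motor marker sits on
    the corset-mounted motor housing; knee/ankle motor markers and the
    bar midpoints sit on the thigh and shank links at a common lateral
    offset.
    """
    for name, val in (("thigh", thigh), ("shank", shank), ("sole", sole)):
        if not val > 0:
            raise ModelDefinitionError(f"exo link {name!r} must be > 0")
    lateral = 0.03  # marker offset from the link axis, equal on all links
    segments = [
        Segment("corset", 0.25, {"ExoHip": EXO_HIP_OFFSET_CORSET + [0.0, 0.0, lateral]}),
        Segment(
            "exo_thigh",
            thigh,
            {
                "ExoKnee": np.array([0.0, -thigh, lateral]),
                "ExoThighMid": np.array([0.0, -thigh / 2, lateral]),
            },
        ),
        Segment(
            "exo_shank",
            shank,
            {
                "ExoAnkle": np.array([0.0, -shank, lateral]),
                "ExoShankMid": np.array([0.0, -shank / 2, lateral]),
            },
        ),
        Segment("exo_sole", sole, {}, longitudinal_axis=0),
    ]
    joints = [
        Joint("corset_free", "free6", "ground", "corset"),
        Joint(
            "exo_hip_flexion",
            "revolute_z",
            "corset",
            "exo_thigh",
            parent_attach=RigidTransform.from_translation(EXO_HIP_OFFSET_CORSET),
            limits=(-30.0, 140.0),
        ),
        Joint(
            "exo_knee_flexion",
            "revolute_z",
            "exo_thigh",
            "exo_shank",
            parent_attach=RigidTransform.from_translation([0.0, -thigh, 0.0]),
            limits=(-10.0, 150.0),
        ),
        Joint(
            "exo_ankle_flexion",
            "revolute_z",
            "exo_shank",
            "exo_sole",
            parent_attach=RigidTransform.from_translation([0.0, -shank, 0.0]),
            limits=(-60.0, 60.0),
        ),
    ]
    return KinematicModel(segments, joints)


def adjust_exo_links(exo: ExoModel, static_markers_with_exo: StaticFrame) -> ExoModel:
    """Set the extensible link lengths from static marker heights.

    The thigh link becomes height(Mk11) - height(Mk7) and the shank link
    height(Mk7) - height(Mk3), so the exoskeleton hip/knee/ankle axes
    sit at the heights of the subject's trochanter, knee and malleolus
    markers in the static upright trial worn with the device.  "Height"
    is the world Y coordinate.  Sole geometry is unchanged.
    """
    frame = _as_frame(static_markers_with_exo)
    for label in ("Mk11", "Mk7", "Mk3"):
        if label not in frame:
            raise MissingMarkerError(f"static frame is missing marker {label!r}")
    y11, y7, y3 = frame["Mk11"][1], frame["Mk7"][1], frame["Mk3"][1]
    if not (y11 > y7 > y3):
        raise ImplausibleStaticPoseError(
            f"marker heights not ordered Mk11 > Mk7 > Mk3: {y11:.3f}, {y7:.3f}, {y3:.3f}"
        )
    return build_exo_model(
        thigh=float(y11 - y7), shank=float(y7 - y3), sole=exo.segments["exo_sole"].length
    )


# ----------------------------------------------------------------------
# coupling
# ----------------------------------------------------------------------

@dataclass
class CoupledModel:
    """Merged human-exoskeleton chain plus its static calibration state.

    The pelvis is welded to the corset (one shared 6-DOF base), with the
    weld translation chosen so the human and exoskeleton hip rotation
    centers coincide in the anterior-posterior direction (and in height,
    a documented assumption).  ``static_posture`` maps every coordinate
    to its value at the static calibration; the hip rotation/ab-adduction
    solved there stay frozen for all subsequent estimation.
    """

    model: KinematicModel
    pelvis_corset_offset: RigidTransform
    static_posture: Dict[str, float] = field(default_factory=dict)
    frozen_hip: Tuple[float, float] = (0.0, 0.0)
    static_residual_rms: float = 0.0
    static_ok: bool = True
    human_coords: Tuple[str, ...] = ("hip_flexion", "knee_flexion", "ankle_flexion")
    exo_coords: Tuple[str, ...] = ("exo_hip_flexion", "exo_knee_flexion", "exo_ankle_flexion")
    pelvis_segment: str = "pelvis"
    corset_segment: str = "corset"
    tibia_segment: str = "tibia"
    foot_segment: str = "foot"
    exo_shank_segment: str = "exo_shank"
    exo_sole_segment: str = "exo_sole"

    @property
    def base_coords(self) -> Tuple[str, ...]:
        return tuple(f"corset_free_{s}" for s in ("tx", "ty", "tz", "rx", "ry", "rz"))


def couple_models(
    human: GenericHumanModel,
    exo: ExoModel,
    pelvis_lateral_offset: float = 0.0,
    static_posture: Optional[Mapping[str, float]] = None,
) -> CoupledModel:
    """Merge a human and an exoskeleton model into one chain.

    The human base joint is dropped; the pelvis hangs off the corset
    through a weld whose translation aligns the hip centers in X
    (anterior-posterior) and Y (height).  No static solve is performed;
    :func:`assemble_coupled` wraps this with the calibration IK.
    """
    human = copy.deepcopy(human)
    exo = copy.deepcopy(exo)
    p_hip = human.joint("hip_flexion").parent_attach.translation
    c_hip = exo.joint("exo_hip_flexion").parent_attach.translation
    t_off = np.array([c_hip[0] - p_hip[0], c_hip[1] - p_hip[1], pelvis_lateral_offset])
    weld = Joint(
        "pelvis_corset_weld",
        "weld",
        "corset",
        "pelvis",
        parent_attach=RigidTransform.from_translation(t_off),
    )
    segments = list(exo.segments.values()) + list(human.segments.values())
    joints = list(exo.joints) + [weld] + [
        j for j in human.joints if j.kind != "free6"
    ]
    merged = KinematicModel(segments, joints)
    posture = dict(static_posture or {})
    for name in merged.coordinate_names:
        posture.setdefault(name, 0.0)
    return CoupledModel(
        model=merged,
        pelvis_corset_offset=RigidTransform.from_translation(t_off),
        static_posture=posture,
    )


def calibrate_sole_tracking_marker(
    coupled: CoupledModel, static_frame: Mapping[str, np.ndarray]
) -> None:
    """Attach virtual sole-tracking anchors from the strapped foot.

    The sole carries no physical marker; because the foot is strapped
    onto it, the calcaneus marker and the calcaneus/fifth-metatarsal
    midpoint are used to track the sole orientation (and hence the
    exoskeleton ankle angle).  Their static-posture positions expressed
    in the sole frame become the local anchors ``SoleHeel`` and
    ``Mk14``.
    """
    if "Mk0" not in static_frame or "Mk1" not in static_frame:
        raise MissingMarkerError("sole calibration requires markers Mk0 and Mk1")
    heel = np.asarray(static_frame["Mk0"], dtype=float).reshape(3)
    midpoint = 0.5 * (heel + np.asarray(static_frame["Mk1"], dtype=float).reshape(3))
    poses = coupled.model.fk_raw(coupled.static_posture, check=False)
    r, t = poses[coupled.exo_sole_segment]
    sole = coupled.model.segments[coupled.exo_sole_segment]
    sole.local_markers["SoleHeel"] = r.T @ (heel - t)
    sole.local_markers["Mk14"] = r.T @ (midpoint - t)


def assemble_coupled(
    human: GenericHumanModel,
    exo: ExoModel,
    static_markers_with_exo: StaticFrame,
    settings=None,
    pelvis_lateral_offset: float = 0.0,
    static_residual_threshold: float = 0.005,
    estimate_hip_orientation: bool = True,
) -> CoupledModel:
    """Couple the scaled human with the adjusted exoskeleton and calibrate.

    The static (exoskeleton worn) capture is solved by marker IK over
    the base translation, the three human flexion angles, the
    exoskeleton hip/knee angles and — once only — the hip
    rotation/ab-adduction, which are then frozen.  The base rotation is
    fixed at zero: the static trial is an upright stand in an
    axis-aligned capture frame, and with no pelvis or corset markers a
    free base rotation would be indeterminate against a common shift of
    both hip angles.  The exoskeleton ankle is likewise unobservable at
    this stage (the sole carries no marker) and stays at zero; the sole
    anchor calibration absorbs its true donning angle consistently.  A
    residual RMS above ``static_residual_threshold`` (m) leaves
    ``static_ok`` False and emits a warning, mirroring the manual
    revision step a poor initialization would require in practice.
    """
    from .ik_engine import IKSettings, fit_frame  # deferred: avoids an import cycle

    coupled = couple_models(human, exo, pelvis_lateral_offset)
    frame = _as_frame(static_markers_with_exo)
    model = coupled.model
    free = (
        list(coupled.base_coords[:3])
        + list(coupled.human_coords)
        + [coupled.exo_coords[0], coupled.exo_coords[1]]
    )

    # initial guess for the base from the trochanter marker position
    x0 = np.zeros(len(free) + (2 if estimate_hip_orientation else 0))
    if "Mk11" in frame:
        mk11 = np.asarray(frame["Mk11"], dtype=float)
        t_off = coupled.pelvis_corset_offset.translation
        x0[0] = mk11[0]
        x0[1] = mk11[1] + 0.07
        x0[2] = mk11[2] - 0.06 - HIP_OFFSET_PELVIS[2] - t_off[2]

    hip_joint = model.joint("hip_flexion") if estimate_hip_orientation else None
    x, rms, converged, extras = fit_frame(
        model, frame, free, x0, settings or IKSettings(), hip_joint=hip_joint
    )
    posture = {name: float(val) for name, val in zip(free, x)}
    for name in model.coordinate_names:
        posture.setdefault(name, 0.0)
    coupled.static_posture = posture
    if extras is not None:
        coupled.frozen_hip = extras
    coupled.static_residual_rms = rms
    coupled.static_ok = bool(converged and rms <= static_residual_threshold)
    if not coupled.static_ok:
        warnings.warn(
            f"static calibration residual RMS {rms * 1000:.2f} mm exceeds "
            f"{static_residual_threshold * 1000:.2f} mm: posture may need manual revision",
            stacklevel=2,
        )
    if "Mk0" in frame and "Mk1" in frame:
        calibrate_sole_tracking_marker(coupled, frame)
    return coupled
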