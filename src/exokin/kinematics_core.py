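"""Rigid-body transform algebra, kinematic trees and forward kinematics.

Conventions used throughout the package
---------------------------------------
* Right-handed frames with **X anterior, Y up, Z to the subject's right**.
  Each segment frame has its origin at the proximal joint and its Y axis
  running from the distal end toward the proximal end, so a segment of
  length ``L`` has its distal joint at local ``(0, -L, 0)``.
* Revolute joints rotate about the local **Z** axis of the joint frame.
  Positive rotation follows the right-hand rule about +Z, which makes
  hip/knee/ankle flexion positive for the right leg.  The neutral angle
  (0 deg) is the configuration in which the Y axes of the two adjacent
  segments are parallel.
* All public angle values are **degrees**; radians appear only inside
  trigonometric helpers.  Angles are reported in ``(-180, 180]`` with the
  branch cut resolved to +180.
* ``free6`` joints use coordinate order ``(tx, ty, tz, rx, ry, rz)`` with
  intrinsic XYZ Euler rotations (``R = Rx @ Ry @ Rz``); translations are
  meters, rotations degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    GeometryViolationError,
    InvalidTransformError,
    ModelDefinitionError,
)

GROUND = "ground"
FREE6_SUFFIXES = ("tx", "ty", "tz", "rx", "ry", "rz")

_ORTHO_TOL = 1e-9
_I3 = np.eye(3)


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle into (-180, 180], ties at the cut resolved to +180."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: 3x3 rotation (orthonormal, det +1) + translation (m)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.array(self.rotation, dtype=float).reshape(3, 3)
        tra = np.array(self.translation, dtype=float).reshape(3)
        if np.max(np.abs(rot.T @ rot - _I3)) > _ORTHO_TOL:
            raise InvalidTransformError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(rot) - 1.0) > _ORTHO_TOL:
            raise InvalidTransformError("rotation determinant differs from +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(_I3.copy(), np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(_I3.copy(), np.asarray(t, dtype=float))

    @classmethod
    def rot_x(cls, deg: float) -> "RigidTransform":
        return cls(_rot_x(deg), np.zeros(3))

    @classmethod
    def rot_y(cls, deg: float) -> "RigidTransform":
        return cls(_rot_y(deg), np.zeros(3))

    @classmethod
    def rot_z(cls, deg: float) -> "RigidTransform":
        return cls(_rot_z(deg), np.zeros(3))

    # -- algebra ------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self ∘ other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point ``(3,)`` or a stack ``(N, 3)`` through the transform."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            return self.rotation @ pts + self.translation
        return pts @ self.rotation.T + self.translation

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_close(self, other: "RigidTransform", tol: float = 1e-12) -> bool:
        return (
            np.max(np.abs(self.rotation - other.rotation)) <= tol
            and np.max(np.abs(self.translation - other.translation)) <= tol
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Compose two transforms; the result applies ``b`` then ``a``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


@dataclass
class Segment:
    """Rigid segment with labeled marker points in its local frame.

    ``longitudinal_axis`` is the local axis index (0=X, 1=Y, 2=Z) along
    which the segment is scaled; it is Y for long bones and X for the
    foot, whose anatomical long axis points anteriorly.
    """

    name: str
    length: float
    local_markers: Dict[str, np.ndarray] = field(default_factory=dict)
    longitudinal_axis: int = 1

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ModelDefinitionError(f"segment {self.name!r}: length must be > 0")
        if self.longitudinal_axis not in (0, 1, 2):
            raise ModelDefinitionError("longitudinal_axis must be 0, 1 or 2")
        self.local_markers = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.local_markers.items()
        }


@dataclass
class Joint:
    """Connection between a parent and a child segment.

    kinds
    -----
    ``revolute_z``
        One angular coordinate (degrees) rotating about the joint Z axis.
    ``weld``
        Zero coordinates; the attachment transforms fix the child rigidly.
    ``free6``
        Six coordinates ``(tx, ty, tz, rx, ry, rz)``; used only for the
        base (ground to pelvis/corset) connection.

    ``fixed_rotation`` is an optional constant rotation applied after the
    coordinate motion; the human hip uses it to carry the frozen hip
    internal/external rotation and ab-adduction angles, which enter the
    forward kinematics as constants rather than coordinates.
    """

    name: str
    kind: str
    parent: str
    child: str
    parent_attach: RigidTransform = field(default_factory=RigidTransform.identity)
    child_attach: RigidTransform = field(default_factory=RigidTransform.identity)
    limits: Optional[Tuple[float, float]] = None
    fixed_rotation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("revolute_z", "weld", "free6"):
            raise ModelDefinitionError(f"unknown joint kind {self.kind!r}")
        if self.fixed_rotation is not None:
            self.fixed_rotation = np.asarray(self.fixed_rotation, dtype=float).reshape(3, 3)

    @property
    def coordinate_names(self) -> Tuple[str, ...]:
        if self.kind == "revolute_z":
            return (self.name,)
        if self.kind == "free6":
            return tuple(f"{self.name}_{s}" for s in FREE6_SUFFIXES)
        return ()


def set_frozen_hip_angles(joint: Joint, rotation_deg: float, adduction_deg: float) -> None:
    """Install frozen hip rotation (about Y) and ab-adduction (about X).

    Applied after the flexion coordinate: ``Rz(flex) @ Ry(rot) @ Rx(add)``.
    """
    joint.fixed_rotation = _rot_y(rotation_deg) @ _rot_x(adduction_deg)
    joint.frozen_rotation_deg = rotation_deg  # type: ignore[attr-defined]
    joint.frozen_adduction_deg = adduction_deg  # type: ignore[attr-defined]


class KinematicModel:
    """Tree of rigid segments rooted at the ground frame.

    The joint graph must be a connected tree: every segment is the child
    of exactly one joint and exactly one joint hangs off ``ground``.
    Closed loops never live inside a model; they arise only through the
    human-exoskeleton coupling constraints.
    """

    def __init__(self, segments: Sequence[Segment], joints: Sequence[Joint]):
        self.segments: Dict[str, Segment] = {}
        for seg in segments:
            if seg.name in self.segments or seg.name == GROUND:
                raise ModelDefinitionError(f"duplicate or reserved segment name {seg.name!r}")
            self.segments[seg.name] = seg
        self.joints: List[Joint] = list(joints)
        self._validate_tree()
        self._order = self._topological_order()
        # global marker-label uniqueness (needed for marker-based IK)
        seen: Dict[str, str] = {}
        for seg in self.segments.values():
            for label in seg.local_markers:
                if label in seen:
                    raise ModelDefinitionError(
                        f"marker {label!r} appears on both {seen[label]!r} and {seg.name!r}"
                    )
                seen[label] = seg.name

    # -- structure ----------------------------------------------------
    def _validate_tree(self) -> None:
        children = [j.child for j in self.joints]
        if len(set(children)) != len(children):
            raise ModelDefinitionError("a segment is the child of more than one joint")
        if set(children) != set(self.segments):
            raise ModelDefinitionError("every segment must be the child of exactly one joint")
        for j in self.joints:
            if j.parent != GROUND and j.parent not in self.segments:
                raise ModelDefinitionError(f"joint {j.name!r}: unknown parent {j.parent!r}")
        roots = [j for j in self.joints if j.parent == GROUND]
        if len(roots) != 1:
            raise ModelDefinitionError("exactly one joint must attach the tree to ground")

    def _topological_order(self) -> List[Joint]:
        by_parent: Dict[str, List[Joint]] = {}
        for j in self.joints:
            by_parent.setdefault(j.parent, []).append(j)
        order: List[Joint] = []
        stack = [GROUND]
        while stack:
            parent = stack.pop(0)
            for j in by_parent.get(parent, []):
                order.append(j)
                stack.append(j.child)
        if len(order) != len(self.joints):
            raise ModelDefinitionError("joint graph is not a connected tree")
        return order

    @property
    def coordinate_names(self) -> List[str]:
        names: List[str] = []
        for j in self._order:
            names.extend(j.coordinate_names)
        return names

    def zero_coordinates(self) -> Dict[str, float]:
        return {name: 0.0 for name in self.coordinate_names}

    # -- forward kinematics -------------------------------------------
    def _check_q(self, q: Mapping[str, float]) -> None:
        known = set(self.coordinate_names)
        for name in q:
            if name not in known:
                raise ConfigurationError(f"unknown coordinate {name!r}")

    def fk_raw(self, q: Mapping[str, float], check: bool = True) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Fast forward kinematics returning ``{segment: (R, t)}`` tuples.

        Missing coordinates default to zero; unknown names raise.  This
        unvalidated path is the hot loop used by the IK solvers.
        """
        if check:
            self._check_q(q)
        poses: Dict[str, Tuple[np.ndarray, np.ndarray]] = {GROUND: (_I3, np.zeros(3))}
        for j in self._order:
            pr, pt = poses[j.parent]
            pa_r, pa_t = j.parent_attach.rotation, j.parent_attach.translation
            if j.kind == "revolute_z":
                val = q.get(j.name, 0.0)
                if j.limits is not None and not (j.limits[0] <= val <= j.limits[1]):
                    warnings.warn(
                        f"coordinate {j.name!r}={val:.2f} deg outside limits {j.limits}",
                        stacklevel=2,
                    )
                motion_r = _rot_z(val)
                motion_t = np.zeros(3)
            elif j.kind == "free6":
                vals = [q.get(f"{j.name}_{s}", 0.0) for s in FREE6_SUFFIXES]
                motion_r = _rot_x(vals[3]) @ _rot_y(vals[4]) @ _rot_z(vals[5])
                motion_t = np.asarray(vals[:3], dtype=float)
            else:  # weld
                motion_r = _I3
                motion_t = np.zeros(3)
            if j.fixed_rotation is not None:
                motion_r = motion_r @ j.fixed_rotation
            ca_inv = j.child_attach.invert()
            # child = parent ∘ parent_attach ∘ motion ∘ child_attach⁻¹
            r1 = pa_r @ motion_r
            t1 = pa_r @ motion_t + pa_t
            r2 = r1 @ ca_inv.rotation
            t2 = r1 @ ca_inv.translation + t1
            poses[j.child] = (pr @ r2, pr @ t2 + pt)
        del poses[GROUND]
        return poses

    def forward_kinematics(self, q: Mapping[str, float]) -> Dict[str, RigidTransform]:
        """World pose of every segment under generalized coordinates ``q``."""
        return {name: RigidTransform(r, t) for name, (r, t) in self.fk_raw(q).items()}

    def marker_positions(self, q: Mapping[str, float]) -> Dict[str, np.ndarray]:
        """World position (m) of every labeled marker under ``q``."""
        poses = self.fk_raw(q)
        out: Dict[str, np.ndarray] = {}
        for seg in self.segments.values():
            r, t = poses[seg.name]
            for label, local in seg.local_markers.items():
                out[label] = r @ local + t
        return out

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise ConfigurationError(f"no joint named {name!r}")

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        def _tf(t: RigidTransform) -> dict:
            return {
                "rotation": [[float(x) for x in row] for row in t.rotation],
                "translation": [float(x) for x in t.translation],
            }

        return {
            "segments": [
                {
                    "name": s.name,
                    "length": float(s.length),
                    "longitudinal_axis": s.longitudinal_axis,
                    "local_markers": {
                        k: [float(x) for x in v] for k, v in s.local_markers.items()
                    },
                }
                for s in self.segments.values()
            ],
            "joints": [
                {
                    "name": j.name,
                    "kind": j.kind,
                    "parent": j.parent,
                    "child": j.child,
                    "parent_attach": _tf(j.parent_attach),
                    "child_attach": _tf(j.child_attach),
                    "limits": list(j.limits) if j.limits is not None else None,
                    "fixed_rotation": (
                        [[float(x) for x in row] for row in j.fixed_rotation]
                        if j.fixed_rotation is not None
                        else None
                    ),
                }
                for j in self.joints
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KinematicModel":
        segments = [
            Segment(
                name=s["name"],
                length=s["length"],
                local_markers={k: np.array(v) for k, v in s["local_markers"].items()},
                longitudinal_axis=s.get("longitudinal_axis", 1),
            )
            for s in data["segments"]
        ]
        joints = [
            Joint(
                name=j["name"],
                kind=j["kind"],
                parent=j["parent"],
                child=j["child"],
                parent_attach=RigidTransform(
                    np.array(j["parent_attach"]["rotation"]),
                    np.array(j["parent_attach"]["translation"]),
                ),
                child_attach=RigidTransform(
                    np.array(j["child_attach"]["rotation"]),
                    np.array(j["child_attach"]["translation"]),
                ),
                limits=tuple(j["limits"]) if j.get("limits") else None,
                fixed_rotation=(
                    np.array(j["fixed_rotation"]) if j.get("fixed_rotation") is not None else None
                ),
            )
            for j in data["joints"]
        ]
        return cls(segments, joints)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "KinematicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def forward_kinematics(model: "KinematicModel", q: Mapping[str, float]) -> Dict[str, RigidTransform]:
    """World pose of every segment of ``model`` under coordinates ``q``."""
    return model.forward_kinematics(q)


def marker_positions(model: "KinematicModel", q: Mapping[str, float]) -> Dict[str, np.ndarray]:
    """World position (m) of every labeled marker of ``model`` under ``q``."""
    return model.marker_positions(q)


def joint_angle_between_frames(
    parent: RigidTransform, child: RigidTransform, joint: Joint, tol: float = 1e-6
) -> float:
    """Signed rotation (deg) about the joint Z axis between two world poses.

    Returns the angle taking the parent Y axis onto the child Y axis in
    ``(-180, 180]``.  Raises :class:`GeometryViolationError` when the
    relative rotation is not a pure Z rotation within ``tol``.
    """
    if joint.kind != "revolute_z":
        raise ConfigurationError("joint_angle_between_frames requires a revolute_z joint")
    r_rel = (
        joint.parent_attach.rotation.T
        @ parent.rotation.T
        @ child.rotation
        @ joint.child_attach.rotation
    )
    if joint.fixed_rotation is not None:
        r_rel = r_rel @ joint.fixed_rotation.T
    off_axis = max(
        abs(r_rel[2, 0]), abs(r_rel[2, 1]), abs(r_rel[0, 2]), abs(r_rel[1, 2]), abs(r_rel[2, 2] - 1.0)
    )
    if off_axis > tol:
        raise GeometryViolationError(
            f"relative rotation is not about the joint Z axis (off-axis {off_axis:.2e})"
        )
    return wrap_angle_deg(math.degrees(math.atan2(r_rel[1, 0], r_rel[0, 0])))
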