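"""Human-exoskeleton fixation constraints and their residuals.

The fixations that strap the exoskeleton to the leg are modeled as a
fixed set of geometric constraints between the two kinematic chains:

* a 6-DOF weld between the human pelvis and the exoskeleton corset,
  implemented structurally (the two chains share one merged base, so the
  weld contributes no residual rows);
* a 2-DOF point-on-line constraint between a point on the tibia and the
  exoskeleton shank bar (the shank brace slides along the bar);
* three 3-DOF point-to-point constraints between the human foot and the
  exoskeleton sole (the foot is strapped flat onto the sole).

The default residual vector therefore has dimension 11 = 2 + 3x3.
Anchor points are calibrated at the static posture so that all residuals
vanish there: the calibration posture is, by construction, the reference
in which human and exoskeleton are "perfectly" strapped together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, TYPE_CHECKING

import numpy as np

from .errors import ValidationError
from .kinematics_core import KinematicModel, RigidTransform

if TYPE_CHECKING:  # pragma: no cover
    from .body_models import CoupledModel

_UNIT_TOL = 1e-12


@dataclass
class ConstraintSpec:
    """One geometric constraint between two segments.

    ``body_a``/``local_a`` name the constrained point.  For
    ``point_to_point3``, ``local_b`` is the anchor point on ``body_b``.
    For ``point_on_line2``, ``line_point``/``line_dir`` define the line
    in the frame of ``body_b`` and ``basis`` holds the two unit vectors
    that complete an orthonormal triad with ``line_dir``; the basis is
    fixed at construction so the two residual components stay continuous
    over the gait cycle.  ``weld6`` is structural and contributes no
    residual rows.
    """

    kind: str
    weight: float = 1.0
    body_a: str = ""
    local_a: Optional[np.ndarray] = None
    body_b: str = ""
    local_b: Optional[np.ndarray] = None
    line_point: Optional[np.ndarray] = None
    line_dir: Optional[np.ndarray] = None
    basis: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("weld6", "point_on_line2", "point_to_point3"):
            raise ValidationError(f"unknown constraint kind {self.kind!r}")
        if not self.weight > 0:
            raise ValidationError("constraint weight must be > 0")
        for attr in ("local_a", "local_b", "line_point", "line_dir"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float).reshape(3))
        if self.kind == "point_on_line2":
            if self.line_dir is None or abs(np.linalg.norm(self.line_dir) - 1.0) > _UNIT_TOL:
                raise ValidationError("line direction must be unit length within 1e-12")
            if self.basis is None:
                self.basis = _complete_basis(self.line_dir)
            else:
                self.basis = (
                    np.asarray(self.basis[0], dtype=float).reshape(3),
                    np.asarray(self.basis[1], dtype=float).reshape(3),
                )

    @property
    def residual_dim(self) -> int:
        return {"weld6": 0, "point_on_line2": 2, "point_to_point3": 3}[self.kind]


def _complete_basis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing an orthonormal triad with ``direction``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    u1 = np.cross(direction, helper)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(direction, u1)
    return u1, u2


@dataclass
class ConstraintSet:
    """Ordered list of constraints with a fixed stacked residual layout."""

    specs: List[ConstraintSpec] = field(default_factory=list)

    @property
    def residual_dim(self) -> int:
        return sum(s.residual_dim for s in self.specs)


# ----------------------------------------------------------------------
# residual primitives
# ----------------------------------------------------------------------

def residual_point_to_point(
    pose_a: RigidTransform,
    local_a: np.ndarray,
    pose_b: RigidTransform,
    local_b: np.ndarray,
) -> np.ndarray:
    """World-frame separation of two body-fixed anchor points (m)."""
    return pose_a.apply(local_a) - pose_b.apply(local_b)


def residual_point_on_line(
    pose_point_body: RigidTransform,
    local_point: np.ndarray,
    pose_line_body: RigidTransform,
    line_point: np.ndarray,
    line_dir: np.ndarray,
    basis: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Two off-axis components of a point's offset from a body-fixed line.

    Sliding the point along the line leaves the residual unchanged; the
    components are taken along the two basis vectors rotated with the
    line's body.
    """
    if abs(np.linalg.norm(line_dir) - 1.0) > _UNIT_TOL:
        raise ValidationError("line direction must be unit length within 1e-12")
    if basis is None:
        basis = _complete_basis(np.asarray(line_dir, dtype=float))
    p = pose_point_body.apply(local_point)
    base = pose_line_body.apply(line_point)
    offset = p - base
    u1 = pose_line_body.rotation @ basis[0]
    u2 = pose_line_body.rotation @ basis[1]
    return np.array([u1 @ offset, u2 @ offset])


# ----------------------------------------------------------------------
# stacked residuals
# ----------------------------------------------------------------------

def constraint_residuals_raw(
    model: KinematicModel, cs: ConstraintSet, q: Mapping[str, float]
) -> np.ndarray:
    """Stacked constraint residual vector (m) at coordinates ``q``.

    Fast path over the raw (R, t) forward kinematics; the residual order
    follows the constraint order in ``cs`` (tibia line first, then the
    three foot points for the default set).
    """
    poses = model.fk_raw(q, check=False)
    out = np.empty(cs.residual_dim)
    k = 0
    for spec in cs.specs:
        if spec.kind == "weld6":
            continue
        ra, ta = poses[spec.body_a]
        rb, tb = poses[spec.body_b]
        pa = ra @ spec.local_a + ta
        sw = spec.weight**0.5
        if spec.kind == "point_to_point3":
            out[k : k + 3] = sw * (pa - (rb @ spec.local_b + tb))
            k += 3
        else:  # point_on_line2
            offset = pa - (rb @ spec.line_point + tb)
            out[k] = sw * ((rb @ spec.basis[0]) @ offset)
            out[k + 1] = sw * ((rb @ spec.basis[1]) @ offset)
            k += 2
    return out


def constraint_residuals(
    coupled: "CoupledModel",
    cs: ConstraintSet,
    q_H: Mapping[str, float],
    q_R: Mapping[str, float],
) -> np.ndarray:
    """Residuals of the coupled chain with the base pinned at the origin.

    ``q_H``/``q_R`` map the human/exoskeleton coordinate names (or the
    plain sagittal channel names) to degrees; base coordinates default
    to zero, which is immaterial since the residuals are invariant to a
    common rigid motion of all bodies.
    """
    from .trajectories import SAGITTAL_CHANNELS

    q: Dict[str, float] = {}
    for coord, channel in zip(coupled.human_coords, SAGITTAL_CHANNELS):
        q[coord] = float(q_H.get(coord, q_H.get(channel, 0.0)))
    for coord, channel in zip(coupled.exo_coords, SAGITTAL_CHANNELS):
        q[coord] = float(q_R.get(coord, q_R.get(channel, 0.0)))
    return constraint_residuals_raw(coupled.model, cs, q)


def make_default_constraint_set(
    coupled: "CoupledModel", config: Optional[Mapping] = None
) -> ConstraintSet:
    """Build the default fixation set calibrated at the static posture.

    Anchor placement (the device's brace coordinates are never published,
    so these are the package's documented choices, all overridable):

    * tibia point at mid-shank on the lateral aspect, constrained to the
      exoskeleton shank bar axis (local Y line);
    * three foot sole points at the heel and the medial/lateral forefoot.

    Counterpart anchors on the exoskeleton are the static-posture world
    positions expressed in the exoskeleton body frames, so every
    residual is exactly zero at the static configuration.

    Constraint weights reflect the relative stiffness of the physical
    fixations: the shank cuff is a snug rigid bracket (weight 4), the
    heel cup grips the foot firmly (weight 3), the forefoot straps are
    the most compliant (weight 1).  Weighting the heel up also moves the
    weighted anchor centroid toward the ankle axis, which reduces the
    leak of unresolvable strap-translation mismatch into the estimated
    ankle rotation.

    ``config`` (for example loaded from YAML) may override the anchors
    and weights in segment-local coordinates::

        tibia_point: [x, y, z]        # meters, tibia frame
        foot_points: [[x, y, z], ...] # meters, foot frame (three points)
        weights: {tibia: w, foot: [w1, w2, w3]}
    """
    config = dict(config or {})
    weights = dict(config.get("weights", {}))
    model = coupled.model
    poses = model.fk_raw(coupled.static_posture, check=False)

    def _pose(name: str) -> RigidTransform:
        r, t = poses[name]
        return RigidTransform(r, t)

    tibia_len = model.segments[coupled.tibia_segment].length
    tibia_point = np.asarray(
        config.get("tibia_point", [0.0, -0.5 * tibia_len, 0.06]), dtype=float
    )
    shank_pose = _pose(coupled.exo_shank_segment)
    tibia_world = _pose(coupled.tibia_segment).apply(tibia_point)
    line_point = shank_pose.invert().apply(tibia_world)
    specs: List[ConstraintSpec] = [
        ConstraintSpec(kind="weld6", body_a=coupled.pelvis_segment, body_b=coupled.corset_segment),
        ConstraintSpec(
            kind="point_on_line2",
            weight=float(weights.get("tibia", 4.0)),
            body_a=coupled.tibia_segment,
            local_a=tibia_point,
            body_b=coupled.exo_shank_segment,
            line_point=line_point,
            line_dir=np.array([0.0, 1.0, 0.0]),
            basis=(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
        ),
    ]

    foot_pose = _pose(coupled.foot_segment)
    sole_pose = _pose(coupled.exo_sole_segment)
    foot_len = model.segments[coupled.foot_segment].length
    default_points = [
        np.array([-0.05, -0.08, 0.0]),                 # heel cup
        np.array([0.72 * foot_len, -0.08, 0.035]),     # medial forefoot
        np.array([0.72 * foot_len, -0.08, -0.035]),    # lateral forefoot
    ]
    points = [np.asarray(p, dtype=float) for p in config.get("foot_points", default_points)]
    foot_weights = list(weights.get("foot", [3.0, 1.0, 1.0]))
    for p, weight in zip(points, foot_weights):
        sole_anchor = sole_pose.invert().apply(foot_pose.apply(p))
        specs.append(
            ConstraintSpec(
                kind="point_to_point3",
                weight=weight,
                body_a=coupled.foot_segment,
                local_a=p,
                body_b=coupled.exo_sole_segment,
                local_b=sole_anchor,
            )
        )
    return ConstraintSet(specs)
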