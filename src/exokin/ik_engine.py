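"""Inverse kinematics: marker-based ground truth, the rigid baseline, and
the constraint-closure estimator.

Three estimators live here:

* :func:`marker_ik` — classic marker tracking: per frame, minimize the
  weighted sum of squared distances between model-attached markers and
  measured markers over the free generalized coordinates.  Used to
  compute ground-truth joint angles from (synthetic) motion capture.
* :func:`rigid_estimate` — the traditional baseline that assumes zero
  relative motion between human and exoskeleton: human angles are taken
  channel-for-channel from the exoskeleton angles.
* :func:`eikpe_estimate` — the coupled-chain estimator: with the
  exoskeleton coordinates clamped to their known values at each instant,
  solve for the three human sagittal angles (hip, knee, ankle flexion)
  that minimize the human-exoskeleton fixation constraint residuals in a
  damped least-squares sense, warm-starting each frame from the previous
  solution.

All solvers are deterministic: identical inputs and settings give
identical outputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from .coupling_constraints import ConstraintSet, constraint_residuals_raw
from .errors import ConfigurationError, MissingMarkerError, SchemaError, UnderdeterminedFrameError, ValidationError
from .kinematics_core import KinematicModel
from .trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS

if TYPE_CHECKING:  # pragma: no cover
    from .body_models import CoupledModel


@dataclass
class IKSettings:
    """Solver settings shared by the marker and constraint IK paths.

    ``tolerance`` is the relative stop criterion on the residual norm /
    step; ``marker_weights`` maps labels to non-negative weights
    (unlisted markers weigh 1); ``residual_warn_m`` is the plausibility
    bound above which a converged constraint solution is still flagged.
    """

    tolerance: float = 1e-10
    max_iterations: int = 100
    marker_weights: Dict[str, float] = field(default_factory=dict)
    warm_start: bool = True
    residual_warn_m: float = 0.02

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0")
        if any(w < 0 for w in self.marker_weights.values()):
            raise ValidationError("marker weights must be non-negative")


@dataclass
class IKResult:
    """Joint-angle trajectory plus per-frame diagnostics."""

    trajectory: JointTrajectory
    per_frame_residual_rms: np.ndarray
    converged: np.ndarray


def _forward_diff_jac(fun, step: float = 1e-6):
    """Forward-difference Jacobian with an absolute step.

    Degrees and meters are both O(1)-scaled here, so a fixed absolute
    step is appropriate; relative stepping underflows when a coordinate
    passes through zero (e.g. warm starts at a neutral posture).
    """

    def jac(x: np.ndarray) -> np.ndarray:
        f0 = fun(x)
        out = np.empty((f0.size, x.size))
        for j in range(x.size):
            xp = x.copy()
            xp[j] += step
            out[:, j] = (fun(xp) - f0) / step
        return out

    return jac


def add_virtual_midpoint_marker(
    traj: MarkerTrajectory, a: str, b: str, name: str
) -> MarkerTrajectory:
    """Add a virtual marker at the per-frame midpoint of two real markers.

    The ankle of the exoskeleton carries no physical marker; its sole is
    tracked through the midpoint of the two forefoot/heel markers of the
    human foot strapped to it.
    """
    if a not in traj.data or b not in traj.data:
        missing = [l for l in (a, b) if l not in traj.data]
        raise MissingMarkerError(f"missing marker(s) {missing} for midpoint {name!r}")
    out = traj.copy()
    out.data[name] = 0.5 * (traj.data[a] + traj.data[b])
    return out


# ----------------------------------------------------------------------
# single-frame weighted marker fit (shared by marker_ik and assembly)
# ----------------------------------------------------------------------

def fit_frame(
    model: KinematicModel,
    measured: Mapping[str, np.ndarray],
    free_coords: Sequence[str],
    x0: np.ndarray,
    settings: Optional[IKSettings] = None,
    frozen_values: Optional[Mapping[str, float]] = None,
    hip_joint=None,
) -> Tuple[np.ndarray, float, bool, Optional[Tuple[float, float]]]:
    """Least-squares fit of one marker frame.

    Returns ``(x, residual_rms, converged, hip_extras)``.  When
    ``hip_joint`` is given, two extra parameters (hip internal rotation
    and ab-adduction, degrees) are appended to the unknowns and written
    into the joint's fixed rotation — used only while solving the static
    calibration posture, after which they stay frozen.
    """
    from .kinematics_core import set_frozen_hip_angles  # local to avoid cycle noise

    settings = settings or IKSettings()
    frozen_values = dict(frozen_values or {})
    free_coords = list(free_coords)

    model_labels = {
        label for seg in model.segments.values() for label in seg.local_markers
    }
    usable: List[Tuple[str, np.ndarray, float]] = []
    for label, pos in measured.items():
        if label not in model_labels:
            continue
        pos = np.asarray(pos, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            continue
        w = settings.marker_weights.get(label, 1.0)
        if w > 0:
            usable.append((label, pos, np.sqrt(w)))
    if len(usable) < 3:
        raise UnderdeterminedFrameError(
            f"only {len(usable)} usable markers in frame; at least 3 required"
        )

    n_free = len(free_coords)
    n_params = n_free + (2 if hip_joint is not None else 0)

    # precompute (segment, local, weight) per usable marker
    seg_of: Dict[str, str] = {}
    local_of: Dict[str, np.ndarray] = {}
    for seg in model.segments.values():
        for label, local in seg.local_markers.items():
            seg_of[label] = seg.name
            local_of[label] = local

    def residuals(x: np.ndarray) -> np.ndarray:
        q = dict(frozen_values)
        for name, val in zip(free_coords, x[:n_free]):
            q[name] = val
        if hip_joint is not None:
            set_frozen_hip_angles(hip_joint, x[n_free], x[n_free + 1])
        poses = model.fk_raw(q, check=False)
        out = np.empty(3 * len(usable))
        for i, (label, pos, w) in enumerate(usable):
            r, t = poses[seg_of[label]]
            out[3 * i : 3 * i + 3] = w * (r @ local_of[label] + t - pos)
        return out

    x0 = np.asarray(x0, dtype=float).reshape(n_params).copy()
    # MINPACK sizes its initial trust region from ||x0||: snap numerically
    # zero warm starts to exact zero so the fallback radius applies
    x0[np.abs(x0) < 1e-9] = 0.0
    method = "lm" if 3 * len(usable) >= n_params else "trf"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # joint-limit warnings inside line search
        sol = least_squares(
            residuals,
            x0,
            jac=_forward_diff_jac(residuals),
            method=method,
            ftol=settings.tolerance,
            xtol=settings.tolerance,
            gtol=1e-14,
            max_nfev=settings.max_iterations * (n_params + 1),
        )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    extras = (float(sol.x[n_free]), float(sol.x[n_free + 1])) if hip_joint is not None else None
    return sol.x[:n_free].copy(), rms, bool(sol.status > 0), extras


def marker_ik(
    model: KinematicModel,
    markers: MarkerTrajectory,
    settings: Optional[IKSettings] = None,
    free_coords: Optional[Sequence[str]] = None,
    frozen_values: Optional[Mapping[str, float]] = None,
    x0: Optional[np.ndarray] = None,
) -> IKResult:
    """Marker-based inverse kinematics over a full trajectory.

    Per frame the free coordinates minimize the weighted squared marker
    mismatch; frozen coordinates (for example the base pose during
    treadmill trials, or the hip rotation/ab-adduction held at their
    static values) are fixed via ``frozen_values``.  Frames are solved in
    capture order with warm starting.
    """
    settings = settings or IKSettings()
    free = list(free_coords) if free_coords is not None else list(model.coordinate_names)
    unknown = [c for c in free if c not in model.coordinate_names]
    if unknown:
        raise ConfigurationError(f"unknown free coordinates {unknown}")
    frozen_values = dict(frozen_values or {})

    n = markers.n
    x = np.zeros(len(free)) if x0 is None else np.asarray(x0, dtype=float).copy()
    values = np.empty((n, len(free)))
    rms = np.empty(n)
    conv = np.empty(n, dtype=bool)
    for i in range(n):
        xi, rms_i, ok, _ = fit_frame(
            model, markers.frame(i), free, x, settings, frozen_values
        )
        values[i] = xi
        rms[i] = rms_i
        conv[i] = ok
        if settings.warm_start:
            x = xi.copy()
        elif x0 is not None:
            x = np.asarray(x0, dtype=float).copy()
        else:
            x = np.zeros(len(free))
    channels = {name: values[:, k] for k, name in enumerate(free)}
    for name, val in frozen_values.items():
        channels.setdefault(name, np.full(n, val))
    traj = JointTrajectory(markers.time.copy(), channels)
    return IKResult(traj, rms, conv)


def rigid_estimate(v_R: JointTrajectory) -> JointTrajectory:
    """Rigid baseline: human joint angles = exoskeleton joint angles.

    Accepts exoskeleton channels either under the sagittal names or with
    an ``exo_`` prefix; the output always uses the sagittal names.
    """
    channels: Dict[str, np.ndarray] = {}
    for name in SAGITTAL_CHANNELS:
        if name in v_R.channels:
            channels[name] = v_R.channels[name].copy()
        elif f"exo_{name}" in v_R.channels:
            channels[name] = v_R.channels[f"exo_{name}"].copy()
        else:
            raise SchemaError(f"exoskeleton trajectory lacks channel {name!r}")
    return JointTrajectory(v_R.time.copy(), channels)


def exo_ankle_from_foot_markers(
    coupled: "CoupledModel",
    markers: MarkerTrajectory,
    v_R: JointTrajectory,
    frozen_base: Mapping[str, float],
) -> np.ndarray:
    """Exoskeleton ankle angle (deg) tracked through the strapped foot.

    The sole carries no physical marker, but the foot strapped onto it
    does: the heel marker and the virtual heel/fifth-metatarsal midpoint
    both ride the foot, so their connecting direction follows the sole
    orientation while being immune to the centimeter-scale position slip
    of the proximal chain (fitting sole points positionally would
    amplify that slip through a short lever arm).  Per frame, the angle
    is the sagittal-plane rotation taking the calibrated sole-local
    direction onto the measured direction, expressed in the exoskeleton
    shank frame posed at the known hip/knee angles.
    """
    from .kinematics_core import wrap_angle_deg

    model = coupled.model
    sole = model.segments[coupled.exo_sole_segment]
    if "Mk14" not in sole.local_markers or "SoleHeel" not in sole.local_markers:
        raise ConfigurationError("coupled model lacks calibrated sole anchors (Mk14/SoleHeel)")
    d_loc = sole.local_markers["Mk14"] - sole.local_markers["SoleHeel"]
    psi_model = np.arctan2(d_loc[1], d_loc[0])
    heel = markers.marker("Mk0")
    mid = markers.marker("Mk14")
    ankle_joint = model.joint(coupled.exo_coords[2])
    pa_r = ankle_joint.parent_attach.rotation
    out = np.empty(markers.n)
    for i in range(markers.n):
        q = dict(frozen_base)
        q[coupled.exo_coords[0]] = float(v_R.channel(coupled.exo_coords[0])[i])
        q[coupled.exo_coords[1]] = float(v_R.channel(coupled.exo_coords[1])[i])
        poses = model.fk_raw(q, check=False)
        r_sh, _ = poses[coupled.exo_shank_segment]
        d_p = (r_sh @ pa_r).T @ (mid[i] - heel[i])
        out[i] = wrap_angle_deg(np.degrees(np.arctan2(d_p[1], d_p[0]) - psi_model))
    return out


# ----------------------------------------------------------------------
# constraint-closure estimation
# ----------------------------------------------------------------------

def _exo_frame(v_R: JointTrajectory, exo_coords: Sequence[str], i: int) -> Dict[str, float]:
    frame: Dict[str, float] = {}
    for coord, channel in zip(exo_coords, SAGITTAL_CHANNELS):
        if coord in v_R.channels:
            frame[coord] = float(v_R.channels[coord][i])
        elif channel in v_R.channels:
            frame[coord] = float(v_R.channels[channel][i])
        else:
            raise SchemaError(f"exoskeleton trajectory lacks channel for {coord!r}")
    return frame


def eikpe_estimate(
    coupled: "CoupledModel",
    cs: ConstraintSet,
    v_R: JointTrajectory,
    settings: Optional[IKSettings] = None,
) -> IKResult:
    """Estimate human sagittal joint angles from exoskeleton joint angles.

    Per frame ``t_i`` the exoskeleton coordinates are clamped to
    ``v_R(t_i)`` and the three human flexion angles are solved by damped
    least squares on the stacked fixation residuals (11 equations, 3
    unknowns).  The base is pinned at the ground origin: joint angles are
    invariant to a common rigid motion of the coupled chain.  Frame 0
    starts from the static calibration posture; later frames warm-start
    from the previous solution.
    """
    settings = settings or IKSettings()
    model = coupled.model
    human = list(coupled.human_coords)
    exo = list(coupled.exo_coords)
    n = v_R.n

    x = np.array([coupled.static_posture.get(c, 0.0) for c in human])
    values = np.empty((n, 3))
    rms = np.empty(n)
    conv = np.empty(n, dtype=bool)
    dim = cs.residual_dim
    warned = False

    for i in range(n):
        q_exo = _exo_frame(v_R, exo, i)

        def residuals(xh: np.ndarray) -> np.ndarray:
            q = dict(q_exo)
            q.update(zip(human, xh))
            return constraint_residuals_raw(model, cs, q)

        x[np.abs(x) < 1e-9] = 0.0  # see fit_frame: trust-region sizing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(
                residuals,
                x,
                jac=_forward_diff_jac(residuals),
                method="lm",
                ftol=settings.tolerance,
                xtol=settings.tolerance,
                gtol=1e-14,
                max_nfev=settings.max_iterations * 4,
            )
        values[i] = sol.x
        rms[i] = float(np.sqrt(np.mean(sol.fun**2)))
        conv[i] = bool(sol.status > 0)
        if rms[i] > settings.residual_warn_m and not warned:
            warnings.warn(
                f"constraint residual RMS {rms[i]:.4f} m at frame {i} exceeds "
                f"plausibility bound {settings.residual_warn_m} m",
                stacklevel=2,
            )
            warned = True
        if settings.warm_start:
            x = sol.x.copy()
        else:
            x = np.array([coupled.static_posture.get(c, 0.0) for c in human])

    traj = JointTrajectory(
        v_R.time.copy(), {ch: values[:, k] for k, ch in enumerate(SAGITTAL_CHANNELS)}
    )
    return IKResult(traj, rms, conv)


def constraint_objective(
    coupled: "CoupledModel", cs: ConstraintSet, q_exo: Mapping[str, float]
) -> Callable[[Sequence[float]], float]:
    """Sum-of-squares fixation residual as a function of the 3 human angles."""
    model = coupled.model
    human = list(coupled.human_coords)

    def objective(xh: Sequence[float]) -> float:
        q = dict(q_exo)
        q.update(zip(human, xh))
        r = constraint_residuals_raw(model, cs, q)
        return float(r @ r)

    return objective


def grid_refine_estimate(
    objective: Callable[[Sequence[float]], float],
    center: Sequence[float],
    half_range: float = 10.0,
    final_step: float = 0.005,
    npts: int = 13,
) -> np.ndarray:
    """Brute-force reference solver: nested dense grid search over 3 angles.

    Evaluates the objective on a uniform 3D grid around ``center`` and
    recursively refines around the best node until the grid step falls
    below ``final_step`` degrees.  Independent of the damped
    least-squares path; used as the oracle in solver-equivalence checks.
    """
    best = np.asarray(center, dtype=float).copy()
    hr = float(half_range)
    while True:
        axes = [np.linspace(c - hr, c + hr, npts) for c in best]
        best_val = np.inf
        for combo in itertools.product(*axes):
            val = objective(combo)
            if val < best_val:
                best_val = val
                best = np.asarray(combo)
        step = 2.0 * hr / (npts - 1)
        if step <= final_step:
            return best
        hr = 2.0 * step
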