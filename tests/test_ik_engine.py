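"""Marker IK, the rigid baseline and the constraint-closure estimator."""

import numpy as np
import pytest

from exokin import (
    IKSettings,
    add_virtual_midpoint_marker,
    assemble_coupled,
    eikpe_estimate,
    grid_refine_estimate,
    make_default_constraint_set,
    marker_ik,
    rigid_estimate,
)
from exokin.coupling_constraints import constraint_residuals_raw
from exokin.errors import MissingMarkerError, SchemaError, UnderdeterminedFrameError
from exokin.ik_engine import constraint_objective, fit_frame
from exokin.trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS


class TestVirtualMidpoint:
    def test_midpoint_definition(self):
        time = np.array([0.0, 0.01])
        traj = MarkerTrajectory(
            time,
            {"a": np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
             "b": np.array([[2.0, 0.0, 0.0], [2.0, 2.0, 0.0]])},
        )
        out = add_virtual_midpoint_marker(traj, "a", "b", "mid")
        np.testing.assert_allclose(out.data["mid"], [[1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        # originals untouched, equidistance holds
        assert set(out.labels) == {"a", "b", "mid"}
        da = np.linalg.norm(out.data["mid"] - out.data["a"], axis=1)
        db = np.linalg.norm(out.data["mid"] - out.data["b"], axis=1)
        np.testing.assert_allclose(da, db, atol=1e-15)

    def test_degenerate_and_missing(self):
        time = np.array([0.0])
        traj = MarkerTrajectory(time, {"a": np.array([[1.0, 2.0, 3.0]])})
        same = add_virtual_midpoint_marker(
            MarkerTrajectory(time, {"a": traj.data["a"], "b": traj.data["a"].copy()}),
            "a", "b", "mid",
        )
        np.testing.assert_allclose(same.data["mid"], traj.data["a"])
        with pytest.raises(MissingMarkerError):
            add_virtual_midpoint_marker(traj, "a", "nope", "mid")


class TestMarkerIK:
    def test_noiseless_round_trip(self, identity_subject, identity_result):
        """Marker IK on noiseless synthetic gait recovers the generating angles."""
        s, res = identity_subject, identity_result
        for ch in SAGITTAL_CHANNELS:
            err = np.max(np.abs(res.gt.channel(ch) - s.v_H.channel(ch)))
            assert err < 0.1

    def test_human_only_walk_round_trip(self, identity_subject):
        """No-exoskeleton walking trial: IK on the 12-marker human model
        recovers the generating angles with the pelvis held at its
        standing pose."""
        s = identity_subject
        sub = MarkerTrajectory(
            s.walk_no_exo.time[:50].copy(),
            {k: v[:50].copy() for k, v in s.walk_no_exo.data.items()},
        )
        hip_y = s.human.segments["femur"].length + s.human.segments["tibia"].length + 0.10
        frozen = {"pelvis_free_ty": hip_y + 0.07}
        res = marker_ik(
            s.human, sub, free_coords=list(SAGITTAL_CHANNELS), frozen_values=frozen
        )
        for ch in SAGITTAL_CHANNELS:
            assert np.max(np.abs(res.trajectory.channel(ch) - s.v_H.channel(ch)[:50])) < 0.1

    def test_static_markers_constant_output(self, identity_subject):
        s = identity_subject
        coupled = assemble_coupled(s.human, s.exo, s.static_with_exo)
        frame = s.static_with_exo.frame(0)
        repeated = MarkerTrajectory(
            np.arange(5) * 0.01, {k: np.tile(v, (5, 1)) for k, v in frame.items()}
        )
        frozen = {c: coupled.static_posture[c] for c in coupled.base_coords}
        free = list(coupled.human_coords)
        res = marker_ik(coupled.model, repeated, free_coords=free, frozen_values=frozen)
        for ch in free:
            assert np.ptp(res.trajectory.channel(ch)) < 1e-9

    def test_underdetermined_frame_rejected(self, human_model):
        pos = human_model.marker_positions(human_model.zero_coordinates())
        frame = {"Mk0": pos["Mk0"], "Mk1": pos["Mk1"]}
        with pytest.raises(UnderdeterminedFrameError):
            fit_frame(human_model, frame, ["hip_flexion"], np.zeros(1))

    def test_determinism(self, identity_subject):
        s = identity_subject
        coupled = assemble_coupled(s.human, s.exo, s.static_with_exo)
        frozen = {c: coupled.static_posture[c] for c in coupled.base_coords}
        sub = MarkerTrajectory(
            s.walk_markers.time[:20].copy(),
            {k: v[:20].copy() for k, v in s.walk_markers.data.items()},
        )
        a = marker_ik(coupled.model, sub, free_coords=list(coupled.human_coords), frozen_values=frozen)
        b = marker_ik(coupled.model, sub, free_coords=list(coupled.human_coords), frozen_values=frozen)
        for ch in coupled.human_coords:
            assert np.array_equal(a.trajectory.channel(ch), b.trajectory.channel(ch))


class TestRigidEstimate:
    def test_identity_mapping(self):
        time = np.arange(10) * 0.01
        v_r = JointTrajectory(
            time,
            {
                "exo_hip_flexion": np.linspace(0, 20, 10),
                "exo_knee_flexion": np.linspace(5, 50, 10),
                "exo_ankle_flexion": np.linspace(-10, 10, 10),
            },
        )
        out = rigid_estimate(v_r)
        assert np.array_equal(out.channel("hip_flexion"), v_r.channel("exo_hip_flexion"))
        assert np.array_equal(out.channel("knee_flexion"), v_r.channel("exo_knee_flexion"))
        assert np.array_equal(out.channel("ankle_flexion"), v_r.channel("exo_ankle_flexion"))

    def test_missing_channel_rejected(self):
        v_r = JointTrajectory(np.arange(3) * 0.01, {"hip_flexion": np.zeros(3)})
        with pytest.raises(SchemaError):
            rigid_estimate(v_r)


class TestEikpe:
    def test_identical_geometry_reproduces_exo_angles(self, identity_subject):
        """Perfectly aligned closed chain: the estimate equals the exo angles."""
        s = identity_subject
        coupled = assemble_coupled(s.human, s.exo, s.static_with_exo)
        cs = make_default_constraint_set(coupled)
        sub = JointTrajectory(
            s.v_R.time[:50].copy(), {k: v[:50].copy() for k, v in s.v_R.channels.items()}
        )
        res = eikpe_estimate(coupled, cs, sub)
        for ch in SAGITTAL_CHANNELS:
            assert np.max(np.abs(res.trajectory.channel(ch) - sub.channel(ch))) < 1e-4

    def test_optimality_vs_rigid_configuration(self, misaligned_subject, misaligned_result):
        """Per frame, the closure residual at the solution never exceeds the
        residual at the rigid (human=exo angles) configuration."""
        res = misaligned_result
        coupled, cs = res.coupled, res.constraint_set
        n_checked = 0
        for i in range(0, res.v_R.n, 10):
            q_r = {c: float(res.v_R.channel(c)[i]) for c in coupled.exo_coords}
            obj = constraint_objective(coupled, cs, q_r)
            at_solution = obj([res.eikpe.channel(ch)[i] for ch in SAGITTAL_CHANNELS])
            at_rigid = obj([res.rigid.channel(ch)[i] for ch in SAGITTAL_CHANNELS])
            assert at_solution <= at_rigid + 1e-15
            n_checked += 1
        assert n_checked >= 20

    def test_matches_grid_search_oracle(self, misaligned_result, rng):
        """Damped least squares agrees with nested dense grid search."""
        res = misaligned_result
        coupled, cs = res.coupled, res.constraint_set
        frames = rng.choice(res.v_R.n, size=5, replace=False)
        for i in frames:
            q_r = {c: float(res.v_R.channel(c)[i]) for c in coupled.exo_coords}
            obj = constraint_objective(coupled, cs, q_r)
            solution = np.array([res.eikpe.channel(ch)[i] for ch in SAGITTAL_CHANNELS])
            oracle = grid_refine_estimate(obj, solution, half_range=3.0)
            assert np.max(np.abs(solution - oracle)) < 0.02

    def test_continuity_no_branch_hopping(self, misaligned_result):
        for ch in SAGITTAL_CHANNELS:
            jumps = np.abs(np.diff(misaligned_result.eikpe.channel(ch)))
            assert np.max(jumps) < 5.0

    def test_determinism(self, identity_subject):
        s = identity_subject
        coupled = assemble_coupled(s.human, s.exo, s.static_with_exo)
        cs = make_default_constraint_set(coupled)
        sub = JointTrajectory(
            s.v_R.time[:20].copy(), {k: v[:20].copy() for k, v in s.v_R.channels.items()}
        )
        a = eikpe_estimate(coupled, cs, sub)
        b = eikpe_estimate(coupled, cs, sub)
        for ch in SAGITTAL_CHANNELS:
            assert np.array_equal(a.trajectory.channel(ch), b.trajectory.channel(ch))
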