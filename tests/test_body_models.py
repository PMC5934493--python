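"""Human model construction, subject scaling, exoskeleton adjustment, coupling."""

import numpy as np
import pytest

from exokin import (
    ScaleFactors,
    adjust_exo_links,
    apply_scaling,
    assemble_coupled,
    build_exo_model,
    build_generic_human,
    compute_scale_factors,
)
from exokin.body_models import HUMAN_MARKER_LABELS, couple_models
from exokin.errors import (
    ImplausibleStaticPoseError,
    MissingMarkerError,
    ValidationError,
)
from exokin.synthetic_gait import generate_subject, soft_tissue_preset, GaitProfileParams
from exokin.trajectories import static_markers_from_mapping


class TestGenericHuman:
    def test_twelve_markers_present(self, human_model):
        labels = {l for s in human_model.segments.values() for l in s.local_markers}
        assert set(HUMAN_MARKER_LABELS) <= labels

    def test_neutral_standing_order(self, human_model):
        pos = human_model.marker_positions(human_model.zero_coordinates())
        assert pos["Mk11"][1] > pos["Mk7"][1] > pos["Mk3"][1]

    def test_femur_span_equals_length(self, human_model):
        pos = human_model.marker_positions(human_model.zero_coordinates())
        span_y = abs(pos["Mk11"][1] - pos["Mk7"][1])
        assert span_y == pytest.approx(0.40, abs=1e-12)


class TestScaling:
    def test_identity_factors(self, human_model):
        frame = human_model.marker_positions(human_model.zero_coordinates())
        f = compute_scale_factors(static_markers_from_mapping(frame), human_model)
        assert (f.femur, f.tibia, f.foot) == pytest.approx((1.0, 1.0, 1.0), abs=1e-12)

    def test_ratio_definition(self, human_model):
        # measured trochanter-knee distance 0.44 m over a 0.40 m model femur
        frame = dict(human_model.marker_positions(human_model.zero_coordinates()))
        frame["Mk11"] = frame["Mk7"] + 1.1 * (frame["Mk11"] - frame["Mk7"])
        f = compute_scale_factors(static_markers_from_mapping(frame), human_model)
        assert f.femur == pytest.approx(1.1, abs=1e-12)

    def test_known_factor_recovery(self, human_model):
        s = generate_subject(
            seed=3,
            scale_factors=ScaleFactors(femur=0.95, tibia=1.05, foot=1.02),
            gait=GaitProfileParams(duration=0.05),
            soft=soft_tissue_preset("none"),
        )
        f = compute_scale_factors(s.static_no_exo, human_model)
        assert abs(f.femur - 0.95) < 1e-6
        assert abs(f.tibia - 1.05) < 1e-6
        assert abs(f.foot - 1.02) < 1e-6

    def test_missing_marker_error(self, human_model):
        frame = dict(human_model.marker_positions(human_model.zero_coordinates()))
        del frame["Mk7"]
        with pytest.raises(MissingMarkerError, match="Mk7"):
            compute_scale_factors(static_markers_from_mapping(frame), human_model)

    def test_apply_identity_is_noop(self, human_model):
        scaled = apply_scaling(human_model, ScaleFactors(1.0, 1.0, 1.0))
        for name, seg in human_model.segments.items():
            assert scaled.segments[name].length == seg.length
            for label, local in seg.local_markers.items():
                assert np.array_equal(scaled.segments[name].local_markers[label], local)

    def test_longitudinal_only(self, human_model):
        scaled = apply_scaling(human_model, ScaleFactors(1.1, 1.0, 1.0))
        assert scaled.segments["femur"].length == pytest.approx(0.44)
        for label, local in human_model.segments["femur"].local_markers.items():
            new = scaled.segments["femur"].local_markers[label]
            assert new[1] == pytest.approx(1.1 * local[1], abs=1e-15)
            assert new[0] == local[0] and new[2] == local[2]

    def test_fixed_point(self, human_model):
        scaled = apply_scaling(human_model, ScaleFactors(0.9, 1.2, 1.05))
        frame = scaled.marker_positions(scaled.zero_coordinates())
        f = compute_scale_factors(static_markers_from_mapping(frame), scaled)
        assert (f.femur, f.tibia, f.foot) == pytest.approx((1.0, 1.0, 1.0), abs=1e-9)

    def test_manual_override_precedence(self, human_model):
        f = ScaleFactors(1.1, 1.0, 1.0, manual_overrides={"femur": 1.3})
        scaled = apply_scaling(human_model, f)
        assert scaled.segments["femur"].length == pytest.approx(0.52)

    def test_invalid_factor(self):
        with pytest.raises(ValidationError):
            ScaleFactors(femur=-1.0, tibia=1.0, foot=1.0)

    def test_topology_preserved(self, human_model):
        scaled = apply_scaling(human_model, ScaleFactors(0.95, 1.05, 1.02))
        assert [j.name for j in scaled.joints] == [j.name for j in human_model.joints]
        assert list(scaled.segments) == list(human_model.segments)


class TestExoModel:
    def test_axes_parallel(self, exo_model, rng):
        q = {n: rng.uniform(-30, 60) for n in ("exo_hip_flexion", "exo_knee_flexion", "exo_ankle_flexion")}
        poses = exo_model.forward_kinematics(q)
        z_axes = [poses[s].rotation @ [0, 0, 1] for s in ("corset", "exo_thigh", "exo_shank", "exo_sole")]
        for z in z_axes[1:]:
            np.testing.assert_allclose(z, z_axes[0], atol=1e-12)

    def test_neutral_marker_order_and_span(self):
        exo = build_exo_model(thigh=0.42, shank=0.38)
        pos = exo.marker_positions(exo.zero_coordinates())
        assert pos["ExoHip"][1] > pos["ExoKnee"][1] > pos["ExoAnkle"][1]
        assert np.linalg.norm(pos["ExoKnee"] - pos["ExoHip"]) == pytest.approx(0.42, abs=1e-12)

    def test_adjust_links_differences(self, exo_model):
        frame = {
            "Mk11": np.array([0.0, 0.90, 0.1]),
            "Mk7": np.array([0.0, 0.48, 0.1]),
            "Mk3": np.array([0.0, 0.10, 0.1]),
        }
        adjusted = adjust_exo_links(exo_model, static_markers_from_mapping(frame))
        assert adjusted.segments["exo_thigh"].length == pytest.approx(0.42)
        assert adjusted.segments["exo_shank"].length == pytest.approx(0.38)

    def test_adjust_links_degenerate(self, exo_model):
        frame = {k: np.array([0.0, 0.5, 0.1]) for k in ("Mk11", "Mk7", "Mk3")}
        with pytest.raises(ImplausibleStaticPoseError):
            adjust_exo_links(exo_model, static_markers_from_mapping(frame))

    def test_adjust_links_round_trip(self):
        s = generate_subject(
            seed=5,
            scale_factors=ScaleFactors(femur=1.04, tibia=0.97, foot=1.0),
            gait=GaitProfileParams(duration=0.05),
            soft=soft_tissue_preset("none"),
        )
        adjusted = adjust_exo_links(build_exo_model(), s.static_with_exo)
        assert adjusted.segments["exo_thigh"].length == pytest.approx(
            s.exo.segments["exo_thigh"].length, abs=1e-9
        )
        assert adjusted.segments["exo_shank"].length == pytest.approx(
            s.exo.segments["exo_shank"].length, abs=1e-9
        )


class TestCoupling:
    def test_hip_centers_aligned_anterior_posterior(self, human_model, exo_model):
        coupled = couple_models(human_model, exo_model)
        poses = coupled.model.fk_raw(coupled.static_posture, check=False)
        r_p, t_p = poses["pelvis"]
        r_c, t_c = poses["corset"]
        hip_h = r_p @ human_model.joint("hip_flexion").parent_attach.translation + t_p
        hip_e = r_c @ exo_model.joint("exo_hip_flexion").parent_attach.translation + t_c
        assert abs(hip_h[0] - hip_e[0]) < 1e-9
        assert abs(hip_h[1] - hip_e[1]) < 1e-9

    def test_coincident_hip_centers_zero_offset(self, human_model, exo_model):
        coupled = couple_models(human_model, exo_model)
        np.testing.assert_allclose(
            coupled.pelvis_corset_offset.translation[:2], [0.0, 0.0], atol=1e-12
        )

    def test_static_posture_recovery(self, identity_subject):
        s = identity_subject
        coupled = assemble_coupled(
            s.human, s.exo, s.static_with_exo
        )
        for coord in coupled.human_coords:
            assert abs(coupled.static_posture[coord]) < 0.1  # truth: neutral stand
        assert coupled.static_ok

    def test_assembly_idempotence(self, identity_subject):
        s = identity_subject
        a = assemble_coupled(s.human, s.exo, s.static_with_exo)
        b = assemble_coupled(s.human, s.exo, s.static_with_exo)
        assert a.static_posture == b.static_posture
        assert a.frozen_hip == b.frozen_hip

    def test_poor_static_fit_flagged(self, identity_subject):
        s = identity_subject
        bad = {k: v + np.array([[0.03, -0.02, 0.01]]) * ((hash(k) % 5) - 2)
               for k, v in s.static_with_exo.data.items()}
        from exokin.trajectories import MarkerTrajectory
        corrupted = MarkerTrajectory(s.static_with_exo.time.copy(), bad)
        with pytest.warns(UserWarning, match="manual revision"):
            coupled = assemble_coupled(s.human, s.exo, corrupted)
        assert not coupled.static_ok
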