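"""Gait profiles, the soft-tissue surrogate, marker synthesis, file I/O."""

import numpy as np
import pytest

from exokin import (
    GaitProfileParams,
    SoftTissueParams,
    derive_exo_motion,
    generate_gait_profile,
    generate_subject,
    read_angles_csv,
    read_trc,
    soft_tissue_preset,
    synthesize_marker_data,
    write_angles_csv,
    write_trc,
)
from exokin.errors import SchemaError, ValidationError
from exokin.fileio import TRCParseError
from exokin.trajectories import JointTrajectory, MarkerTrajectory, SAGITTAL_CHANNELS


class TestGaitProfile:
    def test_default_sampling(self):
        v = generate_gait_profile(GaitProfileParams())
        assert v.n == 1000
        assert v.rate == pytest.approx(100.0)
        assert v.time[-1] == pytest.approx(9.99)

    def test_typical_slow_gait_ranges(self):
        v = generate_gait_profile(GaitProfileParams())
        hip, knee, ankle = (v.channel(c) for c in SAGITTAL_CHANNELS)
        assert -15 < hip.min() < 0 and 15 < hip.max() < 35
        assert -5 < knee.min() < 15 and 45 < knee.max() < 70
        assert -20 < ankle.min() < -5 and 0 < ankle.max() < 18

    def test_zero_amplitudes_constant(self):
        p = GaitProfileParams(fourier={c: (5.0, ()) for c in SAGITTAL_CHANNELS})
        v = generate_gait_profile(p)
        for c in SAGITTAL_CHANNELS:
            assert np.ptp(v.channel(c)) == 0.0
            assert v.channel(c)[0] == 5.0

    def test_deterministic(self):
        a = generate_gait_profile(GaitProfileParams())
        b = generate_gait_profile(GaitProfileParams())
        for c in SAGITTAL_CHANNELS:
            assert np.array_equal(a.channel(c), b.channel(c))

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            GaitProfileParams(duration=-1.0)


class TestSoftTissueSurrogate:
    def test_no_relative_motion_is_bitwise_identity(self):
        v = generate_gait_profile(GaitProfileParams())
        out = derive_exo_motion(v, SoftTissueParams())
        for c in SAGITTAL_CHANNELS:
            assert np.array_equal(out.channel(c), v.channel(c))

    def test_offset_only_shifts_one_channel(self):
        v = generate_gait_profile(GaitProfileParams())
        s = SoftTissueParams(offsets={"hip_flexion": 3.0, "knee_flexion": 0.0, "ankle_flexion": 0.0})
        out = derive_exo_motion(v, s)
        np.testing.assert_array_equal(out.channel("hip_flexion"), v.channel("hip_flexion") + 3.0)
        assert np.array_equal(out.channel("knee_flexion"), v.channel("knee_flexion"))
        assert np.array_equal(out.channel("ankle_flexion"), v.channel("ankle_flexion"))

    def test_gain_scales_range_exactly(self):
        v = generate_gait_profile(GaitProfileParams())
        s = SoftTissueParams(gains={"hip_flexion": 1.0, "knee_flexion": 0.9, "ankle_flexion": 1.0})
        out = derive_exo_motion(v, s)
        assert np.ptp(out.channel("knee_flexion")) == pytest.approx(
            0.9 * np.ptp(v.channel("knee_flexion")), abs=1e-12
        )

    def test_seeded_noise_reproducible(self):
        v = generate_gait_profile(GaitProfileParams())
        s = soft_tissue_preset("paper-like", seed=9)
        a = derive_exo_motion(v, s)
        b = derive_exo_motion(v, s)
        for c in SAGITTAL_CHANNELS:
            assert np.array_equal(a.channel(c), b.channel(c))

    def test_preset_targets_knee(self):
        s = soft_tissue_preset("paper-like")
        assert abs(s.offsets["knee_flexion"]) > abs(s.offsets["hip_flexion"])
        assert s.gains["knee_flexion"] < min(s.gains["hip_flexion"], s.gains["ankle_flexion"])


class TestMarkerSynthesis:
    def test_rigid_body_distances_constant(self, identity_subject):
        walk = identity_subject.walk_markers  # noiseless
        for pair in (("Mk8", "Mk9"), ("Mk4", "Mk5"), ("Mk0", "Mk2"), ("ExoKnee", "ExoThighMid")):
            d = np.linalg.norm(walk.data[pair[0]] - walk.data[pair[1]], axis=1)
            assert np.ptp(d) < 1e-12

    def test_fixed_seed_reproducible(self, identity_subject):
        s = identity_subject
        soft = soft_tissue_preset("paper-like", seed=3)
        a = synthesize_marker_data(s.coupled, s.v_H, s.v_R, soft)
        b = synthesize_marker_data(s.coupled, s.v_H, s.v_R, soft)
        for label in a.labels:
            assert np.array_equal(a.data[label], b.data[label])

    def test_length_mismatch_rejected(self, identity_subject):
        s = identity_subject
        short = JointTrajectory(s.v_R.time[:-5].copy(), {k: v[:-5] for k, v in s.v_R.channels.items()})
        with pytest.raises(SchemaError):
            synthesize_marker_data(s.coupled, s.v_H, short, SoftTissueParams())

    def test_walk_trial_drops_occluded_markers(self, identity_subject):
        labels = set(identity_subject.walk_markers.labels)
        assert {"Mk3", "Mk7", "Mk11"}.isdisjoint(labels)
        assert {"Mk0", "Mk1", "Mk2", "ExoHip", "ExoKnee"} <= labels

    def test_noise_increases_ik_error_monotonically(self):
        """Marker-IK angle error grows with marker noise over 0..2 mm."""
        from exokin.pipeline import process_subject
        from exokin import rmse

        errors = []
        for sigma in (0.0, 0.0005, 0.001, 0.002):
            soft = SoftTissueParams(marker_noise=sigma, seed=123)
            s = generate_subject(
                seed=21, gait=GaitProfileParams(duration=1.0), soft=soft
            )
            res = process_subject(s.static_no_exo, s.static_with_exo, s.walk_markers)
            err = np.mean(
                [rmse(res.gt.channel(c), s.v_H.channel(c)) for c in SAGITTAL_CHANNELS]
            )
            errors.append(err)
        assert all(b > a for a, b in zip(errors, errors[1:]))


class TestTRC:
    def test_round_trip(self, identity_subject, tmp_path):
        walk = identity_subject.walk_markers
        path = tmp_path / "walk.trc"
        write_trc(walk, path)
        back = read_trc(path)
        assert back.labels == walk.labels
        np.testing.assert_allclose(back.time, walk.time, atol=1e-9)
        for label in walk.labels:
            np.testing.assert_allclose(back.data[label], walk.data[label], atol=1e-9)  # 1e-6 mm

    def test_millimeter_conversion(self, tmp_path):
        traj = MarkerTrajectory(np.array([0.0]), {"A": np.array([[0.1, 0.0, 0.0]])})
        path = tmp_path / "one.trc"
        write_trc(traj, path)
        text = path.read_text()
        assert "100.00000000" in text  # stored in mm
        back = read_trc(path)
        np.testing.assert_allclose(back.data["A"], [[0.1, 0.0, 0.0]], atol=1e-12)

    def test_inconsistent_header_rejected(self, identity_subject, tmp_path):
        path = tmp_path / "bad.trc"
        write_trc(identity_subject.static_with_exo, path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace(f"\t{len(identity_subject.static_with_exo.labels)}\t", "\t99\t")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TRCParseError, match="line 4"):
            read_trc(path)

    def test_malformed_header_line_number(self, tmp_path):
        path = tmp_path / "junk.trc"
        path.write_text("not a trc\nx\ny\nz\nw\n")
        with pytest.raises(TRCParseError, match="line 1"):
            read_trc(path)


class TestAnglesCSV:
    def test_round_trip(self, identity_subject, tmp_path):
        path = tmp_path / "angles.csv"
        write_angles_csv(identity_subject.v_H, path)
        back = read_angles_csv(path)
        for c in SAGITTAL_CHANNELS:
            np.testing.assert_allclose(back.channel(c), identity_subject.v_H.channel(c), atol=1e-9)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,hip_flexion\n0.0,1.0\n0.01,2.0\n")
        with pytest.raises(SchemaError, match="knee_flexion"):
            read_angles_csv(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_angles_csv(path)

    def test_non_uniform_time_rejected(self, tmp_path):
        path = tmp_path / "warped.csv"
        path.write_text(
            "time,hip_flexion,knee_flexion,ankle_flexion\n0.0,1,2,3\n0.01,1,2,3\n0.03,1,2,3\n"
        )
        with pytest.raises(ValidationError):
            read_angles_csv(path)
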