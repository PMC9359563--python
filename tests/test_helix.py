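"""Helix detection, axis fitting, orientation labels, amphipathicity and
immersion depth."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import h8kit as hk
from conftest import apply_rigid, make_orientation_toy


class TestAssignHelices:
    def test_extended_chain_has_no_segments(self):
        s = hk.build_extended_chain("L" * 12, chain_id="A")
        assert hk.assign_helices(s, "A") == []

    def test_two_separated_helices_give_two_segments(self):
        a = hk.HelixSpec(sequence="L" * 10, chain_id="R", origin=(0, 0, 0))
        b = hk.HelixSpec(sequence="L" * 12, chain_id="R", origin=(20, 0, 0),
                         start_resnum=30)
        s, _ = hk.build_toy_complex(hk.ToyComplexSpec(receptor_helices=[a, b]))
        segments = hk.assign_helices(s, "R")
        assert [seg.length_residues for seg in segments] == [10, 12]

    def test_too_short_chain_rejected(self):
        s = hk.build_extended_chain("LLLL", chain_id="A")
        with pytest.raises(ValueError, match="fewer than 5"):
            hk.assign_helices(s, "A")


class TestHelixAxis:
    def test_axis_of_z_helix(self, ideal_helix):
        seg = hk.assign_helices(ideal_helix, "R")[0]
        assert np.abs(seg.axis - [0, 0, 1]).max() < 1e-3

    def test_reversed_residue_order_flips_sign(self, ideal_helix):
        reversed_chain = list(reversed(ideal_helix.chains["R"]))
        for i, r in enumerate(reversed_chain):
            r.number = i + 1
        s = hk.Structure(id="rev", chains={"R": reversed_chain})
        seg = hk.assign_helices(s, "R")[0]
        assert np.abs(seg.axis - [0, 0, -1]).max() < 1e-3

    def test_rotation_equivariance(self, ideal_helix):
        rot = Rotation.from_euler("zyx", [31, -12, 77], degrees=True).as_matrix()
        seg = hk.assign_helices(ideal_helix, "R")[0]
        rotated = apply_rigid(ideal_helix, rot, np.array([1.0, -2.0, 3.0]))
        seg_rot = hk.assign_helices(rotated, "R")[0]
        assert np.abs(seg_rot.axis - rot @ seg.axis).max() < 1e-6


class TestOrientation:
    def test_h8_along_reference_is_normal(self):
        s, (tm1, tm7, h8), mf = make_orientation_toy((1, 0, 0))
        report = hk.classify_h8_orientation(s, h8, tm7, tm1, mf)
        assert report.label == "normal"
        assert report.in_plane_angle_to_reference == pytest.approx(0.0, abs=1.0)
        assert report.tilt_to_membrane_plane == pytest.approx(0.0, abs=1.0)

    def test_h8_against_reference_is_inverted(self):
        s, (tm1, tm7, h8), mf = make_orientation_toy((-1, 0, 0))
        report = hk.classify_h8_orientation(s, h8, tm7, tm1, mf)
        assert report.label == "inverted"
        assert report.in_plane_angle_to_reference == pytest.approx(180.0, abs=1.0)

    def test_ninety_degree_boundary_labels_normal(self):
        s, (tm1, tm7, h8), mf = make_orientation_toy((0, 1, 0))
        report = hk.classify_h8_orientation(s, h8, tm7, tm1, mf)
        assert report.in_plane_angle_to_reference == pytest.approx(90.0, abs=1e-6)
        assert report.label == "normal"

    def test_axis_near_normal_is_degenerate(self):
        s, (tm1, tm7, h8), mf = make_orientation_toy((1, 0, 0))
        vertical = hk.HelixSegment(
            chain_id=h8.chain_id, start=h8.start, end=h8.end,
            axis=np.array([0.0, 0.0, 1.0]), anchor=h8.anchor,
            length_residues=h8.length_residues,
        )
        with pytest.raises(ValueError, match="degenerate projection"):
            hk.classify_h8_orientation(s, vertical, tm7, tm1, mf)


class TestAmphipathicity:
    def test_identical_residues_cancel_exactly(self, ideal_helix):
        """18 equal weights at 100 deg spacing sum to the zero vector."""
        seg = hk.assign_helices(ideal_helix, "R")[0]
        report = hk.amphipathicity(ideal_helix, seg, mode="sequence")
        assert report.hydrophobic_moment == pytest.approx(0.0, abs=1e-9)

    def test_structure_mode_agrees_with_sequence_mode_on_ideal_helix(self):
        h = hk.build_ideal_helix(hk.HelixSpec(sequence="LRSLTSHLRTLESLTSHL",
                                              chain_id="R"))
        seg = hk.assign_helices(h, "R")[0]
        mu_seq = hk.amphipathicity(h, seg, mode="sequence").hydrophobic_moment
        mu_3d = hk.amphipathicity(h, seg).hydrophobic_moment
        assert mu_3d == pytest.approx(mu_seq, rel=0.02)

    @staticmethod
    def _half_plane_helix():
        """In-plane helix whose hydrophobic residues all face +z (lipids)."""
        axis = (1.0, 0.0, 0.0)
        letters = []
        border_cos = np.cos(np.deg2rad(80.0))
        for k in range(18):
            p = np.sin(np.deg2rad(100.0 * k))  # u_k . z for this axis/frame
            if p > border_cos:
                letters.append("L")
            elif p < -border_cos:
                letters.append("S")
            else:
                letters.append("T")  # border band; counted in neither face
        spec = hk.HelixSpec(sequence="".join(letters), chain_id="R",
                            origin=(-10, 0, -17), axis=axis)
        helices = [
            spec,
            hk.HelixSpec(sequence="L" * 8, chain_id="R", origin=(30, 30, -10),
                         axis=(0, 0, 1), start_resnum=40),
        ]
        s, _ = hk.build_toy_complex(hk.ToyComplexSpec(receptor_helices=helices))
        seg = hk.assign_helices(s, "R")[0]
        mf = hk.estimate_membrane_frame(s)
        return s, seg, mf

    def test_half_plane_pattern_face_fractions(self):
        s, seg, mf = self._half_plane_helix()
        report = hk.amphipathicity(s, seg, mf)
        assert report.hydrophobic_fraction_lipid_face == 1.0
        assert report.hydrophobic_fraction_cytosol_face == 0.0

    def test_histidine_is_border_class(self):
        s, seg, mf = self._half_plane_helix()
        report = hk.amphipathicity(s, seg, mf)
        h = hk.build_ideal_helix(hk.HelixSpec(
            sequence="H" * 18, chain_id="R", origin=(-10, 0, -17),
            axis=(1, 0, 0)))
        s2 = hk.Structure(id="his", chains={"R": h.chains["R"]})
        seg2 = hk.assign_helices(s2, "R")[0]
        rep2 = hk.amphipathicity(s2, seg2, mf)
        assert all(face == "border" for face in rep2.per_residue_face.values())
        assert set(report.per_residue_face.values()) == {"lipid", "cytosol", "border"}

    def test_rigid_motion_leaves_moment_and_faces_invariant(self):
        s, seg, mf = self._half_plane_helix()
        before = hk.amphipathicity(s, seg, mf)
        rng = np.random.default_rng(4)
        rot = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = apply_rigid(s, rot, t)
        seg_m = hk.assign_helices(moved, "R")[0]
        after = hk.amphipathicity(moved, seg_m, mf.transformed(rot, t))
        assert after.hydrophobic_moment == pytest.approx(
            before.hydrophobic_moment, abs=1e-9)
        assert after.per_residue_face == before.per_residue_face


class TestImmersionDepth:
    def _helix_at(self, z: float) -> tuple[hk.Structure, object, object]:
        helices = [
            hk.HelixSpec(sequence="L" * 10, chain_id="R", origin=(0, 0, z),
                         axis=(1, 0, 0)),
        ]
        s, _ = hk.build_toy_complex(hk.ToyComplexSpec(receptor_helices=helices))
        seg = hk.assign_helices(s, "R")[0]
        mf = hk.estimate_membrane_frame(s)
        return s, seg, mf

    def test_helix_at_phosphoryl_level_has_near_zero_mean_depth(self):
        # residue COMs sit ~0.2 A off the CA axis level (backbone template
        # carbonyl offsets), so "zero depth" holds to a few tenths of an A
        s, seg, mf = self._helix_at(-18.0)
        depths, _ = hk.immersion_depth(s, seg, mf)
        assert np.mean(list(depths.values())) == pytest.approx(0.0, abs=0.5)

    def test_translation_along_normal_shifts_depth(self):
        s0, seg0, mf = self._helix_at(-18.0)
        s3, seg3, _ = self._helix_at(-15.0)
        d0, _ = hk.immersion_depth(s0, seg0, mf)
        d3, _ = hk.immersion_depth(s3, seg3, mf)
        shift = np.mean(list(d3.values())) - np.mean(list(d0.values()))
        assert shift == pytest.approx(3.0, abs=1e-9)

    def test_tilted_helix_terminal_depth_difference(self):
        helices = [hk.HelixSpec(sequence="L" * 10, chain_id="R",
                                origin=(0, 0, -18),
                                axis=(np.cos(0.3), 0, -np.sin(0.3)))]
        s, _ = hk.build_toy_complex(hk.ToyComplexSpec(receptor_helices=helices))
        seg = hk.assign_helices(s, "R")[0]
        mf = hk.estimate_membrane_frame(s)
        _, terminal_diff = hk.immersion_depth(s, seg, mf)
        # the axis drops 9 * 1.5 * sin(0.3) ~ 4 A from residue 1 to residue 10
        expected = 9 * 1.5 * np.sin(0.3)
        assert terminal_diff == pytest.approx(expected, abs=0.5)
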