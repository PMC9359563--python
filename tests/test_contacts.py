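"""Contact rule thresholds, map/occupancy correctness, difference maps."""

import numpy as np
import pytest

import h8kit as hk
from conftest import random_complex
from h8kit.model import AtomRecord, Residue, Structure


def _two_residue_structure(d_cb: float, d_ca: float) -> tuple[Residue, Residue]:
    """Two residues with prescribed CB-CB and CA-CA distances."""
    def residue(chain, num, ca, cb):
        return Residue(
            chain_id=chain, number=num, name3="GLU",
            atoms=[
                AtomRecord(1, "CA", "C", np.asarray(ca, float), 12.011),
                AtomRecord(2, "CB", "C", np.asarray(cb, float), 57.0),
            ],
        )
    a = residue("A", 1, (0, 0, 0), (0, 0, 1))
    b = residue("A", 2, (d_ca, 0, 0), (d_cb, 0, 1))
    return a, b


@pytest.mark.parametrize(
    "d_cb,d_ca,expected",
    [
        (7.9, 13.0, True),   # CB rule alone
        (9.0, 11.9, True),   # CA rule alone
        (9.0, 12.1, False),  # both exceeded
        (8.0, 12.0, True),   # boundaries are inclusive
    ],
)
def test_contact_rule_thresholds(d_cb, d_ca, expected):
    a, b = _two_residue_structure(d_cb, d_ca)
    assert hk.residue_contact(a, b) is expected


def test_glycine_uses_ca_for_the_cb_rule():
    a, b = _two_residue_structure(20.0, 7.0)
    a.name3 = b.name3 = "GLY"
    a.atoms = [a.atoms[0]]
    b.atoms = [b.atoms[0]]
    assert hk.residue_contact(a, b) is True  # CA-CA 7 A stands in for CB


def test_missing_ca_is_an_error():
    a, b = _two_residue_structure(5.0, 5.0)
    a.atoms = [a.atoms[1]]
    with pytest.raises(ValueError, match="no CA"):
        hk.residue_contact(a, b)


class TestContactMap:
    def test_diagonal_true_for_self_map(self, toy_complex):
        s, _ = toy_complex
        cmap = hk.contact_map(s, "chain R")
        assert cmap.matrix.diagonal().all()

    def test_symmetry_and_transpose(self, toy_complex):
        s, _ = toy_complex
        ab = hk.contact_map(s, "chain R", "chain A", mode="CB8_CA12")
        ba = hk.contact_map(s, "chain A", "chain R", mode="CB8_CA12")
        assert np.array_equal(ab.matrix, ba.matrix.T)
        self_map = hk.contact_map(s, "protein", mode="CB8_CA12")
        assert np.array_equal(self_map.matrix, self_map.matrix.T)

    def test_close_helices_all_cross_pairs_within_ca20(self):
        a = hk.HelixSpec(sequence="L" * 8, chain_id="R", origin=(0, 0, 0))
        b = hk.HelixSpec(sequence="L" * 8, chain_id="A", origin=(6, 0, 0))
        # side chains of 6-A-spaced helices interdigitate by construction
        s, _ = hk.build_toy_complex(
            hk.ToyComplexSpec(receptor_helices=[a], galpha_helix=b,
                              min_interchain_distance=1.2))
        cmap = hk.contact_map(s, "chain R", "chain A", mode="CA20")
        assert cmap.matrix.all()

    def test_distant_helices_no_ca20_pairs(self):
        a = hk.HelixSpec(sequence="L" * 8, chain_id="R", origin=(0, 0, 0))
        b = hk.HelixSpec(sequence="L" * 8, chain_id="A", origin=(40, 0, 0))
        s, _ = hk.build_toy_complex(
            hk.ToyComplexSpec(receptor_helices=[a], galpha_helix=b))
        cmap = hk.contact_map(s, "chain R", "chain A", mode="CA20")
        assert not cmap.matrix.any()

    def test_cutoff_monotonicity(self, toy_complex):
        s, _ = toy_complex
        small = hk.contact_map(s, "protein", mode="CA20", cutoff=12.0)
        large = hk.contact_map(s, "protein", mode="CA20", cutoff=20.0)
        assert (large.matrix | small.matrix).sum() == large.matrix.sum()

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_complexes(self, seed):
        """Vectorised maps equal a per-pair residue_contact / distance loop."""
        s = random_complex(seed)
        residues = [r for r in s.residues() if r.is_amino_acid]
        cb_map = hk.contact_map(s, "protein", mode="CB8_CA12")
        ca_map = hk.contact_map(s, "protein", mode="CA20")
        for i, ri in enumerate(residues):
            for j, rj in enumerate(residues):
                assert cb_map.matrix[i, j] == hk.residue_contact(ri, rj)
                d = np.linalg.norm(ri.atom("CA").coords - rj.atom("CA").coords)
                assert ca_map.matrix[i, j] == (d <= 20.0)

    def test_joined_numbering_offsets(self, toy_complex):
        s, _ = toy_complex
        cmap = hk.contact_map(s, "chain R", "chain A")
        rows, cols = cmap.joined_labels({"A": 450})
        assert rows[0] == 1
        assert cols[0] == 451

    def test_empty_selection_rejected(self, toy_complex):
        s, _ = toy_complex
        with pytest.raises(ValueError, match="no residues"):
            hk.contact_map(s, "chain R and resnum 900:950")


class TestOccupancyMap:
    def test_sigma_zero_occupancy_is_binary_and_equals_frame_zero(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=10, fluctuation_sigma=0.0))
        omap = hk.occupancy_map(traj, "protein", mode="CB8_CA12")
        cmap = hk.contact_map(s, "protein", mode="CB8_CA12")
        assert set(np.unique(omap.matrix)) <= {0.0, 1.0}
        assert np.array_equal(omap.matrix.astype(bool), cmap.matrix)

    def test_sigma_zero_occupancy_is_stride_independent(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=30, fluctuation_sigma=0.0))
        full = hk.occupancy_map(traj, "protein", mode="CB8_CA12", stride=1)
        strided = hk.occupancy_map(traj, "protein", mode="CB8_CA12", stride=10)
        assert np.array_equal(full.matrix, strided.matrix)
        assert strided.frames_used == 3

    def test_planted_formation_gives_half_occupancy(self, toy_complex):
        s, _ = toy_complex
        # R:18 and A:1 sit ~34 A apart at baseline, clearly out of contact
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(
                base=s, n_frames=100, fluctuation_sigma=0.05, seed=2,
                events=[hk.ContactEvent(("R", 18), ("A", 1), 50, 4.5)]))
        omap = hk.occupancy_map(traj, "chain R and resnum 18", "chain A and resnum 1",
                                mode="CB8_CA12")
        assert omap.matrix[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_stride_exhausting_frames_rejected(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=5, fluctuation_sigma=0.0))
        with pytest.raises(ValueError, match="at least 2 frames"):
            hk.occupancy_map(traj, "protein", stride=5)


class TestContactDifference:
    def test_map_vs_itself_is_empty(self, toy_complex):
        s, _ = toy_complex
        cmap = hk.contact_map(s, "protein", mode="CB8_CA12")
        assert hk.contact_difference(cmap, cmap) == []

    def test_three_changed_pairs_are_reported(self, toy_complex):
        s, _ = toy_complex
        a = hk.contact_map(s, "protein", mode="CB8_CA12")
        b = hk.ContactMap(
            row_residues=a.row_residues, col_residues=a.col_residues,
            matrix=a.matrix.copy(), cutoff=a.cutoff, mode=a.mode)
        flips = [(0, 37), (3, 20), (11, 30)]
        for i, j in flips:
            b.matrix[i, j] = not b.matrix[i, j]
        diff = hk.contact_difference(a, b, min_change=0.5)
        assert {(a.row_residues[i], a.col_residues[j]) for i, j in flips} == {
            (r, c) for r, c, _ in diff}

    def test_displaced_helix_dominates_first_vs_second_half(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(
                base=s, n_frames=60, fluctuation_sigma=0.05, seed=8,
                events=[hk.ContactEvent(("R", 4), ("A", 2), 30, 4.0)]))
        first = hk.Trajectory(topology=s, frames=traj.frames[:30],
                              times=traj.times[:30])
        second = hk.Trajectory(topology=s, frames=traj.frames[30:],
                               times=traj.times[30:])
        m1 = hk.occupancy_map(first, "protein", mode="CB8_CA12")
        m2 = hk.occupancy_map(second, "protein", mode="CB8_CA12")
        diff = hk.contact_difference(m1, m2, min_change=0.5)
        assert diff, "displacement must change at least one pair"
        top_rows = {r for r, c, _ in diff} | {c for r, c, _ in diff}
        assert ("A", 2, "") in top_rows

    def test_mismatched_lists_rejected(self, toy_complex):
        s, _ = toy_complex
        a = hk.contact_map(s, "chain R")
        b = hk.contact_map(s, "chain A")
        with pytest.raises(ValueError, match="different residue lists"):
            hk.contact_difference(a, b)
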