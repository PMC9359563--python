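"""COM distance series, salt bridges, triads and alternation counting."""

from itertools import combinations

import numpy as np
import pytest

import h8kit as hk
from conftest import make_triad_system


class TestComDistanceSeries:
    def test_constant_distance_for_static_pair(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=10, fluctuation_sigma=0.0))
        series = hk.com_distance_series(traj, ("R", 1), ("R", 10))
        assert np.allclose(series.values, series.values[0])

    def test_step_to_bound_distance_at_formation_frame(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(
                base=s, n_frames=100, fluctuation_sigma=0.1, seed=5,
                events=[hk.ContactEvent(("R", 1), ("A", 5), 50, 4.5)]))
        series = hk.com_distance_series(traj, ("R", 1), ("A", 5))
        assert series.values[49] > 6.0
        assert series.values[50:].mean() == pytest.approx(4.5, abs=0.1)

    def test_symmetric_in_arguments(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=5, fluctuation_sigma=0.2, seed=1))
        ab = hk.com_distance_series(traj, ("R", 2), ("A", 3))
        ba = hk.com_distance_series(traj, ("A", 3), ("R", 2))
        assert np.allclose(ab.values, ba.values)

    def test_same_residue_rejected(self, toy_complex):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=3, fluctuation_sigma=0.0))
        with pytest.raises(ValueError, match="differ"):
            hk.com_distance_series(traj, ("R", 1), ("R", 1))


class TestSaltBridges:
    def _traj_with_pair(self, d: float, names=("GLU", "LYS")):
        """Two single-CB residues whose side-chain COMs sit d apart."""
        from h8kit.model import AtomRecord, Residue, Structure

        def residue(chain, num, name3, x):
            return Residue(chain_id=chain, number=num, name3=name3, atoms=[
                AtomRecord(1, "CA", "C", np.array([x, 0.0, 0.0]), 12.011),
                AtomRecord(2, "CB", "C", np.array([x, 0.0, 1.5]), 60.0),
            ])
        s = Structure(id="pair", chains={
            "A": [residue("A", 1, names[0], 0.0)],
            "B": [residue("B", 1, names[1], d)],
        })
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=10, fluctuation_sigma=0.0))
        return traj

    def test_planted_glu_lys_pair_detected_with_full_occupancy(self):
        bridges = hk.detect_salt_bridges(self._traj_with_pair(4.0))
        assert bridges == [("A:1", "B:1", 1.0)]

    def test_like_charge_pair_not_reported(self):
        assert hk.detect_salt_bridges(self._traj_with_pair(4.0, ("GLU", "GLU"))) == []

    def test_pair_beyond_cutoff_absent(self):
        assert hk.detect_salt_bridges(self._traj_with_pair(9.0)) == []


def brute_force_triads(structure, charge_filter: bool):
    """Oracle: all-triples enumeration from per-pair residue_contact."""
    from h8kit.distances import CHARGED, NEGATIVE, POSITIVE

    residues = [r for r in structure.residues() if r.is_amino_acid]
    if charge_filter:
        residues = [r for r in residues if r.name3 in CHARGED]
    triads = set()
    for a, b, c in combinations(residues, 3):
        if len({a.chain_id, b.chain_id, c.chain_id}) < 2:
            continue
        if not (hk.residue_contact(a, b) and hk.residue_contact(a, c)
                and hk.residue_contact(b, c)):
            continue
        if charge_filter:
            signs = {"-" if r.name3 in NEGATIVE else "+" for r in (a, b, c)}
            if len(signs) < 2:
                continue
        triads.add(tuple(sorted([a.label, b.label, c.label])))
    return triads


class TestFindTriads:
    def test_planted_triad_is_the_only_record(self):
        traj, _, info = make_triad_system(seed=0)
        records = hk.find_triads(traj)
        assert len(records) == 1
        assert set(records[0].residues) == info["triad_labels"]
        assert sorted(records[0].charge_pattern) == ["+", "-", "-"]
        assert min(records[0].pair_occupancy) >= 0.8

    def test_planted_distances_recovered(self):
        traj, truth, info = make_triad_system(seed=3)
        rec = hk.find_triads(traj)[0]
        assert sorted(rec.pair_mean_distance) == pytest.approx(
            sorted(truth.triad.distances), abs=3 * info["sigma"])

    def test_displaced_chain_control_finds_nothing(self):
        """Moving the third helix 30 A away dissolves the triad."""
        traj, _, _ = make_triad_system(seed=4)
        frames = traj.frames.copy()
        slices = {r.id: idx for r, idx in traj.topology.residue_atom_slices()}
        for (chain, num, icode), idx in slices.items():
            if chain == "B":
                frames[:, idx, :] += np.array([0.0, 120.0, 0.0])
        moved = hk.Trajectory(topology=traj.topology, frames=frames,
                              times=traj.times)
        assert hk.find_triads(moved) == []

    @pytest.mark.parametrize("charge_filter", [True, False])
    def test_single_frame_equivalence_with_bruteforce(self, toy_complex, charge_filter):
        s, _ = toy_complex
        traj, _ = hk.synthesize_trajectory(
            hk.TrajectorySpec(base=s, n_frames=2, fluctuation_sigma=0.0))
        got = {tuple(sorted(r.residues))
               for r in hk.find_triads(traj, occupancy_min=1.0,
                                       charge_filter=charge_filter)}
        assert got == brute_force_triads(s, charge_filter)

    def test_triad_pairs_consistent_with_occupancy_map(self):
        """Cross-module consistency: every triad pair has occupancy >= 0.8
        in the pairwise CB8/CA12 occupancy map."""
        traj, _, _ = make_triad_system(seed=6)
        rec = hk.find_triads(traj)[0]
        omap = hk.occupancy_map(traj, "protein", mode="CB8_CA12")
        index = {f"{c}:{n}{i}": k for k, (c, n, i) in enumerate(omap.row_residues)}
        for a, b in combinations(rec.residues, 2):
            assert omap.matrix[index[a], index[b]] >= 0.8


class TestAlternation:
    def _traj_with_partner_pattern(self, offsets_a, offsets_b):
        """Partners A/B at per-frame x-offsets from a centre at the origin."""
        from h8kit.model import AtomRecord, Residue, Structure

        def residue(chain, num, name3, x):
            return Residue(chain_id=chain, number=num, name3=name3, atoms=[
                AtomRecord(1, "CA", "C", np.array([x, 0.0, 0.0]), 12.011),
                AtomRecord(2, "CB", "C", np.array([x, 0.0, 1.5]), 60.0),
            ])
        s = Structure(id="alt", chains={
            "K": [residue("K", 1, "LYS", 0.0)],
            "A": [residue("A", 1, "GLU", 5.0)],
            "B": [residue("B", 1, "GLU", -5.0)],
        })
        base = s.coords()
        n = len(offsets_a)
        frames = np.repeat(base[None, :, :], n, axis=0)
        frames[:, 2:4, 0] += np.asarray(offsets_a)[:, None]  # chain A atoms
        frames[:, 4:6, 0] += np.asarray(offsets_b)[:, None]  # chain B atoms
        traj = hk.Trajectory(topology=s, frames=frames,
                             times=np.arange(n, dtype=float))
        return traj

    def test_constant_nearest_partner_never_switches(self):
        traj = self._traj_with_partner_pattern([0.0] * 20, [-3.0] * 20)
        switches, labels = hk.alternation_events(traj, ("K", 1), (("A", 1), ("B", 1)))
        assert switches == 0

    def test_partner_swap_every_ten_frames_gives_nine_switches(self):
        offsets_a = [-3.0 if (f // 10) % 2 == 0 else 0.0 for f in range(100)]
        offsets_b = [0.0 if (f // 10) % 2 == 0 else 3.0 for f in range(100)]
        traj = self._traj_with_partner_pattern(offsets_a, offsets_b)
        switches, _ = hk.alternation_events(traj, ("K", 1), (("A", 1), ("B", 1)))
        assert switches == 9

    def test_exact_ties_are_sticky(self):
        traj = self._traj_with_partner_pattern([0.0] * 15, [10.0] * 15)
        switches, labels = hk.alternation_events(traj, ("K", 1), (("A", 1), ("B", 1)))
        assert switches == 0
        assert set(labels) == {0}
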