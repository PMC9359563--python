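"""Residue centre-of-mass distance series, salt bridges, charged triads
and partner-alternation counting.

"Centre of mass of an amino acid" is read as the mass-weighted centre of
its heavy atoms; salt-bridge detection uses side-chain-only centres, which
is the scope in which charge actually resides.  A triad is three residues
spanning at least two chains whose three pairs each satisfy the CB8/CA12
contact rule in a minimum fraction of frames; with the charge filter on,
all three must be charged (D, E, K, R, H — histidine counted positive) and
at least one pair must be of opposite charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .contacts import CA_CUTOFF, CB_CUTOFF
from .model import Residue, Structure, Trajectory

NEGATIVE = {"ASP", "GLU"}
POSITIVE = {"LYS", "ARG", "HIS"}
CHARGED = NEGATIVE | POSITIVE

ResidueKey = tuple[str, int]


@dataclass
class DistanceSeries:
    pair: tuple[str, str]  # residue labels, e.g. ("R:331", "A:216")
    values: np.ndarray  # A, per frame
    times: np.ndarray  # ns

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError("values/times length mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class TriadRecord:
    residues: tuple[str, str, str]  # labels
    pair_occupancy: tuple[float, float, float]  # (ab, ac, bc)
    pair_mean_distance: tuple[float, float, float]  # A, whole-residue COM
    pair_min_distance: tuple[float, float, float]
    alternation_count: int
    charge_pattern: tuple[str, str, str]  # "-", "+", "0"


def _charge(res: Residue) -> str:
    if res.name3 in NEGATIVE:
        return "-"
    if res.name3 in POSITIVE:
        return "+"
    return "0"


def _find_residue(structure: Structure, key: ResidueKey | str) -> Residue:
    if isinstance(key, str):
        chain, _, num = key.partition(":")
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        return structure.residue(chain, int(num), icode)
    return structure.residue(key[0], key[1])


def _com_series(traj: Trajectory, res: Residue, scope: str) -> np.ndarray:
    """Per-frame mass-weighted heavy-atom COM of one residue, (n_frames, 3)."""
    slices = {r.id: idx for r, idx in traj.topology.residue_atom_slices()}
    idx = slices[res.id]
    atoms = list(res.atoms)
    keep = []
    for local, a in enumerate(atoms):
        if a.element.upper() == "H":
            continue
        if scope == "sidechain" and a.name in ("N", "CA", "C", "O"):
            continue
        keep.append(local)
    if not keep and scope == "sidechain":
        keep = [local for local, a in enumerate(atoms) if a.name == "CA"]
    if not keep:
        raise ValueError(f"residue {res.label} has no heavy atoms in scope {scope!r}")
    sub = idx[keep]
    w = np.array([a.mass for i, a in enumerate(atoms) if i in set(keep)])
    xyz = traj.frames[:, sub, :]
    return (w[None, :, None] * xyz).sum(axis=1) / w.sum()


def com_distance_series(
    traj: Trajectory,
    res_a: ResidueKey | str,
    res_b: ResidueKey | str,
    atom_scope: str = "residue",
) -> DistanceSeries:
    """Per-frame distance between the centres of mass of two residues."""
    ra = _find_residue(traj.topology, res_a)
    rb = _find_residue(traj.topology, res_b)
    if ra is rb:
        raise ValueError("the two residues must differ")
    da = _com_series(traj, ra, atom_scope)
    db = _com_series(traj, rb, atom_scope)
    values = np.linalg.norm(da - db, axis=1)
    return DistanceSeries(pair=(ra.label, rb.label), values=values, times=traj.times.copy())


def _sidechain_com_stack(traj: Trajectory, residues: list[Residue], scope: str) -> np.ndarray:
    """(n_frames, n_residues, 3) COM stack for a residue list."""
    out = np.empty((traj.n_frames, len(residues), 3))
    for j, r in enumerate(residues):
        out[:, j, :] = _com_series(traj, r, scope)
    return out


def detect_salt_bridges(
    traj: Trajectory,
    cutoff: float = 6.0,
    occupancy_min: float = 0.5,
) -> list[tuple[str, str, float]]:
    """Oppositely charged residue pairs with side-chain COM within
    ``cutoff`` A in at least ``occupancy_min`` of frames.

    Returns (negative residue label, positive residue label, occupancy)
    sorted by decreasing occupancy, ties by residue labels.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    neg = [r for r in traj.topology.residues() if r.name3 in NEGATIVE]
    pos = [r for r in traj.topology.residues() if r.name3 in POSITIVE]
    if not neg or not pos:
        return []
    com_n = _sidechain_com_stack(traj, neg, "sidechain")
    com_p = _sidechain_com_stack(traj, pos, "sidechain")
    occ = np.zeros((len(neg), len(pos)))
    for f in range(traj.n_frames):
        occ += cdist(com_n[f], com_p[f]) <= cutoff
    occ /= traj.n_frames
    out = [
        (neg[i].label, pos[j].label, float(occ[i, j]))
        for i, j in zip(*np.nonzero(occ >= occupancy_min))
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def _contact_occupancy_matrix(traj: Trajectory, residues: list[Residue]) -> np.ndarray:
    """Pairwise CB8/CA12 contact occupancy over frames (square, symmetric)."""
    index = traj.topology.atom_index()
    ca_i, cb_i = [], []
    for r in residues:
        key = (r.chain_id, r.number, r.insertion_code, "CA")
        if key not in index:
            raise ValueError(f"residue {r.label} has no CA atom")
        ca_i.append(index[key])
        cb_i.append(index.get((r.chain_id, r.number, r.insertion_code, "CB"), index[key]))
    ca_i = np.array(ca_i)
    cb_i = np.array(cb_i)
    occ = np.zeros((len(residues), len(residues)))
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        occ += (cdist(xyz[cb_i], xyz[cb_i]) <= CB_CUTOFF) | (
            cdist(xyz[ca_i], xyz[ca_i]) <= CA_CUTOFF
        )
    return occ / traj.n_frames


def find_triads(
    traj: Trajectory,
    occupancy_min: float = 0.8,
    charge_filter: bool = True,
) -> list[TriadRecord]:
    """All residue triples spanning >= 2 chains whose three pairs each hold
    the CB8/CA12 contact in at least ``occupancy_min`` of frames.

    The 0.8 default operationalises residues staying "close to each other"
    over essentially a whole trajectory.  An empty list is a valid result.
    """
    residues = [r for r in traj.topology.residues() if r.is_amino_acid]
    if charge_filter:
        residues = [r for r in residues if r.name3 in CHARGED]
    if len(residues) < 3:
        return []
    occ = _contact_occupancy_matrix(traj, residues)
    adj = occ >= occupancy_min
    np.fill_diagonal(adj, False)

    records = []
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            common = np.nonzero(adj[i] & adj[j])[0]
            for k in common[common > j]:
                trio = (residues[i], residues[j], residues[int(k)])
                chains = {r.chain_id for r in trio}
                if len(chains) < 2:
                    continue
                charges = tuple(_charge(r) for r in trio)
                if charge_filter:
                    if "0" in charges:
                        continue
                    if len(set(charges)) < 2:  # need an opposite-charge pair
                        continue
                records.append(
                    _triad_record(traj, trio, occ, (i, j, int(k)), charges)
                )
    records.sort(key=lambda t: t.residues)
    return records


def _triad_record(
    traj: Trajectory,
    trio: tuple[Residue, Residue, Residue],
    occ: np.ndarray,
    idx: tuple[int, int, int],
    charges: tuple[str, str, str],
) -> TriadRecord:
    coms = [_com_series(traj, r, "residue") for r in trio]
    pairs = [(0, 1), (0, 2), (1, 2)]
    dists = [np.linalg.norm(coms[a] - coms[b], axis=1) for a, b in pairs]
    i, j, k = idx
    occs = (float(occ[i, j]), float(occ[i, k]), float(occ[j, k]))

    # alternation: if one residue's charge differs from the other two, it is
    # the centre and the like-charged pair are the alternating partners
    alternation = 0
    counts = {c: charges.count(c) for c in set(charges)}
    minority = [c for c, cnt in counts.items() if cnt == 1]
    if minority and len(set(charges)) == 2:
        centre_pos = charges.index(minority[0])
        partner_pos = [p for p in range(3) if p != centre_pos]
        labels = _nearest_partner_labels(
            _sc_series(traj, trio[centre_pos]),
            _sc_series(traj, trio[partner_pos[0]]),
            _sc_series(traj, trio[partner_pos[1]]),
        )
        alternation = int(np.sum(labels[1:] != labels[:-1]))
    return TriadRecord(
        residues=tuple(r.label for r in trio),
        pair_occupancy=occs,
        pair_mean_distance=tuple(float(d.mean()) for d in dists),
        pair_min_distance=tuple(float(d.min()) for d in dists),
        alternation_count=alternation,
        charge_pattern=charges,
    )


def _sc_series(traj: Trajectory, res: Residue) -> np.ndarray:
    return _com_series(traj, res, "sidechain")


def _nearest_partner_labels(
    centre: np.ndarray, partner0: np.ndarray, partner1: np.ndarray
) -> np.ndarray:
    """Per-frame nearest-partner labels (0/1) with a sticky tie rule: an
    exact tie keeps the previous frame's label (first frame defaults to 0)."""
    d0 = np.linalg.norm(centre - partner0, axis=1)
    d1 = np.linalg.norm(centre - partner1, axis=1)
    labels = np.zeros(len(d0), dtype=int)
    current = 0 if d0[0] <= d1[0] else 1
    labels[0] = current
    for f in range(1, len(d0)):
        if d0[f] < d1[f]:
            current = 0
        elif d1[f] < d0[f]:
            current = 1
        labels[f] = current
    return labels


def alternation_events(
    traj: Trajectory,
    center: ResidueKey | str,
    partners: tuple[ResidueKey | str, ResidueKey | str],
) -> tuple[int, np.ndarray]:
    """Count nearest-partner switches of ``center`` between two partners.

    The nearest partner (side-chain COM distance) is labelled per frame;
    exact ties keep the previous label.  Returns (switch count, labels).
    """
    rc = _find_residue(traj.topology, center)
    r0 = _find_residue(traj.topology, partners[0])
    r1 = _find_residue(traj.topology, partners[1])
    if rc is r0 or rc is r1 or r0 is r1:
        raise ValueError("center and partners must be three distinct residues")
    labels = _nearest_partner_labels(
        _sc_series(traj, rc), _sc_series(traj, r0), _sc_series(traj, r1)
    )
    switches = int(np.sum(labels[1:] != labels[:-1]))
    return switches, labels
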