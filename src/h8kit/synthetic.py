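"""Synthetic structures and trajectories with known ground truth.

Every analysis stage in this package is testable without downloading any
experimental data: ideal alpha-helices with controllable amphipathic
patterning, a toy receptor/Galpha/Gbeta complex with flat phosphoryl
pseudo-atom planes, and trajectories with isotropic Gaussian positional
fluctuation plus planted contact-formation events and a planted charged
triad.  Side chains are represented by a single CB pseudo-atom carrying
the residue's side-chain mass; no physical realism (force field, lipid
packing) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    BACKBONE_MASS,
    ONE_TO_THREE,
    RESIDUE_MASSES,
    AtomRecord,
    Residue,
    Structure,
    Trajectory,
    mass_of_element,
)

ResidueKey = tuple[str, int]  # (chain_id, residue number); no insertion codes here


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalised")
    return v / n


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal (u, v) spanning the plane normal to axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(ref - (ref @ axis) * axis)
    v = np.cross(axis, u)
    return u, v


@dataclass
class HelixSpec:
    """Geometry of an ideal alpha-helix.

    Defaults are the canonical alpha-helix parameters: 1.5 A rise and 100
    degrees twist per residue, CA at 2.3 A from the axis; the CB
    pseudo-atom sits ``sidechain_offset`` A radially beyond CA (absent for
    glycine).
    """

    sequence: str
    chain_id: str = "A"
    start_resnum: int = 1
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sidechain_offset: float = 1.5
    phase: float = 0.0  # degrees; rotates the whole side-chain pattern

    def __post_init__(self) -> None:
        if len(self.sequence) < 4:
            raise ValueError("helix needs at least 4 residues")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        bad = set(self.sequence) - set(ONE_TO_THREE)
        if bad:
            raise ValueError(f"unknown residue letters {sorted(bad)}")


# Schematic backbone template in local cylindrical coordinates relative to
# the CA of the same residue: (radius A, phase offset deg, axial offset A).
# Chosen to give chemically sane N-CA / CA-C / C-O / C(i)-N(i+1) distances
# on the default helix; only CA/CB geometry is used quantitatively by the
# analysis stages.
_BACKBONE_TEMPLATE = {
    "N": (1.60, -27.0, -0.85),
    "C": (1.65, 24.0, 0.95),
    "O": (2.00, 38.0, 1.20),
}


def build_ideal_helix(spec: HelixSpec) -> Structure:
    """Build an ideal helix as a single-chain structure.

    CA of residue k sits at ``origin + k*rise*axis`` displaced ``radius`` A
    radially at angle ``phase + k*twist``; N, C, O follow a rigid template
    and CB lies radially outward from CA by ``sidechain_offset``.
    """
    axis = _unit(spec.axis)
    origin = np.asarray(spec.origin, dtype=float)
    u, v = _perp_frame(axis)

    residues: list[Residue] = []
    serial = 0
    for k, letter in enumerate(spec.sequence):
        name3 = ONE_TO_THREE[letter]
        angle = np.deg2rad(spec.phase + k * spec.twist)
        radial = np.cos(angle) * u + np.sin(angle) * v
        tangential = -np.sin(angle) * u + np.cos(angle) * v
        ca = origin + k * spec.rise * axis + spec.radius * radial
        atoms: list[AtomRecord] = []

        def place(name: str, pos: np.ndarray, element: str, mass: float | None = None) -> None:
            nonlocal serial
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    coords=pos,
                    mass=mass if mass is not None else mass_of_element(element),
                )
            )

        r_n, ph_n, dz_n = _BACKBONE_TEMPLATE["N"]
        ang_n = np.deg2rad(spec.phase + k * spec.twist + ph_n)
        place("N", origin + (k * spec.rise + dz_n) * axis
              + r_n * (np.cos(ang_n) * u + np.sin(ang_n) * v), "N")
        place("CA", ca, "C")
        for name in ("C", "O"):
            r_t, ph_t, dz_t = _BACKBONE_TEMPLATE[name]
            ang_t = np.deg2rad(spec.phase + k * spec.twist + ph_t)
            place(name, origin + (k * spec.rise + dz_t) * axis
                  + r_t * (np.cos(ang_t) * u + np.sin(ang_t) * v),
                  "C" if name == "C" else "O")
        if name3 != "GLY":
            cb_mass = RESIDUE_MASSES[name3] - BACKBONE_MASS
            place("CB", ca + spec.sidechain_offset * radial, "C", mass=cb_mass)
        _ = tangential  # orientation bookkeeping; not needed for placement
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                number=spec.start_resnum + k,
                name3=name3,
                atoms=atoms,
            )
        )
    return Structure(id=f"helix-{spec.chain_id}", chains={spec.chain_id: residues})


def build_extended_chain(
    sequence: str,
    chain_id: str = "A",
    start_resnum: int = 1,
    spacing: float = 3.8,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> Structure:
    """A fully extended (straight-line CA trace) chain; a non-helix control."""
    d = _unit(direction)
    origin = np.asarray(origin, dtype=float)
    perp, _ = _perp_frame(d)
    residues = []
    serial = 0
    for k, letter in enumerate(sequence):
        name3 = ONE_TO_THREE[letter]
        ca = origin + k * spacing * d
        atoms = [
            AtomRecord(serial := serial + 1, "N", "N", ca - 1.2 * d + 0.5 * perp,
                       mass_of_element("N")),
            AtomRecord(serial := serial + 1, "CA", "C", ca, mass_of_element("C")),
            AtomRecord(serial := serial + 1, "C", "C", ca + 1.2 * d + 0.5 * perp,
                       mass_of_element("C")),
            AtomRecord(serial := serial + 1, "O", "O", ca + 1.4 * d + 1.6 * perp,
                       mass_of_element("O")),
        ]
        if name3 != "GLY":
            atoms.append(
                AtomRecord(serial := serial + 1, "CB", "C", ca + 1.5 * perp,
                           RESIDUE_MASSES[name3] - BACKBONE_MASS)
            )
        residues.append(Residue(chain_id=chain_id, number=start_resnum + k,
                                name3=name3, atoms=atoms))
    return Structure(id=f"extended-{chain_id}", chains={chain_id: residues})


@dataclass
class ToyComplexSpec:
    """A toy receptor/Galpha/Gbeta complex inside flat phosphoryl planes.

    Receptor helices go into chain R, the G-protein helices into chains A
    (Galpha) and B (Gbeta); two flat phosphoryl pseudo-atom planes are laid
    at the z-levels of ``membrane_z``.
    """

    receptor_helices: list[HelixSpec]
    galpha_helix: HelixSpec | None = None
    gbeta_helix: HelixSpec | None = None
    membrane_z: tuple[float, float] = (-18.0, 18.0)
    membrane_halfwidth: float = 30.0
    membrane_spacing: float = 10.0
    membrane_jitter: float = 0.0
    seed: int = 0
    min_interchain_distance: float = 2.0


@dataclass
class ComplexGroundTruth:
    """What was planted: every residue pair satisfying the contact rule."""

    contact_pairs: list[tuple[ResidueKey, ResidueKey]]
    interchain_contact_pairs: list[tuple[ResidueKey, ResidueKey]]
    membrane_levels: tuple[float, float]


def _contact_rule_bruteforce(structure: Structure) -> list[tuple[ResidueKey, ResidueKey]]:
    """All residue pairs with CB-CB <= 8 A or CA-CA <= 12 A (CA for Gly)."""
    items = []
    for r in structure.residues():
        if not r.is_amino_acid:
            continue
        ca = r.atom("CA")
        cb = r.atom("CB") or ca
        items.append((r, ca.coords, cb.coords))
    pairs = []
    for i in range(len(items)):
        ri, cai, cbi = items[i]
        for j in range(i + 1, len(items)):
            rj, caj, cbj = items[j]
            if (np.linalg.norm(cbi - cbj) <= 8.0
                    or np.linalg.norm(cai - caj) <= 12.0):
                pairs.append(((ri.chain_id, ri.number), (rj.chain_id, rj.number)))
    return pairs


def build_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, ComplexGroundTruth]:
    """Assemble the toy complex and record its ground-truth contact list.

    Raises if any two protein chains approach closer than
    ``min_interchain_distance`` (reporting the offending residue pair).
    """
    rng = np.random.default_rng(spec.seed)
    chains: dict[str, list[Residue]] = {}

    def add(helix_spec: HelixSpec, chain_id: str) -> None:
        helix_spec.chain_id = chain_id
        start = spec_start.get(chain_id, 1)
        helix_spec.start_resnum = max(helix_spec.start_resnum, start)
        built = build_ideal_helix(helix_spec)
        chains.setdefault(chain_id, []).extend(built.chains[chain_id])
        spec_start[chain_id] = chains[chain_id][-1].number + 5

    spec_start: dict[str, int] = {}
    for h in spec.receptor_helices:
        add(h, "R")
    if spec.galpha_helix is not None:
        add(spec.galpha_helix, "A")
    if spec.gbeta_helix is not None:
        add(spec.gbeta_helix, "B")

    # phosphoryl pseudo-atom planes, one chain per leaflet
    lo, hi = sorted(spec.membrane_z)
    grid = np.arange(-spec.membrane_halfwidth, spec.membrane_halfwidth + 1e-9,
                     spec.membrane_spacing)
    serial = 0
    for chain_id, z in (("P", lo), ("Q", hi)):
        residues = []
        num = 0
        for x in grid:
            for y in grid:
                num += 1
                serial += 1
                jitter = (rng.normal(0.0, spec.membrane_jitter, size=3)
                          if spec.membrane_jitter > 0 else np.zeros(3))
                residues.append(
                    Residue(
                        chain_id=chain_id,
                        number=num,
                        name3="PHO",
                        atoms=[AtomRecord(serial, "P", "P",
                                          np.array([x, y, z]) + jitter,
                                          mass_of_element("P"))],
                    )
                )
        chains[chain_id] = residues

    structure = Structure(id="toy-complex", chains=chains)

    # clash check between protein chains
    protein_chains = [c for c in ("R", "A", "B") if c in chains]
    for i, ci in enumerate(protein_chains):
        for cj in protein_chains[i + 1:]:
            xi = np.array([a.coords for r in chains[ci] for a in r.atoms])
            xj = np.array([a.coords for r in chains[cj] for a in r.atoms])
            d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(axis=2)
            dmin = float(np.sqrt(d2.min()))
            if dmin < spec.min_interchain_distance:
                ai, aj = np.unravel_index(int(d2.argmin()), d2.shape)
                ri = _residue_of_flat_atom(chains[ci], ai)
                rj = _residue_of_flat_atom(chains[cj], aj)
                raise ValueError(
                    f"chains {ci} and {cj} clash: {ri.label} vs {rj.label} at "
                    f"{dmin:.2f} A < {spec.min_interchain_distance} A"
                )

    pairs = _contact_rule_bruteforce(structure)
    inter = [(a, b) for a, b in pairs if a[0] != b[0]]
    return structure, ComplexGroundTruth(
        contact_pairs=pairs,
        interchain_contact_pairs=inter,
        membrane_levels=(lo, hi),
    )


def _residue_of_flat_atom(residues: list[Residue], flat_index: int) -> Residue:
    i = 0
    for r in residues:
        if flat_index < i + len(r.atoms):
            return r
        i += len(r.atoms)
    raise IndexError(flat_index)


@dataclass
class ContactEvent:
    """A contact-formation event: from ``formation_frame`` on, residue b is
    moved so that its (noiseless) whole-residue COM sits ``bound_distance``
    A from residue a's."""

    res_a: ResidueKey
    res_b: ResidueKey
    formation_frame: int
    bound_distance: float


@dataclass
class TriadSpec:
    """Three residues pinned at mutual COM distances for all frames."""

    residues: tuple[ResidueKey, ResidueKey, ResidueKey]
    distances: tuple[float, float, float]  # d12, d13, d23


@dataclass
class TrajectorySpec:
    base: Structure
    n_frames: int = 100
    fluctuation_sigma: float = 0.3
    dt_ns: float = 1.0
    events: list[ContactEvent] = field(default_factory=list)
    triad: TriadSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.fluctuation_sigma < 0:
            raise ValueError("fluctuation sigma must be non-negative")
        for ev in self.events:
            if not 0 <= ev.formation_frame < self.n_frames:
                raise ValueError("formation_frame outside trajectory")
            if ev.bound_distance < 2.0:
                raise ValueError("bound distance below 2 A is unphysical")
        if self.triad is not None and any(d < 2.0 for d in self.triad.distances):
            raise ValueError("triad distance below 2 A is unphysical")


@dataclass
class TrajectoryGroundTruth:
    seed: int
    fluctuation_sigma: float
    events: list[ContactEvent]
    triad: TriadSpec | None
    # noiseless planted COM distances per event, per frame
    event_distances: dict[int, np.ndarray]


def _residue_indices(structure: Structure) -> dict[ResidueKey, np.ndarray]:
    out = {}
    for r, idx in structure.residue_atom_slices():
        out[(r.chain_id, r.number)] = idx
    return out


def _com(coords: np.ndarray, idx: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses[idx]
    return (w[:, None] * coords[idx]).sum(axis=0) / w.sum()


def _triangle_targets(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                      d12: float, d13: float, d23: float) -> tuple[np.ndarray, np.ndarray]:
    """Positions for points 2 and 3 realising the requested distances while
    staying close to their original placement (point 1 fixed, triangle laid
    in the original three-point plane)."""
    e1 = _unit(p2 - p1)
    n = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(n) < 1e-9:  # collinear: pick any perpendicular plane
        n = np.cross(e1, [0.0, 0.0, 1.0])
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(e1, [0.0, 1.0, 0.0])
    e2 = _unit(np.cross(n, e1))
    if (p3 - p1) @ e2 < 0:
        e2 = -e2
    q2 = p1 + d12 * e1
    x = (d13**2 - d23**2 + d12**2) / (2 * d12)
    y2 = d13**2 - x**2
    if y2 < 0:
        raise ValueError("triad distances violate the triangle inequality")
    q3 = p1 + x * e1 + np.sqrt(y2) * e2
    return q2, q3


def synthesize_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Generate a trajectory over ``spec.base`` with planted ground truth.

    Each frame is the (event/triad-adjusted) base coordinates plus
    independent isotropic Gaussian noise of ``fluctuation_sigma`` per atom
    applied in the lab frame; the same seed gives bitwise-identical output.
    """
    base = spec.base
    rng = np.random.default_rng(spec.seed)
    masses = np.array([a.mass for a in base.atoms()])
    ridx = _residue_indices(base)
    base_xyz = base.coords()

    for ev in spec.events:
        for key in (ev.res_a, ev.res_b):
            if key not in ridx:
                raise KeyError(f"event residue {key} not in topology")
        if ev.res_a == ev.res_b:
            raise ValueError("event residues must differ")
    if spec.triad is not None:
        if len(set(spec.triad.residues)) != 3:
            raise ValueError("triad residues must be distinct")
        for key in spec.triad.residues:
            if key not in ridx:
                raise KeyError(f"triad residue {key} not in topology")

    # displaced (noiseless) base for frames after each event; triad holds in
    # all frames.  Displacements are rigid translations of whole residues.
    adjusted = base_xyz.copy()
    if spec.triad is not None:
        k1, k2, k3 = spec.triad.residues
        p1 = _com(adjusted, ridx[k1], masses)
        p2 = _com(adjusted, ridx[k2], masses)
        p3 = _com(adjusted, ridx[k3], masses)
        q2, q3 = _triangle_targets(p1, p2, p3, *spec.triad.distances)
        adjusted[ridx[k2]] += q2 - p2
        adjusted[ridx[k3]] += q3 - p3

    event_shift: list[np.ndarray] = []
    for ev in spec.events:
        com_a = _com(adjusted, ridx[ev.res_a], masses)
        com_b = _com(adjusted, ridx[ev.res_b], masses)
        delta = com_b - com_a
        d0 = np.linalg.norm(delta)
        direction = delta / d0 if d0 > 1e-9 else np.array([1.0, 0.0, 0.0])
        event_shift.append(com_a + ev.bound_distance * direction - com_b)

    frames = np.empty((spec.n_frames, base.n_atoms, 3))
    event_distances: dict[int, np.ndarray] = {
        i: np.empty(spec.n_frames) for i in range(len(spec.events))
    }
    for f in range(spec.n_frames):
        xyz = adjusted.copy()
        for i, ev in enumerate(spec.events):
            if f >= ev.formation_frame:
                xyz[ridx[ev.res_b]] += event_shift[i]
            event_distances[i][f] = np.linalg.norm(
                _com(xyz, ridx[ev.res_b], masses) - _com(xyz, ridx[ev.res_a], masses)
            )
        if spec.fluctuation_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.fluctuation_sigma, size=xyz.shape)
        frames[f] = xyz

    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ns
    traj = Trajectory(topology=base, frames=frames, times=times)
    truth = TrajectoryGroundTruth(
        seed=spec.seed,
        fluctuation_sigma=spec.fluctuation_sigma,
        events=list(spec.events),
        triad=spec.triad,
        event_distances=event_distances,
    )
    return traj, truth
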