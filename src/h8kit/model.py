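"""Core data model: atoms, residues, structures, trajectories, membrane frames.

Coordinates are in angstroms throughout, times in nanoseconds.  Residue
identity is the author identity ``(chain_id, number, insertion_code)``: no
internal renumbering is ever performed, so every report can be traced back
to the numbering of the source PDB entry or UniProt record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

# Average atomic masses (u) for the elements occurring in protein heavy
# atoms and the phosphoryl pseudo-atoms used for membrane planes.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# Average residue masses within a peptide chain (residue minus water).
RESIDUE_MASSES: dict[str, float] = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}

# Backbone share of the residue mass (= glycine, whose side chain is a
# single H); the remainder is lumped on the CB pseudo-atom in coarse models.
BACKBONE_MASS = RESIDUE_MASSES["GLY"]

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Names accepted for lipid/membrane pseudo-residues (phosphoryl planes).
PSEUDO_RESIDUES = ("PHO", "POP", "PC", "DUM")


def mass_of_element(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {element!r}") from None


@dataclass
class AtomRecord:
    """A single atom: serial, name, element, position (angstrom), mass (u)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.mass > 0:
            raise ValueError(f"atom {self.name}: mass must be positive, got {self.mass}")


@dataclass
class Residue:
    """A residue identified by author numbering within its chain."""

    chain_id: str
    number: int
    name3: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        known = set(RESIDUE_MASSES) | set(PSEUDO_RESIDUES)
        if self.name3 not in known:
            raise ValueError(
                f"residue {self.label}: unknown residue type {self.name3!r}"
            )

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.number}{self.insertion_code}"

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def is_amino_acid(self) -> bool:
        return self.name3 in RESIDUE_MASSES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self, scope: str = "residue") -> list[AtomRecord]:
        """Heavy atoms of the residue; ``scope`` is 'residue' or 'sidechain'.

        For glycine (no side-chain heavy atom) the side-chain scope falls
        back to CA so that distances remain defined.
        """
        heavy = [a for a in self.atoms if a.element.upper() != "H"]
        if scope == "residue":
            return heavy
        if scope == "sidechain":
            side = [a for a in heavy if a.name not in BACKBONE_ATOMS]
            if not side:
                side = [a for a in heavy if a.name == "CA"]
            return side
        raise ValueError(f"unknown atom scope {scope!r}")

    def com(self, scope: str = "residue") -> np.ndarray:
        """Mass-weighted centre of mass over heavy atoms."""
        atoms = self.heavy_atoms(scope)
        if not atoms:
            raise ValueError(f"residue {self.label} has no heavy atoms")
        w = np.array([a.mass for a in atoms])
        xyz = np.array([a.coords for a in atoms])
        return (w[:, None] * xyz).sum(axis=0) / w.sum()


@dataclass
class Structure:
    """A hierarchical chain -> residue -> atom coordinate set."""

    id: str
    chains: dict[str, list[Residue]]
    model_index: int = 1

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a structure must contain at least one chain")
        for cid, residues in self.chains.items():
            seen: set[tuple[str, int, str]] = set()
            for r in residues:
                if r.id in seen:
                    raise ValueError(f"duplicate residue {r.label} in chain {cid}")
                seen.add(r.id)

    def residues(self, chain: str | None = None) -> Iterator[Residue]:
        if chain is not None:
            yield from self.chains[chain]
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self) -> Iterator[AtomRecord]:
        for r in self.residues():
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def residue(self, chain_id: str, number: int, insertion_code: str = "") -> Residue:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure {self.id}")
        for r in self.chains[chain_id]:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"no residue {chain_id}:{number}{insertion_code}")

    def coords(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coordinate array shape {xyz.shape} does not match {self.n_atoms} atoms"
            )
        for a, row in zip(self.atoms(), xyz):
            a.coords = row.copy()

    def copy(self) -> "Structure":
        chains = {
            cid: [
                replace(r, atoms=[replace(a, coords=a.coords.copy()) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(id=self.id, chains=chains, model_index=self.model_index)

    def atom_index(self) -> dict[tuple[str, int, str, str], int]:
        """Map (chain, resnum, icode, atom name) -> flat atom index."""
        out: dict[tuple[str, int, str, str], int] = {}
        for i, (r, a) in enumerate(
            (r, a) for r in self.residues() for a in r.atoms
        ):
            out[(r.chain_id, r.number, r.insertion_code, a.name)] = i
        return out

    def residue_atom_slices(self) -> list[tuple[Residue, np.ndarray]]:
        """Per residue, the flat atom indices into ``coords()`` order."""
        out = []
        i = 0
        for r in self.residues():
            idx = np.arange(i, i + len(r.atoms))
            out.append((r, idx))
            i += len(r.atoms)
        return out


@dataclass
class Trajectory:
    """A frame stack over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in angstrom, ``times`` is in
    nanoseconds and strictly increasing; ``stride_applied`` records the
    sub-sampling already applied relative to the source file.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray
    stride_applied: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        """A copy of the topology carrying the coordinates of frame ``i``."""
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s

    def subsample(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            topology=self.topology,
            frames=self.frames[::stride].copy(),
            times=self.times[::stride].copy(),
            stride_applied=self.stride_applied * stride,
        )


@dataclass
class MembraneFrame:
    """Membrane coordinate frame from phosphoryl planes.

    ``normal`` is a unit vector pointing toward the extracellular side;
    the two levels are the per-leaflet mean projections of the phosphoryl
    atoms onto the normal, so positions between the levels are inside the
    bilayer and positions below the intracellular level are in the cytosol.
    """

    normal: np.ndarray
    intracellular_phosphoryl_level: float
    extracellular_phosphoryl_level: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")
        if not self.extracellular_phosphoryl_level > self.intracellular_phosphoryl_level:
            raise ValueError("extracellular level must exceed intracellular level")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Scalar projection of point(s) onto the membrane normal."""
        return np.asarray(points, dtype=float) @ self.normal

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "MembraneFrame":
        """The frame co-transformed with a rigid motion x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        normal = rotation @ self.normal
        shift = float(normal @ t)
        return MembraneFrame(
            normal=normal,
            intracellular_phosphoryl_level=self.intracellular_phosphoryl_level + shift,
            extracellular_phosphoryl_level=self.extracellular_phosphoryl_level + shift,
        )
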