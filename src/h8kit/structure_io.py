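"""Reading and writing structures/trajectories and the membrane frame.

PDB files are parsed with Biopython (author numbering, insertion codes and
HETATM records preserved); DCD and XTC frame stacks are read with the
MDAnalysis coordinate readers.  Membrane geometry follows the OPM
convention: the phosphoryl pseudo-atom planes of the two leaflets define a
unit normal and two reference levels along it.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .model import (
    ATOMIC_MASSES,
    AtomRecord,
    MembraneFrame,
    PSEUDO_RESIDUES,
    RESIDUE_MASSES,
    Residue,
    Structure,
    Trajectory,
    mass_of_element,
)
from .selection import Selection


class StructureIOError(RuntimeError):
    pass


def _prescan_pdb(path: Path) -> None:
    """Cheap validation pass that reports the line number of a bad record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureIOError(
                        f"{path}:{lineno}: truncated ATOM/HETATM record"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise StructureIOError(
                        f"{path}:{lineno}: malformed coordinate field in "
                        f"{line[:26]!r}"
                    ) from None


def _guess_element(atom_name: str, recorded: str) -> str:
    el = recorded.strip().upper()
    if el and el in ATOMIC_MASSES:
        return el
    name = atom_name.strip()
    if name[:2].upper() in ("SE",):
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model`` is 1-based (the first MODEL block is model 1; files without
    MODEL records have exactly one model).  Author residue numbering,
    insertion codes and HETATM pseudo-atoms are preserved; for altloc
    conformers the highest-occupancy one is kept, ties broken by altloc
    letter order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    _prescan_pdb(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # pragma: no cover - permissive parser
        raise StructureIOError(f"{path}: {exc}") from exc
    models = list(bio.get_models())
    if not 1 <= model <= len(models):
        raise StructureIOError(
            f"{path}: model {model} requested but file has {len(models)} model(s)"
        )
    biomodel = models[model - 1]

    chains: dict[str, list[Residue]] = {}
    for biochain in biomodel:
        residues: list[Residue] = []
        for biores in biochain:
            hetflag, resnum, icode = biores.get_id()
            name3 = biores.get_resname().strip()
            if name3 == "HOH":
                continue
            if name3 not in RESIDUE_MASSES and name3 not in PSEUDO_RESIDUES:
                # keep unknown HETATM ligands/lipids under a generic pseudo type
                name3 = "DUM"
            atoms: list[AtomRecord] = []
            for bioatom in biores:
                if bioatom.is_disordered():
                    alts = sorted(
                        bioatom.child_dict.items(),
                        key=lambda kv: (-(kv[1].get_occupancy() or 0.0), kv[0]),
                    )
                    bioatom = alts[0][1]
                element = _guess_element(bioatom.get_name(), bioatom.element or "")
                atoms.append(
                    AtomRecord(
                        serial=int(bioatom.get_serial_number() or 0),
                        name=bioatom.get_name(),
                        element=element,
                        coords=np.asarray(bioatom.get_coord(), dtype=float),
                        mass=mass_of_element(element),
                    )
                )
            residues.append(
                Residue(
                    chain_id=biochain.id.strip() or "A",
                    number=int(resnum),
                    insertion_code=icode.strip(),
                    name3=name3,
                    atoms=atoms,
                )
            )
        if residues:
            chains[biochain.id.strip() or "A"] = residues
    if not chains:
        raise StructureIOError(f"{path}: no residues parsed")
    return Structure(id=path.stem, chains=chains, model_index=model)


_PDB_ATOM = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file.

    Amino-acid residues become ATOM records, pseudo-residues (phosphoryl
    planes, ligands) become HETATM records; author numbering is preserved.
    """
    path = Path(path)
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in structure.chains.items():
            for r in residues:
                record = "ATOM" if r.is_amino_acid else "HETATM"
                for a in r.atoms:
                    serial += 1
                    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                    fh.write(
                        _PDB_ATOM.format(
                            record=record,
                            serial=serial,
                            name=name,
                            altloc=" ",
                            resname=r.name3,
                            chain=chain_id[:1] or "A",
                            resnum=r.number,
                            icode=r.insertion_code or " ",
                            x=a.coords[0],
                            y=a.coords[1],
                            z=a.coords[2],
                            occ=1.0,
                            b=0.0,
                            element=a.element[:2],
                        )
                    )
            fh.write("TER\n")
        fh.write("END\n")


def read_trajectory(
    topology: Structure,
    path: str | Path,
    stride: int = 1,
    time_unit: str | None = None,
) -> Trajectory:
    """Read a DCD/XTC frame stack over ``topology``, keeping every
    ``stride``-th frame (frame 0 always retained).

    MDAnalysis reports frame times in picoseconds for both formats; they
    are converted to nanoseconds here.  ``time_unit`` may be set to ``"ps"``
    or ``"ns"`` to override the assumed unit of the file's time axis for
    dialects with nonstandard headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trajectory file: {path}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        raise StructureIOError(f"unsupported trajectory format {suffix!r}")

    reader = Reader(str(path))
    if reader.n_atoms != topology.n_atoms:
        raise StructureIOError(
            f"{path}: trajectory has {reader.n_atoms} atoms but topology has "
            f"{topology.n_atoms}"
        )
    frames: list[np.ndarray] = []
    times: list[float] = []
    scale = {"ps": 1e-3, "ns": 1.0, None: 1e-3}[time_unit]
    try:
        for i, ts in enumerate(reader):
            if i % stride == 0:
                frames.append(ts.positions.astype(float).copy())
                times.append(float(ts.time) * scale)
    except (EOFError, OSError) as exc:
        raise StructureIOError(
            f"{path}: unreadable or truncated frame at index {len(frames)}"
        ) from exc
    finally:
        reader.close()
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        # some writers store zero/constant times; fall back to frame index
        warnings.warn(f"{path}: non-increasing frame times; using frame index as ns")
        times_arr = np.arange(len(frames), dtype=float) * stride
    return Trajectory(
        topology=topology,
        frames=np.asarray(frames),
        times=times_arr,
        stride_applied=stride,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as DCD (times become a uniform ps axis)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    path = Path(path)
    n_atoms = traj.frames.shape[1]
    dt_ns = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    universe = mda.Universe.empty(n_atoms, trajectory=True)
    with DCDWriter(str(path), n_atoms=n_atoms, dt=dt_ns * 1e3) as w:
        for frame in traj.frames:
            universe.atoms.positions = frame.astype(np.float32)
            w.write(universe.atoms)


def _two_means_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D 2-means: the sorted split minimising within-class SS."""
    order = np.argsort(values)
    v = values[order]
    n = len(v)
    csum = np.cumsum(v)
    css = np.cumsum(v * v)
    best, best_k = np.inf, 1
    for k in range(1, n):
        ss1 = css[k - 1] - csum[k - 1] ** 2 / k
        ss2 = (css[-1] - css[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        if ss1 + ss2 < best:
            best, best_k = ss1 + ss2, k
    lower = order[:best_k]
    upper = order[best_k:]
    return lower, upper


def estimate_membrane_frame(
    structure: Structure,
    phosphoryl_selection: str | Selection = "resname PHO",
    extracellular_selection: str | Selection | None = None,
    min_separation: float = 10.0,
) -> MembraneFrame:
    """Estimate the membrane normal and leaflet levels from phosphoryl atoms.

    The normal is the eigenvector of smallest covariance eigenvalue of the
    pooled phosphoryl coordinates (the direction in which two flat planes
    have least spread); the leaflets are separated by an exact 1-D 2-means
    split of the projections and the levels are the per-leaflet mean
    projections.  The sign is chosen so the extracellular side is positive:
    if ``extracellular_selection`` is given, its atoms' mean projection
    defines that side; otherwise the sign with non-negative z-component of
    the normal is used (deterministic default).
    """
    sel = (
        phosphoryl_selection
        if isinstance(phosphoryl_selection, Selection)
        else Selection(phosphoryl_selection)
    )
    pairs = sel.atoms(structure)
    if len(pairs) < 6:
        raise ValueError(
            f"need at least 6 phosphoryl atoms to define a membrane, got {len(pairs)}"
        )
    xyz = np.array([a.coords for _, a in pairs])
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / len(xyz)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest eigenvalue first for eigh

    proj = xyz @ normal
    lo_idx, hi_idx = _two_means_split(proj)
    if min(len(lo_idx), len(hi_idx)) < 3:
        raise ValueError("leaflet split leaves fewer than 3 atoms in one leaflet")
    lo, hi = proj[lo_idx].mean(), proj[hi_idx].mean()
    if hi - lo < min_separation:
        raise ValueError(
            f"degenerate membrane: leaflet separation {hi - lo:.2f} A "
            f"< {min_separation} A"
        )

    if extracellular_selection is not None:
        ref_sel = (
            extracellular_selection
            if isinstance(extracellular_selection, Selection)
            else Selection(extracellular_selection)
        )
        ref = np.array([a.coords for _, a in ref_sel.atoms(structure)])
        if len(ref) == 0:
            raise ValueError("extracellular reference selection is empty")
        flip = (ref @ normal).mean() < (lo + hi) / 2
    else:
        flip = normal[2] < 0 or (normal[2] == 0 and (normal[1] < 0 or
                                 (normal[1] == 0 and normal[0] < 0)))
    if flip:
        normal = -normal
        lo, hi = -hi, -lo
    return MembraneFrame(
        normal=normal / np.linalg.norm(normal),
        intracellular_phosphoryl_level=float(lo),
        extracellular_phosphoryl_level=float(hi),
    )
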