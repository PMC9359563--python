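"""Residue contact criteria, contact maps and trajectory occupancy maps.

Two residue-level criteria are supported:

* ``CB8_CA12`` — the residue-contact rule: two residues are in contact if
  their CB atoms are within 8 A or their CA atoms within 12 A (CA standing
  in for the missing CB of glycine).
* ``CA20`` — a plain CA-CA cutoff map (default 20 A), the convention used
  for whole-complex receptor/Galpha maps with joined sequence numbering.

An occupancy ("gradient") map is the per-pair fraction of trajectory
frames in contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model import Residue, Structure, Trajectory
from .selection import Selection

CB_CUTOFF = 8.0
CA_CUTOFF = 12.0
DEFAULT_CA_MAP_CUTOFF = 20.0

ResidueId = tuple[str, int, str]


def _rep_coords(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """(CA, CB-or-CA) coordinate arrays for a residue list."""
    ca = np.empty((len(residues), 3))
    cb = np.empty((len(residues), 3))
    for i, r in enumerate(residues):
        a_ca = r.atom("CA")
        if a_ca is None:
            raise ValueError(f"residue {r.label} has no CA atom")
        a_cb = r.atom("CB")
        ca[i] = a_ca.coords
        cb[i] = a_cb.coords if a_cb is not None else a_ca.coords
    return ca, cb


def residue_contact(res_a: Residue, res_b: Residue) -> bool:
    """True iff CB-CB <= 8 A or CA-CA <= 12 A (CA substituting for Gly CB)."""
    (ca, cb) = _rep_coords([res_a])
    (ca2, cb2) = _rep_coords([res_b])
    return bool(
        np.linalg.norm(cb[0] - cb2[0]) <= CB_CUTOFF
        or np.linalg.norm(ca[0] - ca2[0]) <= CA_CUTOFF
    )


@dataclass
class ContactMap:
    row_residues: list[ResidueId]
    col_residues: list[ResidueId]
    matrix: np.ndarray  # boolean
    cutoff: float
    mode: str

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.row_residues), len(self.col_residues)):
            raise ValueError("matrix shape does not match residue lists")

    def joined_labels(self, offsets: dict[str, int] | None = None) -> tuple[list[int], list[int]]:
        """Row/column integer labels under a joined numbering.

        ``offsets`` maps chain id -> additive offset; chains not listed get
        offset 0.  The convention for receptor + Galpha maps is to keep the
        receptor's UniProt numbering and shift the Galpha chain by a stated
        constant.
        """
        offsets = offsets or {}

        def lab(ids: list[ResidueId]) -> list[int]:
            return [num + offsets.get(chain, 0) for chain, num, _ in ids]

        return lab(self.row_residues), lab(self.col_residues)


@dataclass
class OccupancyMap:
    row_residues: list[ResidueId]
    col_residues: list[ResidueId]
    matrix: np.ndarray  # fractions in [0, 1]
    cutoff: float
    mode: str
    frames_used: int
    stride_ns: float

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.row_residues), len(self.col_residues)):
            raise ValueError("matrix shape does not match residue lists")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("occupancies must lie in [0, 1]")


def _resolve_residues(structure: Structure, sel: str | Selection | list[Residue]) -> list[Residue]:
    if isinstance(sel, list):
        return sel
    selection = sel if isinstance(sel, Selection) else Selection(sel)
    residues = [r for r in selection.residues(structure) if r.is_amino_acid]
    if not residues:
        raise ValueError(f"selection {selection.expression!r} matches no residues")
    return residues


def _pair_matrix(rows: list[Residue], cols: list[Residue], mode: str, cutoff: float) -> np.ndarray:
    ca_r, cb_r = _rep_coords(rows)
    ca_c, cb_c = _rep_coords(cols)
    if mode == "CA20":
        return cdist(ca_r, ca_c) <= cutoff
    if mode == "CB8_CA12":
        return (cdist(cb_r, cb_c) <= CB_CUTOFF) | (cdist(ca_r, ca_c) <= CA_CUTOFF)
    raise ValueError(f"unknown contact mode {mode!r}")


def contact_map(
    frame: Structure,
    rows: str | Selection | list[Residue] = "protein",
    cols: str | Selection | list[Residue] | None = None,
    mode: str = "CA20",
    cutoff: float = DEFAULT_CA_MAP_CUTOFF,
) -> ContactMap:
    """Single-frame boolean contact map between two residue selections."""
    row_res = _resolve_residues(frame, rows)
    col_res = row_res if cols is None else _resolve_residues(frame, cols)
    matrix = _pair_matrix(row_res, col_res, mode, cutoff)
    return ContactMap(
        row_residues=[r.id for r in row_res],
        col_residues=[r.id for r in col_res],
        matrix=matrix,
        cutoff=cutoff if mode == "CA20" else CB_CUTOFF,
        mode=mode,
    )


def occupancy_map(
    traj: Trajectory,
    rows: str | Selection | list[Residue] = "protein",
    cols: str | Selection | list[Residue] | None = None,
    mode: str = "CA20",
    cutoff: float = DEFAULT_CA_MAP_CUTOFF,
    stride: int = 1,
) -> OccupancyMap:
    """Per-pair fraction of (strided) frames in contact."""
    sub = traj.subsample(stride) if stride != 1 else traj
    if sub.n_frames < 2:
        raise ValueError("occupancy needs at least 2 frames after striding")
    top = sub.topology
    row_res = _resolve_residues(top, rows)
    col_res = row_res if cols is None else _resolve_residues(top, cols)

    # per-residue representative atom indices into flat coordinates
    index = top.atom_index()

    def rep_idx(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
        ca_i, cb_i = [], []
        for r in residues:
            key = (r.chain_id, r.number, r.insertion_code, "CA")
            if key not in index:
                raise ValueError(f"residue {r.label} has no CA atom")
            ca_i.append(index[key])
            cb_key = (r.chain_id, r.number, r.insertion_code, "CB")
            cb_i.append(index.get(cb_key, index[key]))
        return np.array(ca_i), np.array(cb_i)

    ca_r, cb_r = rep_idx(row_res)
    ca_c, cb_c = rep_idx(col_res)

    acc = np.zeros((len(row_res), len(col_res)))
    for f in range(sub.n_frames):
        xyz = sub.frames[f]
        if mode == "CA20":
            hit = cdist(xyz[ca_r], xyz[ca_c]) <= cutoff
        elif mode == "CB8_CA12":
            hit = (cdist(xyz[cb_r], xyz[cb_c]) <= CB_CUTOFF) | (
                cdist(xyz[ca_r], xyz[ca_c]) <= CA_CUTOFF
            )
        else:
            raise ValueError(f"unknown contact mode {mode!r}")
        acc += hit
    dt = float(sub.times[1] - sub.times[0]) if sub.n_frames > 1 else 0.0
    return OccupancyMap(
        row_residues=[r.id for r in row_res],
        col_residues=[r.id for r in col_res],
        matrix=acc / sub.n_frames,
        cutoff=cutoff if mode == "CA20" else CB_CUTOFF,
        mode=mode,
        frames_used=sub.n_frames,
        stride_ns=dt,
    )


def contact_difference(
    map_a: ContactMap | OccupancyMap,
    map_b: ContactMap | OccupancyMap,
    min_change: float = 0.5,
) -> list[tuple[ResidueId, ResidueId, float]]:
    """Residue pairs whose contact value changes by at least ``min_change``.

    Returns (row id, col id, delta = b - a) sorted by decreasing |delta|,
    ties broken by residue numbering.  Both maps must be over identical
    residue lists.
    """
    if (map_a.row_residues != map_b.row_residues
            or map_a.col_residues != map_b.col_residues):
        raise ValueError("contact maps cover different residue lists")
    delta = map_b.matrix.astype(float) - map_a.matrix.astype(float)
    out = []
    rows, cols = np.nonzero(np.abs(delta) >= min_change)
    for i, j in zip(rows, cols):
        out.append((map_a.row_residues[i], map_a.col_residues[j], float(delta[i, j])))
    out.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return out


def exclude_near_diagonal(
    cmap: ContactMap | OccupancyMap, min_separation: int = 3
) -> np.ndarray:
    """Mask that is False for self-pairs and |i-j| < min_separation
    neighbours within the same chain (trivially in contact, visual noise)."""
    mask = np.ones_like(cmap.matrix, dtype=bool)
    for i, (ci, ni, _) in enumerate(cmap.row_residues):
        for j, (cj, nj, _) in enumerate(cmap.col_residues):
            if ci == cj and abs(ni - nj) < min_separation:
                mask[i, j] = False
    return mask
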