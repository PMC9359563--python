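"""Helix detection, axis fitting, H8 orientation, amphipathicity and
membrane immersion.

Helix detection uses CA-geometry windows rather than hydrogen-bond
(DSSP-style) assignment so that coarse and synthetic models without
reliable backbone H-bond geometry are handled: residue i is helical when
|CA(i)-CA(i+3)| lies in [4.5, 5.5] A and |CA(i)-CA(i+4)| in [5.0, 6.5] A,
the windows of an ideal alpha-helix with generous margins.

The "inverted" H8 orientation of a GPCR is operationalised against an
in-membrane-plane reference direction drawn from the intracellular end of
TM7 to the intracellular end of TM1: an H8 axis within 90 degrees of that
reference is "normal", beyond it "inverted".  The amphipathicity report
computes the hydrophobic moment mu_H = |sum_k H_k u_k| over the Eisenberg
consensus scale, partitions residues into lipid-facing and cytosol-facing
faces via the membrane normal, and measures immersion depth relative to
the intracellular phosphoryl level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MembraneFrame, Residue, Structure

# CA(i)-CA(i+3) and CA(i)-CA(i+4) acceptance windows, angstrom
I3_WINDOW = (4.5, 5.5)
I4_WINDOW = (5.0, 6.5)

# Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Residues counted as hydrophobic for the face-composition fractions;
# histidine is treated as border-class and enters neither face.
HYDROPHOBIC_SET = set("AVLIMFWCP")

BORDER_HALF_ANGLE_DEG = 80.0  # |u . n| < cos(80 deg) => border


@dataclass
class HelixSegment:
    chain_id: str
    start: tuple[int, str]  # (residue number, insertion code)
    end: tuple[int, str]
    axis: np.ndarray  # unit, N->C sense
    anchor: np.ndarray  # CA centroid
    length_residues: int

    def __post_init__(self) -> None:
        if self.length_residues < 4:
            raise ValueError("a helix segment needs at least 4 residues")
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("segment axis must be a unit vector")


@dataclass
class OrientationReport:
    label: str  # "normal" | "inverted"
    in_plane_angle_to_reference: float  # degrees, [0, 180]
    tilt_to_membrane_plane: float  # degrees, [0, 90]


@dataclass
class AmphipathicityReport:
    hydrophobic_moment: float
    moment_direction: np.ndarray | None  # unit 3-vector (None in sequence mode)
    per_residue_face: dict[str, str]  # residue label -> lipid|cytosol|border
    hydrophobic_fraction_lipid_face: float
    hydrophobic_fraction_cytosol_face: float
    mean_immersion_depth: float  # A, signed


def _segment_residues(structure: Structure, segment: HelixSegment) -> list[Residue]:
    chain = structure.chains[segment.chain_id]
    keys = [(r.number, r.insertion_code) for r in chain]
    i0 = keys.index(segment.start)
    i1 = keys.index(segment.end)
    return chain[i0:i1 + 1]


def assign_helices(structure: Structure, chain: str) -> list[HelixSegment]:
    """Detect helical segments on one chain by CA-geometry windows.

    A residue window starting at i is helical if both the i/i+3 and i/i+4
    CA distances fall in the alpha-helical ranges; maximal runs of helical
    windows, extended to cover their full i..i+4 span, become segments.
    Residues lacking a CA atom break runs and are reported in a warning.
    """
    if chain not in structure.chains:
        raise KeyError(f"no chain {chain!r}")
    residues = structure.chains[chain]
    cas: list[np.ndarray | None] = []
    missing = []
    for r in residues:
        a = r.atom("CA")
        cas.append(None if a is None else a.coords)
        if a is None:
            missing.append(r.label)
    if sum(c is not None for c in cas) < 5:
        raise ValueError(f"chain {chain} has fewer than 5 residues with CA")
    if missing:
        warnings.warn(f"residues without CA treated as helix breaks: {missing}")

    n = len(residues)
    helical = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        window = cas[i:i + 5]
        if any(c is None for c in window):
            continue
        d3 = np.linalg.norm(window[0] - window[3])
        d4 = np.linalg.norm(window[0] - window[4])
        helical[i] = (I3_WINDOW[0] <= d3 <= I3_WINDOW[1]
                      and I4_WINDOW[0] <= d4 <= I4_WINDOW[1])

    segments = []
    i = 0
    while i < n:
        if not helical[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and helical[j + 1]:
            j += 1
        span = residues[i:j + 5]  # window i..j covers residues up to j+4
        if len(span) >= 4:
            segments.append(_fit_segment(structure, span))
        i = j + 1
    return segments


def _fit_segment(structure: Structure, span: list[Residue]) -> HelixSegment:
    axis, anchor = _axis_of(span)
    return HelixSegment(
        chain_id=span[0].chain_id,
        start=(span[0].number, span[0].insertion_code),
        end=(span[-1].number, span[-1].insertion_code),
        axis=axis,
        anchor=anchor,
        length_residues=len(span),
    )


def _axis_of(span: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Axis (unit, N->C sense) and CA centroid of a helical span.

    The axis is fitted from the local chord bisectors
    CA(k-1) + CA(k+1) - 2 CA(k), which point radially toward the helix
    axis (their axial components cancel): the axis is their
    smallest-variance direction.  Unlike a plain principal component of
    the CA cloud this is unbiased even when the span does not cover a
    whole number of turns.  Degenerate (near-straight) spans fall back to
    the CA principal direction.
    """
    cas = np.array([r.atom("CA").coords for r in span if r.atom("CA") is not None])
    if len(cas) < 4:
        raise ValueError("axis fit needs at least 4 CA atoms")
    anchor = cas.mean(axis=0)
    bis = cas[:-2] + cas[2:] - 2 * cas[1:-1]
    gram = bis.T @ bis
    eigvals, eigvecs = np.linalg.eigh(gram)
    # need two independent radial directions for the null space to be 1-D
    if eigvals[1] > 1e-6 * max(eigvals[2], 1.0):
        axis = eigvecs[:, 0]
    else:
        centered = cas - anchor
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if (cas[-1] - cas[0]) @ axis < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), anchor


def helix_axis(structure: Structure, segment: HelixSegment) -> HelixSegment:
    """Re-fit a segment's axis/anchor from current coordinates.

    The axis is the principal (largest-variance) direction of the CA
    coordinates, signed from the N-terminal toward the C-terminal CA.
    """
    span = _segment_residues(structure, segment)
    return _fit_segment(structure, span)


def _intracellular_end_ca(
    structure: Structure, segment: HelixSegment, membrane: MembraneFrame
) -> np.ndarray:
    """CA of the terminal residue with the smaller membrane-normal projection."""
    span = _segment_residues(structure, segment)
    first, last = span[0].atom("CA").coords, span[-1].atom("CA").coords
    return first if membrane.project(first) <= membrane.project(last) else last


def _in_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def classify_h8_orientation(
    structure: Structure,
    h8: HelixSegment,
    tm7: HelixSegment,
    tm1: HelixSegment,
    membrane: MembraneFrame,
) -> OrientationReport:
    """Label the H8 orientation as normal or inverted.

    The reference direction is the in-plane projection of (TM1
    intracellular-end CA - TM7 intracellular-end CA); H8 axes within 90
    degrees of it (inclusive) are "normal", beyond it "inverted".  The
    tilt is the angle of the H8 axis out of the membrane plane.
    """
    n = membrane.normal
    cos_to_normal = abs(float(h8.axis @ n))
    if cos_to_normal > np.cos(np.deg2rad(5.0)):
        raise ValueError(
            "degenerate projection: H8 axis within 5 degrees of the membrane normal"
        )
    ref = _in_plane(
        _intracellular_end_ca(structure, tm1, membrane)
        - _intracellular_end_ca(structure, tm7, membrane),
        n,
    )
    if np.linalg.norm(ref) < 1e-9:
        raise ValueError("TM1/TM7 intracellular ends give no in-plane reference")
    ref = ref / np.linalg.norm(ref)
    h8p = _in_plane(h8.axis, n)
    h8p = h8p / np.linalg.norm(h8p)
    angle = float(np.degrees(np.arccos(np.clip(ref @ h8p, -1.0, 1.0))))
    tilt = 90.0 - float(np.degrees(np.arccos(np.clip(cos_to_normal, -1.0, 1.0))))
    return OrientationReport(
        label="normal" if angle <= 90.0 else "inverted",
        in_plane_angle_to_reference=angle,
        tilt_to_membrane_plane=tilt,
    )


def _sidechain_centroid(res: Residue) -> np.ndarray | None:
    side = [a for a in res.atoms
            if a.element.upper() != "H" and a.name not in ("N", "CA", "C", "O")]
    if not side:
        return None
    w = np.array([a.mass for a in side])
    xyz = np.array([a.coords for a in side])
    return (w[:, None] * xyz).sum(axis=0) / w.sum()


def amphipathicity(
    structure: Structure,
    segment: HelixSegment,
    membrane: MembraneFrame | None = None,
    scale: dict[str, float] | None = None,
    mode: str = "structure",
) -> AmphipathicityReport:
    """Hydrophobic moment, face partition and immersion of a helix.

    In ``structure`` mode the per-residue unit vector u_k points from the
    helix axis to the residue's side-chain centroid, projected
    perpendicular to the axis; in ``sequence`` mode u_k is the ideal
    helical-wheel direction at 100 degrees per residue (no coordinates or
    membrane needed).  mu_H = |sum_k H_k u_k| with H_k from ``scale``
    (Eisenberg consensus by default).

    Residues whose unit vector lies within 10 degrees of the membrane
    plane are "border"; histidine is always border-class.  Face fractions
    are the hydrophobic share (A,V,L,I,M,F,W,C,P) of each face.
    """
    scale = scale or EISENBERG
    span = _segment_residues(structure, segment)
    for r in span:
        if r.one_letter not in scale:
            raise ValueError(f"no hydrophobicity value for residue {r.label} ({r.name3})")

    if mode == "sequence":
        vec = np.zeros(2)
        for k, r in enumerate(span):
            angle = np.deg2rad(100.0 * k)
            vec += scale[r.one_letter] * np.array([np.cos(angle), np.sin(angle)])
        return AmphipathicityReport(
            hydrophobic_moment=float(np.linalg.norm(vec)),
            moment_direction=None,
            per_residue_face={},
            hydrophobic_fraction_lipid_face=float("nan"),
            hydrophobic_fraction_cytosol_face=float("nan"),
            mean_immersion_depth=float("nan"),
        )
    if mode != "structure":
        raise ValueError(f"unknown amphipathicity mode {mode!r}")

    seg = helix_axis(structure, segment)
    axis, anchor = seg.axis, seg.anchor
    moment = np.zeros(3)
    faces: dict[str, str] = {}
    face_letters: dict[str, list[str]] = {"lipid": [], "cytosol": []}
    border_cos = np.cos(np.deg2rad(BORDER_HALF_ANGLE_DEG))
    for r in span:
        sc = _sidechain_centroid(r)
        if sc is None:
            warnings.warn(f"residue {r.label} has no side-chain atom; counted as border")
            faces[r.label] = "border"
            continue
        radial = sc - anchor
        radial = radial - (radial @ axis) * axis
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            faces[r.label] = "border"
            continue
        u = radial / norm
        moment += scale[r.one_letter] * u
        if membrane is None:
            faces[r.label] = "border"
            continue
        p = float(u @ membrane.normal)
        if r.one_letter == "H" or abs(p) < border_cos:
            faces[r.label] = "border"
        elif p > 0:
            faces[r.label] = "lipid"
            face_letters["lipid"].append(r.one_letter)
        else:
            faces[r.label] = "cytosol"
            face_letters["cytosol"].append(r.one_letter)

    def frac(letters: list[str]) -> float:
        if not letters:
            return float("nan")
        return sum(c in HYDROPHOBIC_SET for c in letters) / len(letters)

    mu = float(np.linalg.norm(moment))
    depth = float("nan")
    if membrane is not None:
        depths, _ = immersion_depth(structure, segment, membrane)
        depth = float(np.mean(list(depths.values())))
    return AmphipathicityReport(
        hydrophobic_moment=mu,
        moment_direction=moment / mu if mu > 1e-12 else None,
        per_residue_face=faces,
        hydrophobic_fraction_lipid_face=frac(face_letters["lipid"]),
        hydrophobic_fraction_cytosol_face=frac(face_letters["cytosol"]),
        mean_immersion_depth=depth,
    )


def immersion_depth(
    structure: Structure,
    segment: HelixSegment,
    membrane: MembraneFrame,
) -> tuple[dict[str, float], float]:
    """Signed per-residue immersion depths and the N-vs-C terminal
    difference.

    depth(residue) = projection of its whole-residue COM on the membrane
    normal minus the intracellular phosphoryl level; positive values are
    inside the bilayer (toward the lipids), negative toward the cytosol.
    The terminal difference depth(N-terminal) - depth(C-terminal) captures
    one helix end dipping deeper than the other.
    """
    span = _segment_residues(structure, segment)
    depths = {
        r.label: float(membrane.project(r.com("residue"))
                       - membrane.intracellular_phosphoryl_level)
        for r in span
    }
    vals = list(depths.values())
    return depths, vals[0] - vals[-1]
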