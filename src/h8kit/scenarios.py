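"""Ready-made synthetic study systems.

These builders assemble the standard test-bench systems used throughout
the package's validation: an orientation toy receptor (TM1/TM7 plus an H8
of chosen direction), a triad/event trajectory with exactly one planted
charged triad, random multi-helix complexes for oracle comparisons, a
half-plane amphipathic helix, and an ideal-geometry reconstruction of the
C5aR1 helix-8 sequence region.  They encode the package's reference
conditions once, so tests and reproduction scripts agree on them.
"""

from __future__ import annotations

import numpy as np

from .model import Structure
from .selection import Selection
from .structure_io import estimate_membrane_frame
from .helix import BORDER_HALF_ANGLE_DEG, assign_helices
from .sequences import bundled_c5ar_sequences, load_regions
from .synthetic import (
    ContactEvent,
    HelixSpec,
    ToyComplexSpec,
    TrajectorySpec,
    TriadSpec,
    build_extended_chain,
    build_ideal_helix,
    build_toy_complex,
    synthesize_trajectory,
)


def make_orientation_toy(h8_direction: tuple[float, float, float]):
    """A toy receptor with TM1 (x=+10), TM7 (x=-10) and an H8 along
    ``h8_direction`` near the intracellular leaflet.

    The intracellular reference direction (TM7 end -> TM1 end) is +x, so
    an H8 along +x is "normal" and along -x "inverted".  Returns
    (structure, [tm1, tm7, h8] segments, membrane frame).
    """
    d = np.asarray(h8_direction, dtype=float)
    d = d / np.linalg.norm(d)
    tm1 = HelixSpec(sequence="L" * 21, chain_id="R", origin=(10, 0, -15),
                    axis=(0, 0, 1))
    tm7 = HelixSpec(sequence="L" * 21, chain_id="R", origin=(-10, 0, -15),
                    axis=(0, 0, 1))
    h8 = HelixSpec(sequence="LRSLTSHLRT", chain_id="R",
                   origin=(-8, 8, -16), axis=tuple(d))
    structure, _ = build_toy_complex(
        ToyComplexSpec(receptor_helices=[tm1, tm7, h8])
    )
    membrane = estimate_membrane_frame(structure)
    segments = assign_helices(structure, "R")
    if len(segments) != 3:
        raise RuntimeError("orientation toy must yield exactly TM1, TM7, H8")
    return structure, segments, membrane


def make_triad_system(seed: int, n_frames: int = 100,
                      fluctuation_sigma: float = 0.25):
    """Three well-separated helices with exactly one planted charged triad
    (Glu on R, Glu on A, Lys on B at COM distances 5/6/7 A) and one planted
    contact-formation event between uncharged residues (frame 50, 4.5 A).

    Chains sit 30 A apart so that, apart from the planted interactions, no
    cross-chain residue pair satisfies the contact rule.  Returns
    (trajectory, ground truth, info dict).
    """
    rec = HelixSpec(sequence="LSTLTSLLSTETSLLSTL", chain_id="R",
                    origin=(0, 0, 0), axis=(0, 0, 1))
    ga = HelixSpec(sequence="ASTLLSTLETSLLSTA", chain_id="A",
                   origin=(30, 0, 0), axis=(0, 0, 1))
    gb = HelixSpec(sequence="ASTLKSTLLTSLLSTA", chain_id="B",
                   origin=(-30, 0, 0), axis=(0, 0, 1))
    base, _ = build_toy_complex(
        ToyComplexSpec(receptor_helices=[rec], galpha_helix=ga, gbeta_helix=gb,
                       membrane_z=(-40.0, 40.0))
    )
    triad = TriadSpec(residues=(("R", 11), ("A", 9), ("B", 5)),
                      distances=(5.0, 6.0, 7.0))
    event = ContactEvent(res_a=("R", 3), res_b=("A", 3),
                         formation_frame=n_frames // 2, bound_distance=4.5)
    spec = TrajectorySpec(base=base, n_frames=n_frames,
                          fluctuation_sigma=fluctuation_sigma,
                          events=[event], triad=triad, seed=seed)
    traj, truth = synthesize_trajectory(spec)
    info = {
        "triad_labels": {"R:11", "A:9", "B:5"},
        "event": event,
        "sigma": fluctuation_sigma,
    }
    return traj, truth, info


def random_complex(seed: int) -> Structure:
    """A random 2-4 helix complex (<= 200 residues) for oracle tests."""
    rng = np.random.default_rng(seed)
    n_helices = int(rng.integers(2, 5))
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    chain_ids = ["R", "A", "B", "C"][:n_helices]
    chains = {}
    for cid in chain_ids:
        length = int(rng.integers(8, 25))
        seq = "".join(rng.choice(letters, size=length))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        origin = tuple(rng.uniform(-15, 15, size=3))
        built = build_ideal_helix(
            HelixSpec(sequence=seq, chain_id=cid, origin=origin, axis=tuple(axis))
        )
        chains[cid] = built.chains[cid]
    return Structure(id=f"random-{seed}", chains=chains)


def make_half_plane_helix():
    """An in-plane helix whose hydrophobic residues (Leu) all point toward
    the lipids (+z) and whose polar residues (Ser) all point to the
    cytosol; residues in the 10-degree border band are Thr.

    Returns (structure, helix segment, membrane frame).
    """
    border_cos = np.cos(np.deg2rad(BORDER_HALF_ANGLE_DEG))
    letters = []
    for k in range(18):
        p = np.sin(np.deg2rad(100.0 * k))  # u_k . z for an x-axis helix
        if p > border_cos:
            letters.append("L")
        elif p < -border_cos:
            letters.append("S")
        else:
            letters.append("T")
    helix = HelixSpec(sequence="".join(letters), chain_id="R",
                      origin=(-10, 0, -17), axis=(1.0, 0.0, 0.0))
    anchor = HelixSpec(sequence="L" * 8, chain_id="R", origin=(30, 30, -10),
                       axis=(0, 0, 1), start_resnum=40)
    s, _ = build_toy_complex(ToyComplexSpec(receptor_helices=[helix, anchor]))
    seg = assign_helices(s, "R")[0]
    membrane = estimate_membrane_frame(s)
    return s, seg, membrane


def make_crystal_h8_reconstruction() -> Structure:
    """SYNTHETIC ideal-geometry reconstruction of the C5aR1 H8 region.

    The crystallographically resolved H8 residue range of C5aR1 (UniProt
    315-324, the span whose side chains the inactive-state structures
    resolve) is rebuilt as an ideal helix, flanked C-terminally by the
    following receptor residues in an extended conformation.  These are
    synthetic coordinates carrying the real sequence and numbering — a
    stand-in for the crystal coordinates themselves, suitable for
    exercising helix detection on the H8 sequence but not for any claim
    about the experimental geometry.
    """
    seq = bundled_c5ar_sequences()["P21730"].residues
    h8_span = next(r for r in load_regions()["P21730"] if r.name == "H8")
    h8_seq = seq[h8_span.start - 1:h8_span.end]
    tail_seq = seq[h8_span.end:h8_span.end + 8]

    helix = build_ideal_helix(
        HelixSpec(sequence=h8_seq, chain_id="R", start_resnum=h8_span.start,
                  origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0))
    )
    helix_end_z = (len(h8_seq) - 1) * 1.5
    tail = build_extended_chain(
        tail_seq, chain_id="R", start_resnum=h8_span.end + 1,
        origin=(6.0, 0.0, helix_end_z + 4.0), direction=(1.0, 0.0, 0.3),
    )
    residues = helix.chains["R"] + tail.chains["R"]
    return Structure(id="c5ar1-h8-synthetic", chains={"R": residues})
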