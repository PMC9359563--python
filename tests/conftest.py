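"""Shared fixtures: synthetic helices, toy complexes and trajectories.

Everything is generated programmatically; the heavier reference systems
live in :mod:`h8kit.scenarios` so that tests and the reproduction script
agree on the same study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import h8kit as hk
from h8kit.scenarios import (  # noqa: F401  (re-exported for tests)
    make_crystal_h8_reconstruction,
    make_half_plane_helix,
    make_orientation_toy,
    make_triad_system,
    random_complex,
)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    return rot, t


def apply_rigid(structure: hk.Structure, rot: np.ndarray, t: np.ndarray) -> hk.Structure:
    s = structure.copy()
    s.set_coords(structure.coords() @ rot.T + t)
    return s


@pytest.fixture
def ideal_helix() -> hk.Structure:
    """18-residue poly-Leu ideal helix along +z."""
    return hk.build_ideal_helix(hk.HelixSpec(sequence="L" * 18, chain_id="R"))


@pytest.fixture
def toy_complex() -> tuple[hk.Structure, object]:
    """Receptor/Galpha/Gbeta helices close enough for cross-chain contacts,
    inside phosphoryl planes at z = -18 / +18."""
    rec = hk.HelixSpec(sequence="LESLTSELRTLESLTSEL", chain_id="R",
                       origin=(0, 0, -12), axis=(0, 0, 1))
    ga = hk.HelixSpec(sequence="AESLKSHLAT", chain_id="A",
                      origin=(8, 0, -20), axis=(0, 0, 1))
    gb = hk.HelixSpec(sequence="AKSLESHLAT", chain_id="B",
                      origin=(-8, 0, -22), axis=(0, 0, 1))
    return hk.build_toy_complex(
        hk.ToyComplexSpec(receptor_helices=[rec], galpha_helix=ga, gbeta_helix=gb)
    )
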