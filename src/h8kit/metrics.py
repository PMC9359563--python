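"""Rigid-body superposition, selection-wise RMSD series and stabilization
time estimation.

Superposition is the least-squares optimal rigid motion (Kabsch); the
RMSD series fits each frame on one atom selection and measures the RMSD
over another without re-fitting, the standard way to ask "how much did
this sub-structure move relative to that frame of reference".  "Heavy
atom backbone" means the N, CA, C, O atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Structure, Trajectory
from .selection import Selection

BACKBONE_SELECTION = "name N CA C O"


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # applied as x -> R x + t
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    fit_selection: str
    measure_selection: str
    reference_id: str
    values: np.ndarray  # A
    times: np.ndarray  # ns

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError("values/times length mismatch")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("RMSD values must be non-negative")


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of ``mobile``
    onto ``reference`` (equal-length coordinate arrays, n >= 3,
    non-collinear).  The returned rmsd is the minimised value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    a = mobile - cm
    b = reference - cr
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set; rotation undetermined")
    rot, rssd = Rotation.align_vectors(b, a)
    matrix = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(len(mobile)))
    translation = cr - matrix @ cm
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit: str | Selection = BACKBONE_SELECTION,
    measure: str | Selection | None = None,
) -> RMSDSeries:
    """Per-frame RMSD over ``measure`` atoms after superposing on ``fit``
    atoms (no re-fitting on the measured set).

    With ``measure`` omitted the fit selection is measured, which equals a
    plain per-frame optimal-superposition RMSD.  The fit and measure
    selections must resolve to the same atoms on the reference and on the
    trajectory topology.
    """
    fit_sel = fit if isinstance(fit, Selection) else Selection(fit)
    measure_sel = (
        fit_sel if measure is None
        else measure if isinstance(measure, Selection) else Selection(measure)
    )
    fit_top = fit_sel.atom_indices(traj.topology)
    fit_ref = fit_sel.atom_indices(reference)
    mea_top = measure_sel.atom_indices(traj.topology)
    mea_ref = measure_sel.atom_indices(reference)
    if len(fit_top) != len(fit_ref) or len(mea_top) != len(mea_ref):
        raise ValueError(
            "selection resolves to different atom counts on reference and topology"
        )
    if len(fit_top) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    if len(mea_top) == 0:
        raise ValueError("measure selection is empty")
    ref_xyz = reference.coords()
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        sup = superpose(xyz[fit_top], ref_xyz[fit_ref])
        moved = sup.apply(xyz[mea_top])
        diff = moved - ref_xyz[mea_ref]
        values[f] = np.sqrt((diff * diff).sum() / len(mea_top))
    return RMSDSeries(
        fit_selection=fit_sel.expression,
        measure_selection=measure_sel.expression,
        reference_id=reference.id,
        values=values,
        times=traj.times.copy(),
    )


def stabilization_time(
    series: RMSDSeries,
    window: int = 50,
    tolerance: float = 0.5,
) -> float | None:
    """Earliest time from which every windowed mean stays within
    ``tolerance`` of the final windowed mean.

    The series is scanned with a sliding mean of ``window`` frames; the
    returned time is that of the first frame of the earliest window w such
    that all windowed means from w onward lie within +/- tolerance of the
    last window's mean.  If only the final window satisfies this (the
    criterion is then vacuous, as for a monotonically drifting series),
    ``None`` is returned ("not stabilized").
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    v = series.values
    if window > len(v):
        raise ValueError("window exceeds series length")
    kernel = np.ones(window) / window
    means = np.convolve(v, kernel, mode="valid")  # means[j] = mean of v[j:j+window]
    final = means[-1]
    ok = np.abs(means - final) <= tolerance
    # suffix_all[j] = all means from j onward within tolerance
    suffix_all = np.flip(np.logical_and.accumulate(np.flip(ok)))
    candidates = np.nonzero(suffix_all)[0]
    j = int(candidates[0])
    if j >= len(means) - 1 and len(means) > 1:
        return None
    return float(series.times[j])
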