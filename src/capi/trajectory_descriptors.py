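"""Descriptors over multi-model ensembles: RMSF, distance series, smoothing.

The two descriptors that matter for the GCAP1 conformational-switch story
are (i) per-residue root-mean-square fluctuation of the C-alpha trace after
rigid-body superposition and (ii) inter-residue distance time series — in
particular the C-alpha(D168)-C-alpha(R178) distance, a compact readout of
the "twisted accordion" transition between the calcium-loaded (inhibitor)
and magnesium-loaded (activator) states.  Distance traces are smoothed with
a centered running mean/SD over 100 frames (1 ns at a 10-ps stride).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from capi.structure_io import StructureModel, TrajectoryEnsemble, select
from capi.geometry_core import ring_centroid, TRP_RING_6, PHE_TYR_RING, ARG_CATION_ATOM


class DegenerateFitError(ValueError):
    """Superposition selection is too small or collinear."""


class SelectionError(LookupError):
    """A point specification could not be resolved in the ensemble."""


@dataclass
class RMSFProfile:
    """Per-atom RMSF (Angstrom) with the residue numbers of the selected atoms."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray  # Angstrom, >= 0

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_numbers.shape != self.rmsf.shape:
            raise ValueError("residue_numbers and rmsf lengths differ")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")


@dataclass
class DistanceSeries:
    """A per-frame distance trace plus its running mean/SD."""

    label_a: str
    label_b: str
    times: np.ndarray  # ps
    values: np.ndarray  # Angstrom
    smoothed_mean: np.ndarray
    smoothed_sd: np.ndarray
    window: int


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with a proper rotation matrix R (det = +1) and
    translation t such that ``mobile @ R.T + t`` best matches the reference;
    the RMSD is over the fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have equal shapes")
    idx = np.arange(mobile.shape[0]) if fit_selection is None else np.asarray(fit_selection, dtype=int)
    if idx.size < 3:
        raise DegenerateFitError("need >=3 fit atoms")
    mob = mobile[idx]
    ref = reference[idx]
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of the centered selection
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateFitError("fit selection is collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def _superpose_all(frames: np.ndarray, reference: np.ndarray, sel: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for k in range(frames.shape[0]):
        R, t, _ = superpose(frames[k], reference, sel)
        out[k] = frames[k] @ R.T + t
    return out


def rmsf(
    traj: TrajectoryEnsemble,
    selection: Sequence[int] | None = None,
    ref: str = "mean",
) -> RMSFProfile:
    """Per-atom RMSF of the selected atoms after superposition.

    ``ref="mean"`` (default) superposes every frame onto the iteratively
    refined mean structure (two refinement passes); ``ref="first"``
    superposes onto the first frame, the convention of the common MD
    utilities.  RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = (np.array([i for i, a in enumerate(traj.reference.atoms) if a.atom_name == "CA"], dtype=int)
           if selection is None else np.asarray(selection, dtype=int))
    if sel.size < 3:
        raise DegenerateFitError("selection must contain >=3 atoms")
    frames = traj.frames
    if ref == "first":
        aligned = _superpose_all(frames, frames[0], sel)
    elif ref == "mean":
        target = frames[0]
        aligned = frames
        for _ in range(2):
            aligned = _superpose_all(frames, target, sel)
            target = aligned.mean(axis=0)
        aligned = _superpose_all(frames, target, sel)
    else:
        raise ValueError("ref must be 'mean' or 'first'")
    coords = aligned[:, sel, :]
    mean = coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    res = np.array([traj.reference.atoms[i].residue_number for i in sel], dtype=int)
    return RMSFProfile(residue_numbers=res, rmsf=fluct)


# ---------------------------------------------------------------------------
# point specifications for distance series

_SIDECHAIN_POINT = {
    "TRP": ("ring", TRP_RING_6),
    "PHE": ("ring", PHE_TYR_RING),
    "TYR": ("ring", PHE_TYR_RING),
    "ARG": ("atom", (ARG_CATION_ATOM,)),
}


def _resolve_point_indices(model: StructureModel, spec: str) -> tuple[np.ndarray, str]:
    """Resolve ``"chain:resnum:atom"`` / ``:ring`` / ``:sidechain`` to atom indices.

    Returns the index array (the point is the mean of their positions) and a
    human-readable label.
    """
    parts = spec.split(":")
    if len(parts) == 2:
        parts.append("CA")
    if len(parts) != 3:
        raise SelectionError(f"bad point spec {spec!r} (want chain:resnum[:atom|ring|sidechain])")
    chain, resnum_s, kind = parts
    resnum = int(resnum_s)
    residue = [ (i, a) for i, a in enumerate(model.atoms)
                if a.chain_id == chain and a.residue_number == resnum ]
    if not residue:
        raise SelectionError(f"no residue {chain}:{resnum} in model")
    res_name = residue[0][1].residue_name
    if kind == "sidechain":
        mode, names = _SIDECHAIN_POINT.get(res_name, ("atom", ("CA",)))
    elif kind == "ring":
        mode, names = _SIDECHAIN_POINT.get(res_name, ("ring", TRP_RING_6))
    else:
        mode, names = "atom", (kind,)
    idx = np.array([i for i, a in residue if a.atom_name in names], dtype=int)
    if idx.size == 0 or (mode == "ring" and idx.size < 3):
        raise SelectionError(f"cannot resolve point {spec!r}: atoms {names} missing "
                             f"in {res_name} {chain}:{resnum}")
    label = f"{chain}:{res_name}{resnum}:{kind}"
    return idx, label


def running_stats(series: Sequence[float], window: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Centered running mean and population SD with truncated edge windows.

    At index i the window is ``[i - (window-1)//2, i + window//2]`` clipped
    to the series; interior windows hold exactly ``window`` points, edge
    windows all available points within the half-window.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return x.copy(), np.zeros(n)
    lo = np.maximum(np.arange(n) - (window - 1) // 2, 0)
    hi = np.minimum(np.arange(n) + window // 2, n - 1) + 1  # exclusive
    # center globally before the cumsum trick: the window variance is
    # shift-invariant and this avoids catastrophic cancellation
    shift = x.mean()
    xc = x - shift
    cs = np.concatenate([[0.0], np.cumsum(xc)])
    cs2 = np.concatenate([[0.0], np.cumsum(xc * xc)])
    cnt = (hi - lo).astype(float)
    mean_c = (cs[hi] - cs[lo]) / cnt
    var = (cs2[hi] - cs2[lo]) / cnt - mean_c**2
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean_c + shift, sd


def distance_series(
    traj: TrajectoryEnsemble,
    point_a: str,
    point_b: str,
    window: int = 100,
) -> DistanceSeries:
    """Per-frame Euclidean distance between two point specs, with smoothing.

    A point spec is ``"chain:resnum"`` (C-alpha), ``"chain:resnum:NAME"`` (a
    named atom), ``"chain:resnum:ring"`` (aromatic-ring centroid) or
    ``"chain:resnum:sidechain"`` (ring centroid for TRP/PHE/TYR, CZ for ARG,
    C-alpha otherwise).
    """
    idx_a, lab_a = _resolve_point_indices(traj.reference, point_a)
    idx_b, lab_b = _resolve_point_indices(traj.reference, point_b)
    pa = traj.frames[:, idx_a, :].mean(axis=1)
    pb = traj.frames[:, idx_b, :].mean(axis=1)
    d = np.linalg.norm(pa - pb, axis=1)
    w = min(window, d.size)
    mean, sd = running_stats(d, w)
    return DistanceSeries(label_a=lab_a, label_b=lab_b, times=traj.times.copy(),
                          values=d, smoothed_mean=mean, smoothed_sd=sd, window=w)


def twisted_accordion(traj: TrajectoryEnsemble, chain: str = "A", window: int = 100) -> DistanceSeries:
    """C-alpha(168)-C-alpha(178) distance trace, the accordion-switch readout."""
    return distance_series(traj, f"{chain}:168:CA", f"{chain}:178:CA", window=window)
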