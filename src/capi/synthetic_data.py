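"""Seeded generators for every input class, with exactly planted ground truth.

Each generator is a deterministic function of its arguments (including the
seed) and has a closed-form relationship to the analysis operation that
consumes it: planted (theta, phi, d) triples round-trip through the
cation-pi measurement, planted per-atom amplitudes equal the expected RMSF,
planted ITC/melt parameters are recoverable by the fitters.

Geometric feasibility of (theta, phi)
-------------------------------------
Aromatic hydrogens lie in the ring plane, so the angle phi between the
centroid-to-cation direction (polar angle theta from the normal) and any
in-plane H direction is constrained to [90 - theta, 90 + theta] degrees.
Pairs outside that band are not realizable by any in-plane hydrogen
placement and raise :class:`ParameterError`.  The generator emits a single
planted aromatic H at the azimuth that realizes phi exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from capi.structure_io import AtomRecord, StructureModel, TrajectoryEnsemble, write_pdb
from capi.geometry_core import RingSpec, TRP_RING_6, PHE_TYR_RING
from capi.binding_thermo import ITCModel, ITCSchedule, Thermogram, predict_heats
from capi.spectro_fits import CDSpectrum, MeltCurve, hill_sigmoid

RING_RADIUS = 1.40  # Angstrom, aromatic carbon hexagon
H_RADIUS = 2.48  # Angstrom, aromatic H distance from ring center


class ParameterError(ValueError):
    """Generator parameters out of range or geometrically infeasible."""


class InfeasibleGeometryError(ParameterError):
    """A requested bridge geometry cannot be realized without atom clashes."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator settings used by the CLI ``synth`` verb."""

    seed: int = 0
    sigma_itc_ucal: float = 0.1
    sigma_melt_mdeg: float = 0.3
    sigma_traj_A: float = 0.346
    n_frames: int = 2000
    decoys: int = 0


def _hexagon(radius: float) -> np.ndarray:
    ang = np.deg2rad(np.arange(0, 360, 60))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _phi_feasible(theta: float, phi: float, tol: float = 1e-9) -> bool:
    return (90.0 - theta) - tol <= phi <= (90.0 + theta) + tol


def make_ring_cation(
    theta: float,
    phi: float,
    d: float,
    chain_id: str = "A",
    ring_residue: int = 94,
    cation_residue: int = 86,
) -> tuple[StructureModel, RingSpec]:
    """Build a ring+cation fixture whose measured geometry equals (theta, phi, d).

    The ring is a regular TRP-named carbon hexagon of radius 1.40 A in the
    z = 0 plane, centered at the origin, with one aromatic H (``HZ2``) at
    radius 2.48 A placed at the azimuth that realizes phi; the cation is an
    ARG CZ pseudo-atom at distance d, polar angle theta from +z.

    Raises
    ------
    ParameterError
        If theta is outside [0, 90], phi outside [0, 180], d <= 0, or
        (theta, phi) violates the in-plane-hydrogen feasibility band
        phi in [90 - theta, 90 + theta].
    """
    if not (0.0 <= theta <= 90.0) or not (0.0 <= phi <= 180.0) or d <= 0:
        raise ParameterError(f"theta={theta}, phi={phi}, d={d} out of range")
    if not _phi_feasible(theta, phi):
        raise ParameterError(
            f"phi={phi} not realizable at theta={theta}: in-plane hydrogens "
            f"restrict phi to [{90 - theta:.3f}, {90 + theta:.3f}]"
        )
    th = math.radians(theta)
    cation = np.array([d * math.sin(th), 0.0, d * math.cos(th)])
    sin_t = math.sin(th)
    if sin_t < 1e-12:  # axial: any in-plane H gives phi = 90
        beta = 0.0
    else:
        beta = math.acos(min(1.0, max(-1.0, math.cos(math.radians(phi)) / sin_t)))
    h_pos = np.array([H_RADIUS * math.cos(beta), H_RADIUS * math.sin(beta), 0.0])

    atoms = []
    for i, (name, pos) in enumerate(zip(TRP_RING_6, _hexagon(RING_RADIUS))):
        atoms.append(AtomRecord(i + 1, name, "TRP", chain_id, ring_residue, "C", pos))
    atoms.append(AtomRecord(7, "HZ2", "TRP", chain_id, ring_residue, "H", h_pos))
    atoms.append(AtomRecord(8, "CZ", "ARG", chain_id, cation_residue, "C", cation))
    model = StructureModel(atoms)
    ring = RingSpec(chain_id, ring_residue, "TRP", TRP_RING_6, ("HZ2",))
    return model, ring


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 degrees about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(math.pi * axis).as_matrix()
    return Rotation.from_rotvec(v / np.linalg.norm(v) * math.acos(max(-1.0, min(1.0, c)))).as_matrix()


def make_bridge_pdb(
    geom_a: tuple[float, float, float],
    geom_b: tuple[float, float, float],
    decoys: int = 0,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[StructureModel, list[RingSpec]]:
    """Fixture with one ARG-like cation bridging two TRP rings (residues 21/86/94).

    ``geom_a``/``geom_b`` are the planted (theta, phi, d) of the cation
    against ring 21 and ring 94; the rings are placed on opposite sides of
    the cation.  ``decoys`` extra non-interacting PHE rings are scattered
    >= 12 A from the cation.  If ``path`` is given the model is also
    written there as a PDB file.
    """
    model_a, _ = make_ring_cation(*geom_a, ring_residue=21)
    model_b, _ = make_ring_cation(*geom_b, ring_residue=94)
    cation_a = model_a.atoms[-1].position  # CZ of ring-A frame
    cation_b = model_b.atoms[-1].position

    # Rigidly move the ring-B assembly so its cation point lands on cation_a
    # and its centroid sits on the far side of the cation from ring A.
    u = cation_a / np.linalg.norm(cation_a)  # centroid A -> cation direction
    d_b = float(np.linalg.norm(cation_b))
    R = _rotation_between(cation_b / d_b, -u)
    moved_b = [(a, R @ (a.position - cation_b) + cation_a) for a in model_b.atoms[:-1]]

    # clash check: every ring-A heavy atom vs every moved ring-B atom
    pos_a = np.array([a.position for a in model_a.atoms[:-1]])
    pos_b = np.array([p for _, p in moved_b])
    if np.min(np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)) < 1.5:
        raise InfeasibleGeometryError(
            "rings overlap: the two planted distances place ring atoms closer than 1.5 A"
        )

    atoms: list[AtomRecord] = []
    serial = 1
    for a in model_a.atoms[:-1]:
        atoms.append(AtomRecord(serial, a.atom_name, a.residue_name, a.chain_id, 21, a.element, a.position))
        serial += 1
    for a, p in moved_b:
        atoms.append(AtomRecord(serial, a.atom_name, a.residue_name, a.chain_id, 94, a.element, p))
        serial += 1
    atoms.append(AtomRecord(serial, "CZ", "ARG", "A", 86, "C", cation_a))
    serial += 1

    rng = np.random.default_rng(seed)
    for k in range(decoys):
        # random orientation and a center >= 12 A from the cation
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = cation_a + direction * rng.uniform(14.0, 25.0)
        orient = Rotation.random(rng=rng).as_matrix()
        for name, pos in zip(PHE_TYR_RING, _hexagon(RING_RADIUS)):
            atoms.append(AtomRecord(serial, name, "PHE", "A", 200 + k, "C", orient @ pos + center))
            serial += 1

    model = StructureModel(atoms)
    rings = [
        RingSpec("A", 21, "TRP", TRP_RING_6, ("HZ2",)),
        RingSpec("A", 94, "TRP", TRP_RING_6, ("HZ2",)),
    ]
    if path is not None:
        write_pdb(model, path)
    return model, rings


def make_trajectory(
    base: StructureModel,
    amplitudes: float | np.ndarray,
    n_frames: int,
    seed: int = 0,
    dt_ps: float = 10.0,
    pair_switch: tuple[int, int, float, float, int] | None = None,
) -> TrajectoryEnsemble:
    """Gaussian-fluctuation ensemble around ``base`` with planted RMSF.

    Displacements are isotropic Gaussian with per-coordinate sigma =
    amplitude / sqrt(3), so the expected RMSF of each atom equals its
    planted amplitude exactly.  ``pair_switch = (i, j, d1, d2, frame)``
    moves atom j's mean position along the i->j axis so the i-j distance is
    d1 before ``frame`` and d2 from it on (a two-state jump).
    """
    coords = base.coordinates()
    n_atoms = coords.shape[0]
    amp = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_atoms,))
    if np.any(amp < 0):
        raise ParameterError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = (amp / math.sqrt(3.0))[None, :, None]
    frames = coords[None, :, :] + rng.normal(size=(n_frames, n_atoms, 3)) * sigma
    if pair_switch is not None:
        i, j, d1, d2, switch_frame = pair_switch
        axis = coords[j] - coords[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ParameterError("pair_switch atoms coincide")
        axis = axis / norm
        for frame_idx in range(n_frames):
            target = d1 if frame_idx < switch_frame else d2
            frames[frame_idx, j] += axis * (target - norm)
    times = np.arange(n_frames, dtype=float) * dt_ps
    return TrajectoryEnsemble(reference=base, frames=frames, times=times)


def make_itc(
    model: ITCModel,
    schedule: ITCSchedule,
    sigma_ucal: float = 0.1,
    seed: int = 0,
) -> Thermogram:
    """Noisy synthetic thermogram: predict_heats plus iid Gaussian(0, sigma)."""
    if sigma_ucal < 0:
        raise ParameterError("sigma_ucal must be >= 0")
    clean = predict_heats(model, schedule)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_ucal, size=clean.heats.shape) if sigma_ucal > 0 else 0.0
    return Thermogram(heats=clean.heats + noise, cumulative_titrant=clean.cumulative_titrant)


def itc_to_csv(thermogram: Thermogram, schedule: ITCSchedule, path: str | Path,
               blank_heat_ucal: float | None = None) -> Path:
    """Write a thermogram as the package's ITC CSV exchange format."""
    df = pd.DataFrame({
        "injection_index": np.arange(1, thermogram.heats.size + 1),
        "injection_volume_uL": np.asarray(schedule.injection_volumes) * 1e6,
        "heat_ucal": thermogram.heats if blank_heat_ucal is None
                     else thermogram.heats + blank_heat_ucal,
    })
    if blank_heat_ucal is not None:
        df["blank_heat_ucal"] = blank_heat_ucal
    df.to_csv(path, index=False)
    return Path(path)


def make_melt(
    tm: float,
    h: float = 25.0,
    theta_folded: float = -20.0,
    theta_unfolded: float = -5.0,
    sigma_mdeg: float = 0.3,
    seed: int = 0,
    scan: tuple[float, float, float] = (20.0, 96.0, 0.5),
) -> MeltCurve:
    """Hill-sigmoid melt curve plus iid Gaussian noise on the scan grid."""
    if sigma_mdeg < 0:
        raise ParameterError("sigma_mdeg must be >= 0")
    lo, hi, step = scan
    t = np.arange(lo, hi + step / 2, step)
    y = hill_sigmoid(t, theta_folded, theta_unfolded, tm, h)
    if sigma_mdeg > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma_mdeg, size=t.shape)
    return MeltCurve(temperature=t, ellipticity=y)


def make_cd_spectrum(
    theta222: float,
    theta208: float,
    wavelengths: np.ndarray | None = None,
    width208: float = 7.0,
    width222: float = 9.0,
) -> CDSpectrum:
    """Two-Gaussian far-UV alpha-helix-like spectrum with exact planted minima.

    Band amplitudes are solved from a 2x2 linear system so that the
    spectrum evaluates to exactly ``theta208`` at 208.0 nm and ``theta222``
    at 222.0 nm.
    """
    w = np.arange(200.0, 250.5, 0.5) if wavelengths is None else np.asarray(wavelengths, dtype=float)

    def g(center, width):
        return np.exp(-0.5 * ((w - center) / width) ** 2)

    def g_at(x, center, width):
        return math.exp(-0.5 * ((x - center) / width) ** 2)

    mat = np.array([
        [g_at(208.0, 208.0, width208), g_at(208.0, 222.0, width222)],
        [g_at(222.0, 208.0, width208), g_at(222.0, 222.0, width222)],
    ])
    amp = np.linalg.solve(mat, np.array([theta208, theta222]))
    return CDSpectrum(w, amp[0] * g(208.0, width208) + amp[1] * g(222.0, width222))


def make_near_uv_spectrum(offset: float = 2.0, scale: float = 1.0) -> CDSpectrum:
    """Near-UV (250-320 nm) fixture: aromatic-band bumps on a constant offset.

    The 310-320 nm region carries only the offset, so
    :func:`capi.spectro_fits.normalize_near_uv` removes exactly ``offset``.
    """
    w = np.arange(250.0, 320.5, 0.5)
    bands = (scale * -0.8 * np.exp(-0.5 * ((w - 262.0) / 3.0) ** 2)  # Phe
             + scale * 1.2 * np.exp(-0.5 * ((w - 278.0) / 4.0) ** 2)  # Tyr
             + scale * 0.9 * np.exp(-0.5 * ((w - 292.0) / 3.0) ** 2))  # Trp
    return CDSpectrum(w, bands + offset)
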