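"""Cation-pi interaction geometry on protein structures.

A cation-pi contact between an arginine guanidinium group and an aromatic
ring is described here by three numbers per ring-cation pair:

* ``d``      — distance from the ring centroid to the cation point (Angstrom),
* ``theta``  — angle between the ring-plane *normal* and the centroid-to-cation
  vector, folded to [0, 90] degrees, so theta = 0 is the textbook axial
  (on-axis) approach and theta = 90 is an in-plane, lateral approach,
* ``phi``    — angle cation / ring-centroid / aromatic-H, minimized over the
  ring's hydrogens; phi near 0 means the cation points straight at a ring
  hydrogen (the signature of a lateral contact).

The theta convention deserves a note: "angle between the aromatic plane and
the cation" is ambiguous, and a lateral contact reported with a 60-90 degree
window is only consistent with measuring from the plane normal (90 = in
plane).  That is the convention used by the common MD analysis utilities and
the one adopted here; ``theta_from_plane=True`` converts to the complementary
convention for anyone who wants the angle from the plane itself.

Classification uses the lateral window theta in (theta_lateral_min, 90]
with phi <= phi_max, the axial branch theta <= theta_axial_max, and a
distance gate d <= d_max.  Only the 60-90 degree theta window is a
literature value; the remaining thresholds are package defaults and are
echoed in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from capi.structure_io import AtomRecord, StructureModel, select

__all__ = [
    "TRP_RING_6", "TRP_RING_5", "TRP_RING_9", "PHE_TYR_RING",
    "TRP_RING_H", "ARG_CATION_ATOM", "DEFAULT_THRESHOLDS",
    "RingSpec", "CationPiGeometry", "Thresholds",
    "ring_centroid", "ring_plane_normal", "cation_pi_geometry",
    "classify_cation_pi", "bridge_scan", "resolve_cation_point",
]

# Ring atom sets.  TRP defaults to the six-membered benzene ring of the
# indole: a single well-defined plane.  The 5-ring and all-9 variants are
# provided for sensitivity checks.
TRP_RING_6 = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
TRP_RING_5 = ("CG", "CD1", "NE1", "CE2", "CD2")
TRP_RING_9 = ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")
PHE_TYR_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
# Aromatic hydrogens of the TRP benzene ring (read if present, never added).
TRP_RING_H = ("HE3", "HZ2", "HZ3", "HH2")
# ARG cation reference point: CZ approximates the guanidinium charge
# centroid and always exists in heavy-atom models.  "NH-mean" uses the
# mean of NE/NH1/NH2 instead.
ARG_CATION_ATOM = "CZ"


class DegenerateRingError(ValueError):
    """Fewer than three ring atoms, or (near-)collinear ring atoms."""


class CoincidentPointError(ValueError):
    """Cation point coincides with the ring centroid."""


@dataclass(frozen=True)
class RingSpec:
    """An aromatic ring of one residue: which atoms span the plane, which
    hydrogens are candidates for the phi angle (may be empty)."""

    chain_id: str
    residue_number: int
    residue_name: str = ""
    ring_atom_names: tuple[str, ...] = TRP_RING_6
    hydrogen_atom_names: tuple[str, ...] = TRP_RING_H

    def resolve(self, model: StructureModel) -> tuple[list[AtomRecord], list[AtomRecord]]:
        """Return (ring atoms, hydrogen atoms) found in ``model``; hydrogens may be absent."""
        ring = select(model, chain=self.chain_id, residue_number=self.residue_number,
                      atom_names=self.ring_atom_names)
        hyds = select(model, chain=self.chain_id, residue_number=self.residue_number,
                      atom_names=self.hydrogen_atom_names)
        return ring, hyds

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name or 'RING'}{self.residue_number}"


@dataclass(frozen=True)
class CationPiGeometry:
    """(theta, phi, d) of one ring-cation pair in one frame.

    ``phi`` is NaN when the ring has no hydrogens to measure against.
    """

    theta: float  # degrees, [0, 90]
    phi: float  # degrees, [0, 180]; NaN if no hydrogens
    distance: float  # Angstrom
    frame_index: int = 0
    label: str = "none"

    @property
    def phi_missing(self) -> bool:
        return math.isnan(self.phi)


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds; only the theta window is a literature value."""

    d_max: float = 6.0  # Angstrom
    phi_max: float = 30.0  # degrees
    theta_lateral_min: float = 60.0  # degrees
    theta_axial_max: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if min(self.d_max, self.phi_max, self.theta_lateral_min, self.theta_axial_max) <= 0:
            raise ValueError("thresholds must be positive")
        if self.theta_axial_max >= self.theta_lateral_min:
            raise ValueError("theta_axial_max must be below theta_lateral_min")


DEFAULT_THRESHOLDS = Thresholds()


def _positions(atoms: Sequence[AtomRecord] | np.ndarray) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return np.asarray(atoms, dtype=float)
    return np.array([a.position for a in atoms], dtype=float)


def ring_centroid(ring_atoms: Sequence[AtomRecord] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of the ring-atom positions (Angstrom)."""
    pos = _positions(ring_atoms)
    if pos.shape[0] < 3:
        raise DegenerateRingError(f"ring needs >=3 atoms, got {pos.shape[0]}")
    return pos.mean(axis=0)


def ring_plane_normal(ring_atoms: Sequence[AtomRecord] | np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through the ring atoms.

    The normal is the direction of least orthogonal variance (smallest
    right-singular vector of the centered coordinates).  Its sign is fixed
    so the z component is >= 0 (ties broken toward x >= 0, then y >= 0);
    theta folding makes the sign irrelevant downstream.
    """
    pos = _positions(ring_atoms)
    if pos.shape[0] < 3:
        raise DegenerateRingError(f"ring needs >=3 atoms, got {pos.shape[0]}")
    centered = pos - pos.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear atoms: second singular value vanishes relative to the first
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateRingError("ring atoms are (near-)collinear; plane undefined")
    normal = vt[2]
    eps = 1e-12
    if normal[2] < -eps:
        normal = -normal
    elif abs(normal[2]) <= eps:
        if normal[0] < -eps:
            normal = -normal
        elif abs(normal[0]) <= eps and normal[1] < 0:
            normal = -normal
    return normal / np.linalg.norm(normal)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def cation_pi_geometry(
    ring_atoms: Sequence[AtomRecord] | np.ndarray,
    cation_point: np.ndarray,
    hydrogen_atoms: Sequence[AtomRecord] | np.ndarray = (),
    frame_index: int = 0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    theta_from_plane: bool = False,
) -> CationPiGeometry:
    """Measure (theta, phi, d) of a ring-cation pair and classify it.

    Parameters
    ----------
    ring_atoms:
        Atoms (or an (n, 3) array) spanning the aromatic plane.
    cation_point:
        Cation reference position, Angstrom.
    hydrogen_atoms:
        Candidate aromatic hydrogens; phi is the minimum angle
        cation-centroid-H over them, NaN if empty.
    theta_from_plane:
        Report theta measured from the plane instead of from its normal
        (complementary convention, 90 - theta).
    """
    cation = np.asarray(cation_point, dtype=float)
    if cation.shape != (3,) or not np.all(np.isfinite(cation)):
        raise ValueError("cation_point must be a finite 3-vector")
    centroid = ring_centroid(ring_atoms)
    normal = ring_plane_normal(ring_atoms)
    to_cation = cation - centroid
    d = float(np.linalg.norm(to_cation))
    if d <= 1e-9:
        raise CoincidentPointError("cation coincides with ring centroid")
    # |dot| folds the angle to [0, 90]: the normal's sign carries no information
    cos_t = abs(float(np.dot(normal, to_cation)) / d)
    theta = math.degrees(math.acos(min(1.0, cos_t)))
    h_pos = _positions(hydrogen_atoms) if len(hydrogen_atoms) else np.empty((0, 3))
    if h_pos.shape[0]:
        phi = min(_angle_deg(to_cation, h - centroid) for h in h_pos)
    else:
        phi = float("nan")
    theta_report = 90.0 - theta if theta_from_plane else theta
    geom = CationPiGeometry(theta=theta_report, phi=phi, distance=d, frame_index=frame_index)
    label = classify_cation_pi(geom if not theta_from_plane else
                               CationPiGeometry(theta, phi, d, frame_index), thresholds)
    return CationPiGeometry(theta=theta_report, phi=phi, distance=d,
                            frame_index=frame_index, label=label)


def classify_cation_pi(g: CationPiGeometry, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Label a geometry as "lateral", "axial" or "none".

    "none" beyond the distance gate; "lateral" for theta in
    (theta_lateral_min, 90] with phi <= phi_max (phi missing: theta alone
    decides); "axial" for theta <= theta_axial_max.
    """
    if g.distance > thresholds.d_max:
        return "none"
    phi_ok = g.phi_missing or g.phi <= thresholds.phi_max
    if thresholds.theta_lateral_min < g.theta <= 90.0 and phi_ok:
        return "lateral"
    if g.theta <= thresholds.theta_axial_max:
        return "axial"
    return "none"


def resolve_cation_point(model: StructureModel, chain_id: str, residue_number: int,
                         convention: str = "CZ") -> np.ndarray:
    """Cation reference point of an ARG-like residue.

    ``"CZ"`` (default) uses the CZ atom; ``"NH-mean"`` averages NE/NH1/NH2.
    """
    if convention == "CZ":
        atoms = select(model, chain=chain_id, residue_number=residue_number,
                       atom_names=[ARG_CATION_ATOM])
        if not atoms:
            raise LookupError(f"no CZ atom in {chain_id}:{residue_number}")
        return atoms[0].position
    if convention == "NH-mean":
        atoms = select(model, chain=chain_id, residue_number=residue_number,
                       atom_names=["NE", "NH1", "NH2"])
        if len(atoms) < 3:
            raise LookupError(f"guanidinium N atoms missing in {chain_id}:{residue_number}")
        return _positions(atoms).mean(axis=0)
    raise ValueError(f"unknown cation convention {convention!r}")


@dataclass(frozen=True)
class Bridge:
    """One cation simultaneously engaging two distinct aromatic rings."""

    cation: tuple[str, int]  # (chain, residue_number)
    ring_a: RingSpec
    ring_b: RingSpec
    geometry_a: CationPiGeometry
    geometry_b: CationPiGeometry


def bridge_scan(
    model: StructureModel,
    cation_residues: Iterable[tuple[str, int]],
    rings: Iterable[RingSpec],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    cation_convention: str = "CZ",
    frame_index: int = 0,
) -> list[Bridge]:
    """Find every cation that classifies (non-"none") against two distinct rings.

    This is the detector for the R86-bridged W21/W94 "lock": a single
    arginine lying in a cation-pi geometry with two tryptophan rings at
    once.  Rings whose atoms cannot be resolved are skipped silently (a
    scan over a truncated model is still meaningful); an empty result is
    valid.
    """
    rings = list(rings)
    out: list[Bridge] = []
    for cat in cation_residues:
        try:
            cation_point = resolve_cation_point(model, cat[0], cat[1], cation_convention)
        except LookupError:
            continue
        hits: list[tuple[RingSpec, CationPiGeometry]] = []
        for ring in rings:
            ring_atoms, hyds = ring.resolve(model)
            if len(ring_atoms) < 3:
                continue
            geom = cation_pi_geometry(ring_atoms, cation_point, hyds,
                                      frame_index=frame_index, thresholds=thresholds)
            if geom.label != "none":
                hits.append((ring, geom))
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                out.append(Bridge(cation=cat, ring_a=hits[i][0], ring_b=hits[j][0],
                                  geometry_a=hits[i][1], geometry_b=hits[j][1]))
    return out
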