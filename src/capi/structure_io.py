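"""PDB structure and multi-model ensemble I/O.

Light domain containers (:class:`AtomRecord`, :class:`StructureModel`,
:class:`TrajectoryEnsemble`) over biotite's PDB reader/writer.  Residue
numbers are always taken verbatim from the file — the toolkit never
renumbers, because residue labels (e.g. W21, R86, W94, D168, R178 in GCAP1)
are positional claims.  Multi-model PDB files are the canonical trajectory
exchange format; frames are Gaussian-scale snapshots, timestamps default to
0, 1, 2, ... ps unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed or contains no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with residue identity and coordinates in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.atom_name:
            raise ValueError(f"atom {self.serial}: empty atom name")


@dataclass
class StructureModel:
    """An ordered collection of atoms (one MODEL of a PDB file)."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __post_init__(self) -> None:
        keys = [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue_number, atom_name) in model")

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over one atom table.

    ``reference`` fixes atom identities and ordering; ``frames`` is an
    (n_frames, n_atoms, 3) array; ``times`` are strictly increasing
    picoseconds.  Any object yielding ``(times, frames)`` with fixed atom
    ordering can be adapted into this container, so binary trajectory
    formats stay out of the core.
    """

    reference: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ps, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.reference):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{len(self.reference)} reference atoms"
            )
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("times and frames lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def model(self, index: int) -> StructureModel:
        """Materialize frame ``index`` as a StructureModel."""
        ref = self.reference
        atoms = [
            AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                       a.residue_number, a.element, self.frames[index, i])
            for i, a in enumerate(ref.atoms)
        ]
        return StructureModel(atoms, model_id=index + 1)


def _from_atom_array(arr: struc.AtomArray, model_id: int) -> StructureModel:
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=int(arr.get_annotation("atom_id")[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
                atom_name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                residue_number=int(arr.res_id[i]),
                element=str(arr.element[i]),
                position=arr.coord[i],
            )
        )
    return StructureModel(atoms, model_id=model_id)


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.coordinates()
    arr.chain_id = np.array([a.chain_id for a in model.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in model.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in model.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in model.atoms], dtype="U6")
    arr.element = np.array([a.element for a in model.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", np.array([a.serial for a in model.atoms], dtype=int))
    return arr


def read_pdb(path: str | Path, frame_dt_ps: float = 1.0) -> StructureModel | TrajectoryEnsemble:
    """Read a PDB file into a StructureModel or, if multi-model, a TrajectoryEnsemble.

    Parameters
    ----------
    path:
        Path to a PDB file with ATOM/HETATM records.
    frame_dt_ps:
        Spacing of the default timestamps assigned to the models of a
        multi-model file (times ``0, dt, 2*dt, ...`` ps).

    Raises
    ------
    PDBParseError
        If the file contains no atoms or cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = _pdb.PDBFile.read(str(path))
        stack = _pdb.get_structure(pdb_file, model=None, extra_fields=["atom_id"])
    except Exception as exc:  # biotite reports the offending line in its message
        raise PDBParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no atoms found")

    n_models = stack.stack_depth()
    if n_models == 1:
        return _from_atom_array(stack[0], model_id=1)
    reference = _from_atom_array(stack[0], model_id=1)
    times = np.arange(n_models, dtype=float) * frame_dt_ps
    return TrajectoryEnsemble(reference=reference, frames=stack.coord.copy(), times=times)


def write_pdb(obj: StructureModel | TrajectoryEnsemble, path: str | Path) -> Path:
    """Write a StructureModel (single MODEL) or TrajectoryEnsemble (multi MODEL)."""
    path = Path(path)
    pdb_file = _pdb.PDBFile()
    if isinstance(obj, StructureModel):
        _pdb.set_structure(pdb_file, _to_atom_array(obj))
    else:
        template = _to_atom_array(obj.reference)
        stack = struc.stack([template] * obj.n_frames)
        stack.coord = np.asarray(obj.frames, dtype=float)
        _pdb.set_structure(pdb_file, stack)
    pdb_file.write(str(path))
    return path


def select(
    model: StructureModel,
    chain: str | None = None,
    residue_number: int | None = None,
    atom_names: Sequence[str] | None = None,
    residue_name: str | None = None,
) -> list[AtomRecord]:
    """Pure filter over a model's atoms; file order preserved, empty result valid."""
    out = []
    names = set(atom_names) if atom_names is not None else None
    for a in model.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if residue_number is not None and a.residue_number != residue_number:
            continue
        if residue_name is not None and a.residue_name != residue_name:
            continue
        if names is not None and a.atom_name not in names:
            continue
        out.append(a)
    return out
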