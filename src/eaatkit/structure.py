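"""Structure and trajectory containers, PDB I/O and rigid-body superposition.

Coordinates are in Ångström throughout and residue numbering follows the
1-based PDB convention. Ions and ligands enter as first-class atoms marked
``hetero`` and distinguished by residue name (e.g. the Na+ ions that the
gating metrics address by residue number 601-603).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as _struc
from biotite.structure.io import pdb as _pdb

from .errors import (
    DegenerateFitError,
    IntegrityError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "SuperpositionResult",
    "read_pdb",
    "read_multimodel_pdb",
    "write_pdb",
    "write_trajectory_pdb",
    "select",
    "superpose",
]

_PROTEIN_BACKBONE_ATOM = "CA"


@dataclass(frozen=True)
class Atom:
    """A single atom with PDB-style identity and Å coordinates."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    coordinates: np.ndarray
    hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom coordinates must be a finite 3-vector, got {coords!r}")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class StructureModel:
    """An ordered collection of atoms addressable by chain/residue/atom name.

    Stored column-wise as numpy arrays for efficient selection and distance
    work; :meth:`atoms` yields :class:`Atom` views in file order.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    hetero: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        if n == 0:
            raise ValueError("StructureModel must contain at least one atom")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype="U5")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.coords = np.asarray(self.coords, dtype=float)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], label: str = "") -> "StructureModel":
        return cls(
            chain_ids=np.array([a.chain_id for a in atoms]),
            residue_numbers=np.array([a.residue_number for a in atoms]),
            residue_names=np.array([a.residue_name for a in atoms]),
            atom_names=np.array([a.atom_name for a in atoms]),
            coords=np.array([a.coordinates for a in atoms], dtype=float),
            hetero=np.array([a.hetero for a in atoms]),
            label=label,
        )

    # -- basic accessors -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield self.atom_at(i)

    def atom_at(self, index: int) -> Atom:
        return Atom(
            chain_id=str(self.chain_ids[index]),
            residue_number=int(self.residue_numbers[index]),
            residue_name=str(self.residue_names[index]),
            atom_name=str(self.atom_names[index]),
            coordinates=self.coords[index].copy(),
            hetero=bool(self.hetero[index]),
        )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            chain_ids=self.chain_ids[mask],
            residue_numbers=self.residue_numbers[mask],
            residue_names=self.residue_names[mask],
            atom_names=self.atom_names[mask],
            coords=self.coords[mask],
            hetero=self.hetero[mask],
            label=self.label if label is None else label,
        )

    def indices_where(
        self,
        chain: str | None = None,
        residue_number: int | None = None,
        residue_name: str | None = None,
        atom_name: str | None = None,
        hetero: bool | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching every given criterion (None = wildcard)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if residue_number is not None:
            mask &= self.residue_numbers == residue_number
        if residue_name is not None:
            mask &= self.residue_names == residue_name
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if hetero is not None:
            mask &= self.hetero == hetero
        return np.flatnonzero(mask)

    def protein_ca_indices(self, chain: str | None = None) -> np.ndarray:
        """Indices of non-hetero Cα atoms, optionally restricted to a chain."""
        return self.indices_where(chain=chain, atom_name=_PROTEIN_BACKBONE_ATOM, hetero=False)


def select(model: StructureModel, chain: str | None, residue_number: int,
           atom_name: str) -> Atom:
    """Return the unique atom matching the query.

    ``chain=None`` searches all chains (used to address monotopic ions by
    residue number alone). A query with no match raises
    :class:`SelectionError`; multiple matches raise :class:`IntegrityError`.
    """
    idx = model.indices_where(chain=chain, residue_number=residue_number,
                              atom_name=atom_name)
    query = f"(chain={chain!r}, residue_number={residue_number}, atom_name={atom_name!r})"
    if len(idx) == 0:
        raise SelectionError(f"no atom matches {query}")
    if len(idx) > 1:
        raise IntegrityError(f"{len(idx)} atoms match {query}; expected exactly one")
    return model.atom_at(int(idx[0]))


@dataclass
class Trajectory:
    """Frame-ordered coordinate sets sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``dt_ps`` is the frame
    spacing in picoseconds.
    """

    topology: StructureModel
    frames: np.ndarray
    dt_ps: float = 500.0
    replicate_id: int = 0
    system_label: str = "WT"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not self.dt_ps > 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps

    def frame_model(self, index: int) -> StructureModel:
        """Topology with the coordinates of one frame."""
        m = self.topology.subset(np.ones(self.topology.n_atoms, dtype=bool))
        m.coords = self.frames[index].copy()
        return m


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _find_malformed_line(path: Path) -> str | None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtext = line[lo:hi]
                    try:
                        float(fieldtext)
                    except ValueError:
                        return (f"line {lineno}: malformed coordinate field "
                                f"{fieldtext.strip()!r}")
    return None


def _stack_from_file(path: Path) -> _struc.AtomArrayStack:
    try:
        pdb_file = _pdb.PDBFile.read(path)
        return pdb_file.get_structure()
    except Exception as exc:
        detail = _find_malformed_line(path)
        if detail is not None:
            raise PDBParseError(f"{path}: {detail}") from exc
        if "atoms" in str(exc) and "model" in str(exc).lower():
            raise TopologyError(f"{path}: {exc}") from exc
        raise PDBParseError(f"{path}: {exc}") from exc


def _model_from_array(arr: _struc.AtomArray, label: str) -> StructureModel:
    if "ins_code" in arr.get_annotation_categories():
        ins = arr.ins_code
        if np.any(ins != ""):
            raise PDBParseError(f"{label}: insertion codes are not supported")
    return StructureModel(
        chain_ids=arr.chain_id.astype("U4"),
        residue_numbers=arr.res_id.astype(np.int64),
        residue_names=arr.res_name.astype("U5"),
        atom_names=arr.atom_name.astype("U6"),
        coords=np.asarray(arr.coord, dtype=float),
        hetero=arr.hetero.astype(bool),
        label=label,
    )


def read_pdb(path: str | Path, label: str | None = None) -> StructureModel:
    """Read a single-model PDB file into a :class:`StructureModel`."""
    path = Path(path)
    stack = _stack_from_file(path)
    return _model_from_array(stack[0], label or path.stem)


def read_multimodel_pdb(path: str | Path, dt_ps: float = 500.0,
                        replicate_id: int = 0,
                        system_label: str = "WT") -> Trajectory:
    """Read a multi-model PDB file (MODEL/ENDMDL frames) into a Trajectory."""
    path = Path(path)
    stack = _stack_from_file(path)
    topology = _model_from_array(stack[0], path.stem)
    return Trajectory(
        topology=topology,
        frames=np.asarray(stack.coord, dtype=float),
        dt_ps=dt_ps,
        replicate_id=replicate_id,
        system_label=system_label,
    )


def _array_from_model(model: StructureModel, coords: np.ndarray) -> _struc.AtomArray:
    n = model.n_atoms
    arr = _struc.AtomArray(n)
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.residue_numbers.astype(int)
    arr.res_name = model.residue_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.hetero = model.hetero.astype(bool)
    arr.coord = np.asarray(coords, dtype=np.float32)
    # crude element guess from the atom name; enough for fixture files
    elements = []
    for name in model.atom_names:
        stripped = str(name).strip()
        if stripped in ("NA", "CL", "MG", "ZN", "K"):
            elements.append(stripped)
        else:
            elements.append(stripped[:1])
    arr.element = np.array(elements, dtype="U2")
    return arr


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file (fixed-width, 3-decimal coordinates)."""
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(_array_from_model(model, model.coords))
    pdb_file.write(Path(path))


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file, one MODEL per frame."""
    arrays = [_array_from_model(traj.topology, traj.frames[i])
              for i in range(traj.n_frames)]
    stack = _struc.stack(arrays)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(Path(path))


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Optimal rigid transform (x' = R x + t) and transformed coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    fitted_coords: np.ndarray
    rmsd: float = field(default=np.nan)


def _check_fit_subset(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError(
            f"superposition needs >= 3 fit points, got {points.shape[0]}")
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-8 * max(svals[0], 1.0):
        raise DegenerateFitError("fit subset is collinear (or coincident)")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto reference.

    Uses the SVD form of the Kabsch algorithm with unit weights and a proper
    rotation (det R = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal point counts")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    return rotation, translation


def superpose(mobile_coords: np.ndarray, reference_coords: np.ndarray,
              fit_subset: np.ndarray | None = None) -> SuperpositionResult:
    """Superpose mobile coordinates onto a reference frame.

    The least-squares rigid-body optimum (Kabsch) is computed over
    ``fit_subset`` (indices into both coordinate sets; all atoms if None)
    and applied to *all* mobile atoms. The reported RMSD is over the fit
    subset after transformation.
    """
    mobile_coords = np.asarray(mobile_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    if mobile_coords.shape != reference_coords.shape:
        raise ValueError("mobile and reference must have the same shape")
    if fit_subset is None:
        fit_subset = np.arange(mobile_coords.shape[0])
    fit_subset = np.asarray(fit_subset)
    mob_fit = mobile_coords[fit_subset]
    ref_fit = reference_coords[fit_subset]
    _check_fit_subset(mob_fit)
    rotation, translation = kabsch(mob_fit, ref_fit)
    fitted = mobile_coords @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted[fit_subset] - ref_fit) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               fitted_coords=fitted, rmsd=rmsd)


def kabsch_batch(frames: np.ndarray, reference: np.ndarray,
                 fit_subset: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame of (n_frames, n_atoms, 3) onto one reference.

    Vectorized over frames (batched 3x3 SVD); used by trajectory fitting
    where thousands of Kabsch solves are needed.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_subset is None:
        fit_subset = np.arange(frames.shape[1])
    fit_subset = np.asarray(fit_subset)
    ref_fit = reference[fit_subset]
    _check_fit_subset(ref_fit)
    _check_fit_subset(frames[0][fit_subset])
    ref_c = ref_fit.mean(axis=0)
    ref_fit_c = ref_fit - ref_c

    mob_fit = frames[:, fit_subset, :]
    mob_c = mob_fit.mean(axis=1, keepdims=True)
    mob_fit_c = mob_fit - mob_c
    h = np.einsum("fni,nj->fij", mob_fit_c, ref_fit_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", vt.transpose(0, 2, 1),
                                  u.transpose(0, 2, 1)))
    corr = np.repeat(np.eye(3)[None, :, :], frames.shape[0], axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", vt.transpose(0, 2, 1), corr,
                    u.transpose(0, 2, 1))
    translation = ref_c - np.einsum("fij,fj->fi", rot, mob_c[:, 0, :])
    fitted = np.einsum("fij,fnj->fni", rot, frames) + translation[:, None, :]
    return fitted
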