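"""Multi-model PDB input/output and rigid-body geometric primitives.

The pipeline manipulates three kinds of structural objects, all represented
by the same light containers defined here: a peptide conformational ensemble
(one model per snapshot), the receptor (a single model of the MMP-14
catalytic domain), and an ensemble of docked peptide poses (one model per
docking solution).  Parsing and writing of the PDB v3.3 fixed-width format
is delegated to biotite; this module adds the validation the pipeline
relies on (line-numbered parse errors, identical atom identity across
models) and the geometric primitives every downstream stage uses: atom
selection, centers of mass, and Kabsch least-squares superposition.

Coordinates are in Angstroms throughout.  Residue numbering is taken from
the file verbatim and never renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """A PDB record could not be parsed; the message names the line."""


class StructuralInconsistencyError(ValueError):
    """Models of one ensemble do not share the same atom identity list."""


class InsufficientAtomsError(ValueError):
    """A superposition selection yielded fewer than 3 matched atoms."""


@dataclass(frozen=True)
class Atom:
    """One atom of a structure model.

    ``residue_seq`` is the 1-based PDB residue number exactly as read from
    the file.  ``coords`` is a length-3 float array in Angstroms.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def identity(self) -> tuple[str, int, str]:
        """(atom name, residue number, chain) — the cross-model atom key."""
        return (self.name, self.residue_seq, self.chain_id)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class StructureModel:
    """One conformation or docked pose: an ordered list of atoms."""

    model_id: int
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("StructureModel must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def identities(self) -> list[tuple[str, int, str]]:
        return [a.identity for a in self.atoms]

    def select(
        self,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
        predicate: Callable[[Atom], bool] | None = None,
    ) -> "StructureModel":
        """Return a sub-model keeping atom order.

        ``atom_names`` keeps only atoms whose name is in the set (e.g.
        ``{"CA"}`` for alpha-carbons); ``heavy_only`` drops hydrogens;
        ``predicate`` is an arbitrary extra filter.
        """
        names = {n.strip().upper() for n in atom_names} if atom_names is not None else None
        kept = [
            a
            for a in self.atoms
            if (names is None or a.name.upper() in names)
            and not (heavy_only and a.is_hydrogen)
            and (predicate is None or predicate(a))
        ]
        if not kept:
            raise ValueError("selection matched no atoms")
        return StructureModel(self.model_id, kept)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply the rigid motion x -> R x + t and return a new model."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                 a.residue_seq, R @ a.coords + t, a.occupancy, a.b_factor)
            for a in self.atoms
        ]
        return StructureModel(self.model_id, atoms)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        """Return a copy with replaced coordinates (same atom identities)."""
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                 a.residue_seq, c, a.occupancy, a.b_factor)
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(self.model_id if model_id is None else model_id, atoms)


@dataclass
class Ensemble:
    """An ordered collection of models sharing one atom identity list."""

    models: list[StructureModel]
    label: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("Ensemble must contain at least one model")
        ref = self.models[0].identities()
        for m in self.models[1:]:
            if m.identities() != ref:
                raise StructuralInconsistencyError(
                    f"model {m.model_id} atom identities differ from model "
                    f"{self.models[0].model_id} in ensemble {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    @property
    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.models])


# --- atomic masses -----------------------------------------------------------

def element_mass(element: str) -> float:
    mass = struc_info.mass(element.strip().capitalize())
    if mass is None or mass == 0:
        raise ValueError(f"unknown element {element!r}: cannot assign a mass")
    return float(mass)


def center_of_mass(model: StructureModel, mass_mode: str = "element") -> np.ndarray:
    """Center of mass (``mass_mode="element"``) or centroid (``"uniform"``).

    The element-weighted mode is the "center of gravity" used to place a
    docked pose at a single point on the receptor surface.
    """
    coords = model.coords
    if mass_mode == "uniform":
        return coords.mean(axis=0)
    if mass_mode == "element":
        unknown = sorted({a.element for a in model.atoms if not a.element.strip()})
        if unknown:
            raise ValueError(f"atoms with empty element symbol: {unknown}")
        masses = np.array([element_mass(a.element) for a in model.atoms])
        return masses @ coords / masses.sum()
    raise ValueError(f"mass_mode must be 'uniform' or 'element', got {mass_mode!r}")


# --- superposition -----------------------------------------------------------

def _matched_coords(
    mobile: StructureModel, reference: StructureModel, selection: Iterable[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    names = {n.strip().upper() for n in selection} if selection is not None else None

    def pick(model: StructureModel) -> dict[tuple[str, int, str], np.ndarray]:
        return {
            a.identity: a.coords
            for a in model.atoms
            if names is None or a.name.upper() in names
        }

    mob, ref = pick(mobile), pick(reference)
    common = [k for k in ref if k in mob]  # reference order
    if len(common) < 3:
        raise InsufficientAtomsError(
            f"superposition needs >=3 matched atoms, selection yielded {len(common)}"
        )
    return (np.array([mob[k] for k in common]), np.array([ref[k] for k in common]))


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Atoms are matched by (name, residue number, chain) identity after the
    optional atom-name ``selection`` filter.  Returns ``(rotation 3x3,
    translation 3-vector, rmsd)`` such that ``R x + t`` maps mobile
    coordinates into the reference frame.  The rotation is always proper
    (det +1): a mirror image is never superposed onto its enantiomer with
    zero RMSD.
    """
    mob, ref = _matched_coords(mobile, reference, selection)
    mob_com, ref_com = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_com, mob - mob_com)
    R = rot.as_matrix()
    t = ref_com - R @ mob_com
    rmsd = float(rssd / np.sqrt(len(mob)))
    return R, t, rmsd


def rmsd_after_fit(
    a: StructureModel, b: StructureModel, selection: Iterable[str] | None = None
) -> float:
    """Post-fit RMSD between two models over the matched selection."""
    return superpose(a, b, selection)[2]


# --- PDB reading / writing ---------------------------------------------------

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _prevalidate_pdb_lines(lines: Sequence[str], path: str) -> None:
    """Raise PDBParseError naming the first malformed ATOM/HETATM line."""
    for i, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"{path}, line {i}: truncated {rec} record")
        for lo, hi in _COORD_SLICES:
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"{path}, line {i}: unparseable coordinate field {line[lo:hi]!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"{path}, line {i}: unparseable residue number {line[22:26]!r}"
            ) from None


def _array_to_model(arr: struc.AtomArray, model_id: int) -> StructureModel:
    atoms = [
        Atom(
            serial=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]) or "A",
            residue_seq=int(arr.res_id[i]),
            coords=arr.coord[i],
            occupancy=float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0,
            b_factor=float(arr.b_factor[i]) if "b_factor" in arr.get_annotation_categories() else 0.0,
        )
        for i in range(arr.array_length())
    ]
    return StructureModel(model_id, atoms)


def read_multimodel_pdb(
    path: str | Path, label: str = "", include_hetatm: bool = False
) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`.

    Files with MODEL/ENDMDL blocks yield one model per block; a file
    without MODEL records yields an ensemble of size 1.  HETATM records
    are ignored unless ``include_hetatm`` (docked poses and the receptor
    are peptide/protein only).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    _prevalidate_pdb_lines(lines, str(path))
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    models: list[StructureModel] = []
    for i in range(1, n_models + 1):
        try:
            arr = pdb.get_structure(
                model=i, extra_fields=["atom_id", "occupancy", "b_factor"]
            )
        except Exception as exc:  # biotite raises InvalidFileError subclasses
            raise PDBParseError(f"{path}: {exc}") from exc
        if not include_hetatm:
            arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise PDBParseError(f"{path}: model {i} contains no (non-HETATM) atoms")
        models.append(_array_to_model(arr, model_id=i))
    return Ensemble(models, label=label or path.stem)


def write_multimodel_pdb(path: str | Path, ensemble: Ensemble) -> None:
    """Write an ensemble as a MODEL-blocked PDB v3.3 file.

    Coordinates are written at the standard %8.3f precision, so a
    read-back reproduces them exactly at that precision.
    """
    arrays = []
    for m in ensemble.models:
        n = len(m)
        arr = struc.AtomArray(n)
        arr.coord = m.coords
        arr.atom_name = np.array([a.name for a in m.atoms], dtype="U6")
        arr.res_name = np.array([a.residue_name for a in m.atoms], dtype="U5")
        arr.res_id = np.array([a.residue_seq for a in m.atoms])
        arr.chain_id = np.array([a.chain_id for a in m.atoms], dtype="U4")
        arr.element = np.array([a.element for a in m.atoms], dtype="U2")
        arr.add_annotation("atom_id", int)
        arr.atom_id[:] = [a.serial for a in m.atoms]
        arr.add_annotation("occupancy", float)
        arr.occupancy[:] = [a.occupancy for a in m.atoms]
        arr.add_annotation("b_factor", float)
        arr.b_factor[:] = [a.b_factor for a in m.atoms]
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
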