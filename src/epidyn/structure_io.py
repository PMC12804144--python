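"""Atomic structures and multi-model trajectories in PDB format.

Parsing and serialisation are delegated to :mod:`biotite.structure.io.pdb`;
this module layers the domain policies on top: alternate-location resolution
(highest occupancy, ties broken lexicographically), optional water skipping,
element inference for records with blank element columns, and congruence
checking across trajectory models.

Coordinates are in angstroms throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import numpy as np

from .errors import (
    CongruenceError,
    InputError,
    LookupAtomError,
    PDBParseError,
    SelectionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RadiiTable",
    "AtomSelection",
    "BONDI_RADII",
    "parse_pdb",
    "parse_multimodel",
    "write_pdb",
    "write_multimodel",
    "select_atoms",
    "assign_radii",
]


@dataclass(frozen=True)
class Atom:
    """One atomic coordinate record.

    ``residue_seq`` follows the author-assigned PDB numbering verbatim;
    insertion codes are carried separately in ``ins_code``.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetatm: bool = False
    ins_code: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise InputError(f"non-finite coordinates for atom {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.serial}"
            )
        if not self.element:
            raise InputError(f"empty element for atom {self.serial} ({self.name})")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.ins_code)


class Structure:
    """An ordered collection of atoms with residue-level accessors."""

    def __init__(self, atoms: list[Atom]):
        self.atoms: list[Atom] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __eq__(self, other) -> bool:
        return isinstance(other, Structure) and self.atoms == other.atoms

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (angstrom)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise InputError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        return Structure(
            [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords)]
        )

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain_id, residue_seq, ins_code), file order."""
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def residue(self, chain_id: str, residue_seq: int, ins_code: str = "") -> list[Atom]:
        atoms = [
            a
            for a in self.atoms
            if a.chain_id == chain_id
            and a.residue_seq == residue_seq
            and a.ins_code == ins_code
        ]
        if not atoms:
            raise LookupAtomError(
                f"residue {chain_id}:{residue_seq}{ins_code} not in structure"
            )
        return atoms

    def atom(self, chain_id: str, residue_seq: int, name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.name == name
            ):
                return a
        raise LookupAtomError(f"atom {chain_id}:{residue_seq}:{name} not in structure")


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``frames`` is an (n_frames, n_atoms, 3) array congruent with
    ``topology``; frame 0 provides the naming.
    """

    topology: Structure
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise CongruenceError(
                f"frame array shape {self.frames.shape} incongruent with "
                f"{len(self.topology)}-atom topology"
            )

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


#: van der Waals radii (Bondi 1964), angstrom.
BONDI_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius (angstrom), with a fallback."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.50

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise InputError("van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper().capitalize(), self.default_radius)


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter; unset fields do not constrain.

    A selection with no constraints at all is treated as an error when used.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None  # inclusive
    residue_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    heavy_only: bool = False

    def is_empty(self) -> bool:
        return (
            self.chain_id is None
            and self.residue_range is None
            and self.residue_names is None
            and self.atom_names is None
            and not self.heavy_only
        )

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= atom.residue_seq <= hi:
                return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.heavy_only and atom.element == "H":
            return False
        return True


_COORD_FIELDS = [(30, 38), (38, 46), (46, 54)]  # x, y, z columns (0-based)


def _validate_records(text: str) -> int:
    """Pre-scan fixed-width numeric fields; return coordinate-record count."""
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_records += 1
        for start, stop in _COORD_FIELDS:
            fragment = line[start:stop].strip()
            try:
                float(fragment)
            except ValueError:
                raise PDBParseError(
                    f"malformed numeric field {fragment!r} on line {lineno}"
                ) from None
    return n_records


_ELEMENTS_TWO_LETTER = {"FE", "ZN", "MG", "MN", "NA", "CL", "BR", "SE", "CA", "CU"}


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Element from the atom-name columns when columns 77-78 are blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    # Two-letter element only for ion/het residues named after the element
    # (e.g. residue "ZN", atom "ZN"); in polymers "CA" is an alpha carbon.
    if stripped[:2].upper() in _ELEMENTS_TWO_LETTER and residue_name.strip().upper() == stripped[:2].upper():
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _array_to_atoms(arr: struc.AtomArray, skip_waters: bool) -> list[Atom]:
    atoms: list[Atom] = []
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    occupancies = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length())
    )
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        if skip_waters and res_name == "HOH":
            continue
        element = str(arr.element[i]).strip()
        if not element:
            element = _infer_element(str(arr.atom_name[i]), res_name)
        if not element:
            raise PDBParseError(
                f"cannot determine element for atom {serials[i]} "
                f"({arr.atom_name[i]!r} in {res_name})"
            )
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=element.capitalize(),
                residue_name=res_name,
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                # PDB text carries exactly 3 decimals; snap the float32
                # parse back to the nearest double of the printed value
                coords=tuple(round(float(c), 3) for c in arr.coord[i]),
                occupancy=float(np.clip(occupancies[i], 0.0, 1.0)),
                altloc=str(arr.altloc_id[i]).strip()
                if "altloc_id" in arr.get_annotation_categories()
                else "",
                is_hetatm=bool(arr.hetero[i]),
                ins_code=str(arr.ins_code[i]).strip(),
            )
        )
    return atoms


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one record per (chain, resSeq, ins, atom name): highest occupancy,
    ties broken by lexicographically smallest altloc."""
    best: dict[tuple, int] = {}
    for idx, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq, a.ins_code, a.name)
        if key not in best:
            best[key] = idx
            continue
        b = atoms[best[key]]
        if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
            best[key] = idx
    keep = sorted(best.values())
    return [atoms[i] for i in keep]


def _altloc_rank(altloc: str) -> float:
    # Higher rank wins; lexicographically smaller altloc ranks higher.
    return -ord(altloc) if altloc else 0.0


def _read_pdbfile(text: str) -> _pdb.PDBFile:
    try:
        return _pdb.PDBFile.read(io.StringIO(text))
    except Exception as exc:  # biotite raises bare ValueError etc.
        raise PDBParseError(f"cannot read PDB text: {exc}") from exc


def parse_pdb(text: str, skip_waters: bool = True) -> Structure:
    """Parse single-model PDB text into a :class:`Structure`.

    Files wrapped in a single MODEL/ENDMDL pair parse identically to
    unwrapped files. Duplicated altloc records collapse to the
    highest-occupancy copy (ties -> lexicographically first altloc).

    Parameters
    ----------
    text:
        PDB-format content with at least one ATOM or HETATM record.
    skip_waters:
        Drop HOH residues (default true).
    """
    if _validate_records(text) == 0:
        raise PDBParseError("no ATOM or HETATM records found")
    pdbfile = _read_pdbfile(text)
    arr = pdbfile.get_structure(
        model=1, altloc="all", extra_fields=["occupancy", "atom_id"]
    )
    atoms = _resolve_altlocs(_array_to_atoms(arr, skip_waters=skip_waters))
    if not atoms:
        raise PDBParseError("no atoms remain after filtering")
    return Structure(atoms)


def parse_multimodel(text: str, skip_waters: bool = True) -> Trajectory:
    """Parse a multi-model PDB file into a :class:`Trajectory`.

    Every MODEL block must contain the same atoms in the same order;
    otherwise a :class:`CongruenceError` is raised. Topology (naming,
    residues) comes from the first model.
    """
    if _validate_records(text) == 0:
        raise PDBParseError("no ATOM or HETATM records found")
    pdbfile = _read_pdbfile(text)
    try:
        stack = pdbfile.get_structure(
            model=None, altloc="all", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:
        raise CongruenceError(f"models are not atom-congruent: {exc}") from exc
    first = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    atoms_all = _array_to_atoms(first, skip_waters=skip_waters)
    atoms = _resolve_altlocs(atoms_all)
    # Indices of retained atoms within the full first-model record list.
    keep = _kept_indices(atoms_all, atoms, first, skip_waters)
    if isinstance(stack, struc.AtomArrayStack):
        frames = stack.coord[:, keep, :]
    else:
        frames = stack.coord[np.newaxis, keep, :]
    frames = np.round(frames.astype(float), 3)
    return Trajectory(topology=Structure(atoms), frames=frames)


def _kept_indices(
    atoms_all: list[Atom],
    atoms_kept: list[Atom],
    arr: struc.AtomArray,
    skip_waters: bool,
) -> np.ndarray:
    # Map retained Atom objects back to column indices of the biotite array.
    kept_ids = {id(a) for a in atoms_kept}
    cols = []
    j = 0
    for i in range(arr.array_length()):
        if skip_waters and str(arr.res_name[i]) == "HOH":
            continue
        if id(atoms_all[j]) in kept_ids:
            cols.append(i)
        j += 1
    return np.array(cols, dtype=int)


def _atoms_to_array(s: Structure) -> struc.AtomArray:
    n = len(s)
    arr = struc.AtomArray(n)
    arr.coord = s.coords
    arr.chain_id = np.array([a.chain_id for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_seq for a in s.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in s.atoms], dtype="U2")
    arr.hetero = np.array([a.is_hetatm for a in s.atoms], dtype=bool)
    arr.ins_code = np.array([a.ins_code for a in s.atoms], dtype="U1")
    arr.set_annotation(
        "occupancy", np.array([a.occupancy for a in s.atoms], dtype=float)
    )
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms], dtype=int))
    arr.set_annotation(
        "altloc_id", np.array([a.altloc or " " for a in s.atoms], dtype="U1")
    )
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_pdb(s: Structure) -> str:
    """Serialise a structure to fixed-width PDB text."""
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(_atoms_to_array(s))
    buf = io.StringIO()
    pdbfile.write(buf)
    return buf.getvalue()


def write_multimodel(traj: Trajectory) -> str:
    """Serialise a trajectory as a multi-model PDB file."""
    template = _atoms_to_array(traj.topology)
    stack = struc.AtomArrayStack(traj.frame_count, len(traj.topology))
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.frames.copy()
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(stack)
    buf = io.StringIO()
    pdbfile.write(buf)
    return buf.getvalue()


def select_atoms(s: Structure, sel: AtomSelection) -> Structure:
    """Filter a structure by an :class:`AtomSelection`, preserving order.

    Raises
    ------
    SelectionError
        If the selection has no constraints or matches nothing.
    """
    if sel.is_empty():
        raise SelectionError("selection has no constraints")
    atoms = [a for a in s.atoms if sel.matches(a)]
    if not atoms:
        raise SelectionError(f"selection {sel} matched no atoms")
    return Structure(atoms)


def assign_radii(s: Structure, table: RadiiTable | None = None) -> np.ndarray:
    """Per-atom van der Waals radii (angstrom) by element lookup.

    Unknown elements receive ``table.default_radius`` and are logged.
    """
    table = table or RadiiTable()
    unknown = set()
    radii = np.empty(len(s))
    for i, a in enumerate(s.atoms):
        key = a.element.capitalize()
        if key in table.radii:
            radii[i] = table.radii[key]
        else:
            radii[i] = table.default_radius
            unknown.add(a.element)
    if unknown:
        logger.warning(
            "unknown element(s) %s assigned default radius %.2f A",
            sorted(unknown),
            table.default_radius,
        )
    return radii
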