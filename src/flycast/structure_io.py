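"""PDB structure reading/writing and residue/atom selections.

The in-memory unit all geometry operates on is :class:`Structure`: a flat,
mass-annotated atom table (numpy-backed).  PDB parsing and formatting is
delegated to biotite; this module owns the polymer-filtering policy
(waters and non-passlisted heteroatoms are dropped, phospho-residues such
as TPO are kept as polymer residues), mass assignment and the selection
algebra used by the restraint and analysis layers.

Residue numbers follow author numbering from the source PDB (1-based,
gaps allowed).  Altloc resolution keeps the highest-occupancy variant,
ties broken in favour of altloc 'A'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptyStructureError,
    FormatError,
    OverflowFieldError,
    UnknownChainError,
)

__all__ = [
    "ATOMIC_MASSES",
    "Structure",
    "Selection",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "write_pdb_models",
    "resolve_selection",
]

# Standard atomic masses (Da), heavy atoms found in proteins plus H.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# HETATM residue names retained as polymer residues (phospho-residues).
DEFAULT_HETERO_PASSLIST = frozenset({"TPO", "SEP", "PTR"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


@dataclass
class Structure:
    """Mass-annotated atom table.

    All array fields have one entry per atom, in file order.  Coordinates
    are in Angstrom, masses in Dalton.
    """

    chain_id: np.ndarray  # str array
    res_id: np.ndarray  # int array
    ins_code: np.ndarray  # str array
    res_name: np.ndarray  # str array
    atom_name: np.ndarray  # str array
    element: np.ndarray  # str array
    coord: np.ndarray  # (n, 3) float
    mass: np.ndarray  # (n,) float
    title: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        for name in ("chain_id", "res_id", "ins_code", "res_name",
                     "atom_name", "element"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not np.all(np.isfinite(self.coord)):
            raise FormatError("non-finite coordinates in structure")
        if self.n_atoms and not np.all(self.mass > 0):
            raise FormatError("every atom must have mass > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_keys(self):
        """Ordered unique (chain, res_id, ins_code) keys."""
        seen: dict[tuple, None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def with_coord(self, coord: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coord = np.asarray(coord, dtype=float)
        if coord.shape != self.coord.shape:
            raise ValueError("coordinate shape mismatch")
        return replace(self, coord=coord)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            chain_id=self.chain_id[idx],
            res_id=self.res_id[idx],
            ins_code=self.ins_code[idx],
            res_name=self.res_name[idx],
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            coord=self.coord[idx],
            mass=self.mass[idx],
            title=self.title,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return (
            self.n_atoms == other.n_atoms
            and all(
                np.array_equal(getattr(self, f), getattr(other, f))
                for f in ("chain_id", "res_id", "ins_code", "res_name",
                          "atom_name", "element")
            )
            and np.allclose(self.coord, other.coord, atol=5e-4)
            and np.allclose(self.mass, other.mass)
        )


@dataclass(frozen=True)
class Selection:
    """A chain + residue-set + atom-level filter.

    ``atoms`` is one of ``"all"``, ``"calpha"``, ``"sidechain"`` or a
    tuple of atom names.  ``residues=None`` selects the whole chain.
    """

    chain: str
    residues: frozenset[int] | None = None
    atoms: str | tuple[str, ...] = "all"

    def __post_init__(self):
        if self.residues is not None:
            object.__setattr__(self, "residues", frozenset(int(r) for r in self.residues))
        if isinstance(self.atoms, list):
            object.__setattr__(self, "atoms", tuple(self.atoms))

    @classmethod
    def residue_range(cls, chain: str, start: int, stop: int,
                      atoms: str | tuple[str, ...] = "all") -> "Selection":
        """Inclusive residue range, author numbering."""
        return cls(chain, frozenset(range(start, stop + 1)), atoms)

    def describe(self) -> str:
        res = "all" if self.residues is None else \
            ",".join(str(r) for r in sorted(self.residues))
        atoms = self.atoms if isinstance(self.atoms, str) else "+".join(self.atoms)
        return f"chain {self.chain} res {res} atoms {atoms}"


def _mass_for(element: str, atom_name: str) -> float:
    el = element.upper().strip()
    if el in ATOMIC_MASSES:
        return ATOMIC_MASSES[el]
    # fall back to first letter of the atom name (older PDBs omit element)
    guess = atom_name.strip().lstrip("0123456789")[:1].upper()
    if guess in ATOMIC_MASSES:
        return ATOMIC_MASSES[guess]
    raise FormatError(f"unknown element {element!r} for atom {atom_name!r}")


def _from_atom_array(arr: bts.AtomArray, title: str = "",
                     hetero_passlist=DEFAULT_HETERO_PASSLIST,
                     drop_hetero: bool = True) -> Structure:
    if drop_hetero:
        keep = ~arr.hetero | np.isin(arr.res_name, list(hetero_passlist))
        keep &= ~np.isin(arr.res_name, list(_WATER_NAMES))
        arr = arr[keep]
    if arr.array_length() == 0:
        raise EmptyStructureError("no polymer atoms after filtering")
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else \
        np.full(arr.array_length(), "", dtype="U1")
    masses = np.array([
        _mass_for(el, an) for el, an in zip(arr.element, arr.atom_name)
    ])
    return Structure(
        chain_id=arr.chain_id.astype("U4"),
        res_id=arr.res_id.astype(int),
        ins_code=ins.astype("U1"),
        res_name=arr.res_name.astype("U5"),
        atom_name=arr.atom_name.astype("U6"),
        element=arr.element.astype("U2"),
        coord=np.asarray(arr.coord, dtype=float),
        mass=masses,
        title=title,
    )


def _to_atom_array(s: Structure) -> bts.AtomArray:
    arr = bts.AtomArray(s.n_atoms)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_id.astype(int)
    arr.ins_code = s.ins_code.astype("U1")
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = np.isin(s.res_name, list(DEFAULT_HETERO_PASSLIST))
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    return arr


def read_pdb(path, hetero_passlist=DEFAULT_HETERO_PASSLIST,
             model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters and heteroatoms are dropped except residue names in
    ``hetero_passlist`` (default keeps phospho-residues TPO/SEP/PTR).
    Altlocs resolve to the highest-occupancy variant.
    """
    try:
        pdb_file = PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=model, altloc="occupancy")
    except EmptyStructureError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return _from_atom_array(arr, title=str(path),
                            hetero_passlist=hetero_passlist)


def read_pdb_models(path, hetero_passlist=DEFAULT_HETERO_PASSLIST
                    ) -> list[Structure]:
    """Read every MODEL of a multi-model PDB file."""
    try:
        pdb_file = PDBFile.read(str(path))
        n = pdb_file.get_model_count()
        return [
            _from_atom_array(
                pdb_file.get_structure(model=m, altloc="occupancy"),
                title=f"{path}#{m}", hetero_passlist=hetero_passlist)
            for m in range(1, n + 1)
        ]
    except EmptyStructureError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _check_overflow(coords: np.ndarray):
    # PDB coordinate columns are %8.3f: representable range (-999.999, 9999.999)
    if np.any(coords <= -1000.0) or np.any(coords >= 10000.0):
        raise OverflowFieldError(
            "coordinates exceed PDB fixed-width fields (±1000 Å)")


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB file with 3-decimal coordinates."""
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    _check_overflow(structure.coord)
    pdb_file = PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    pdb_file.write(str(path))


def write_pdb_models(structure: Structure, coords_per_model: np.ndarray,
                     path) -> None:
    """Write a multi-model PDB (one MODEL block per frame).

    ``coords_per_model`` has shape (n_models, n_atoms, 3); atom metadata
    is shared across models (trajectory convention).
    """
    coords = np.asarray(coords_per_model, dtype=float)
    if coords.ndim != 3 or coords.shape[1] != structure.n_atoms:
        raise ValueError("coords_per_model must be (models, atoms, 3)")
    _check_overflow(coords)
    template = _to_atom_array(structure)
    stack = bts.AtomArrayStack(coords.shape[0], structure.n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = coords.astype(np.float32)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def resolve_selection(structure: Structure, selection: Selection
                      ) -> np.ndarray:
    """Resolve a :class:`Selection` to sorted atom indices.

    Deterministic and order-stable (indices ascend in storage order).
    An empty result is returned as an empty array, never an error — but a
    chain id absent from the structure raises :class:`UnknownChainError`
    so typos are never silently broadened to "no atoms".
    """
    chain_mask = structure.chain_id == selection.chain
    if not chain_mask.any():
        raise UnknownChainError(
            f"chain {selection.chain!r} not in structure "
            f"(has {structure.chains})")
    mask = chain_mask
    if selection.residues is not None:
        mask = mask & np.isin(structure.res_id,
                              np.fromiter(selection.residues, dtype=int))
    atoms = selection.atoms
    if atoms == "all":
        pass
    elif atoms == "calpha":
        mask = mask & (structure.atom_name == "CA")
    elif atoms == "sidechain":
        mask = mask & ~np.isin(structure.atom_name, list(_BACKBONE_ATOMS))
    elif isinstance(atoms, tuple):
        mask = mask & np.isin(structure.atom_name, list(atoms))
    else:
        raise ValueError(f"unknown atom filter {atoms!r}")
    return np.flatnonzero(mask)
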