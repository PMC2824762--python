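"""Macromolecular coordinate I/O and selection.

A thin, typed layer over :mod:`gemmi` that exposes the hierarchical
``Structure -> chains -> Residue -> Atom`` container consumed by every
other module in the package.  Solvent is flagged rather than dropped so
that deposited-model atom counts (protein + nucleic acid only) remain
reproducible, and author residue numbering is kept untouched because the
clamp literature refers to residues by author numbers (Lys 20, Arg 149,
His 190, ...).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ParseError",
    "SelectionError",
    "SerialOverflowError",
    "read_structure",
    "write_structure",
    "select",
    "count_atoms",
]

#: Standard amino-acid residue names (3-letter, PDB chemical component codes).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

#: Deoxyribonucleotide names -- both PDB v3 two-letter and legacy
#: one-letter dialects are accepted.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "A", "C", "G", "T", "I"}

SOLVENT_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """A coordinate file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is malformed.

    Carries ``position``: the character offset of the offending token.
    """

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class SerialOverflowError(ValueError):
    """Atom serial exceeds the fixed-width PDB field; write mmCIF instead."""


def classify_residue(name: str) -> str:
    """Map a residue name to ``protein`` / ``dna`` / ``other``."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    return "other"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    #: For alt-loc groups, the highest-occupancy conformer is marked primary.
    primary: bool = True

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element symbol is empty")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.coord.copy(),
                    self.alt_loc, self.occupancy, self.b_factor, self.primary)


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""
    kind: str = ""
    is_solvent: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.number}: no atoms")
        if not self.kind:
            self.kind = classify_residue(self.name)
        if not self.is_solvent:
            self.is_solvent = self.name.strip().upper() in SOLVENT_RESIDUES

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name and a.primary:
                return a
        raise KeyError(f"residue {self.name} {self.number} ({self.chain_id}) "
                       f"has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name and a.primary for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.number, self.name,
                       [a.copy() for a in self.atoms],
                       self.insertion_code, self.kind, self.is_solvent)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for r in residues:
                r.chain_id = cid

    # -- iteration -----------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def coords(self, atom_name: str | None = None,
               primary_only: bool = True) -> np.ndarray:
        """Coordinates as an (n, 3) array, optionally restricted by atom name."""
        pts = [a.coord for r, a in self.atoms()
               if (atom_name is None or a.name == atom_name)
               and (a.primary or not primary_only)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return Structure(self.id,
                         {cid: [r.copy() for r in res]
                          for cid, res in self.chains.items()},
                         dict(self.metadata))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy with every atom coordinate replaced, in iteration order."""
        out = self.copy()
        coords = np.asarray(coords, dtype=float)
        it = iter(coords)
        for _, a in out.atoms():
            a.coord = np.array(next(it), dtype=float)
        return out

    def add_chain(self, chain_id: str, residues: list[Residue]) -> None:
        if chain_id in self.chains:
            raise ValueError(f"duplicate chain id {chain_id!r}")
        for r in residues:
            r.chain_id = chain_id
        self.chains[chain_id] = residues


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _mark_primary_altlocs(atoms: list[Atom]) -> None:
    """Within each atom-name group, mark the highest-occupancy alt-loc primary.

    Ties are broken by alt-loc label order so geometry is deterministic.
    """
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    for group in by_name.values():
        if len(group) == 1:
            group[0].primary = True
            continue
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
        for a in group:
            a.primary = a is best


def _guess_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise ValueError(f"unknown format {fmt!r}; use 'pdb', 'mmcif' or 'auto'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # fall back on content sniffing
    head = path.read_text(errors="replace")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model of multi-model files is taken.  Waters are
    flagged (``is_solvent``) but retained; alternate locations are
    retained with the highest-occupancy conformer marked primary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinate models found")

    metadata: dict = {"format": fmt}
    if st.spacegroup_hm:
        metadata["space_group"] = st.spacegroup_hm
    cell = st.cell
    if cell and cell.a > 1.0:
        metadata["cell"] = (cell.a, cell.b, cell.c,
                            cell.alpha, cell.beta, cell.gamma)

    structure = Structure(id=st.name or path.stem, metadata=metadata)
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = []
            for atom in res:
                alt = atom.altloc if atom.altloc and atom.altloc != "\x00" else ""
                atoms.append(Atom(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    alt_loc=alt,
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=atom.b_iso,
                ))
            if not atoms:
                continue
            _mark_primary_altlocs(atoms)
            residues.append(Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                name=res.name,
                atoms=atoms,
            ))
        if residues:
            if chain.name in structure.chains:
                structure.chains[chain.name].extend(residues)
            else:
                structure.chains[chain.name] = residues
    return structure


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> Path:
    """Write a :class:`Structure` as PDB or mmCIF.

    PDB output is fixed-width: coordinates are rounded to 3 decimals and
    atom serials above 99999 raise :class:`SerialOverflowError`.
    """
    if s.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)

    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model(1)
    serial = 0
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
            if r.is_solvent:
                res.het_flag = "H"
            for a in r.atoms:
                serial = max(serial + 1, a.serial)
                if format == "pdb" and a.serial > 99999:
                    raise SerialOverflowError(
                        f"atom serial {a.serial} exceeds the PDB fixed-width "
                        f"field; write mmCIF instead")
                atom = gemmi.Atom()
                atom.name = a.name
                atom.serial = a.serial
                atom.element = gemmi.Element(a.element)
                atom.altloc = a.alt_loc or "\x00"
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                atom.pos = gemmi.Position(*np.round(a.coord, 3))
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

_CLAUSE_KEYS = ("chain", "resi", "resname", "name", "kind", "element", "all")


def _parse_int_ranges(text: str, position: int) -> set[int]:
    numbers: set[int] = set()
    for part in text.split(","):
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", part.strip())
        if not m:
            raise SelectionError(f"bad residue range {part!r}", position)
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(f"inverted range {part!r}", position)
        numbers.update(range(lo, hi + 1))
    return numbers


def _parse_query(query: str) -> list[tuple[str, object]]:
    clauses: list[tuple[str, object]] = []
    pos = 0
    for raw in query.split(" and "):
        clause = raw.strip()
        offset = query.find(raw, pos)
        pos = offset + len(raw)
        if not clause:
            raise SelectionError("empty clause", offset)
        parts = clause.split(None, 1)
        key = parts[0].lower()
        if key not in _CLAUSE_KEYS:
            raise SelectionError(f"unknown selection keyword {parts[0]!r}", offset)
        if key == "all":
            if len(parts) > 1:
                raise SelectionError("'all' takes no argument", offset)
            clauses.append(("all", None))
            continue
        if len(parts) != 2:
            raise SelectionError(f"keyword {key!r} needs an argument", offset)
        arg = parts[1].strip()
        if key == "resi":
            clauses.append((key, _parse_int_ranges(arg, offset)))
        elif key == "kind":
            if arg.lower() not in ("protein", "dna", "other"):
                raise SelectionError(f"unknown kind {arg!r}", offset)
            clauses.append((key, arg.lower()))
        else:
            values = {v.strip().upper() for v in arg.split(",") if v.strip()}
            if not values:
                raise SelectionError(f"keyword {key!r} needs an argument", offset)
            clauses.append((key, values))
    return clauses


def select(s: Structure, query: str) -> Structure:
    """Select a sub-structure by a simple ``and``-joined expression.

    Grammar (clauses joined with ``and``)::

        all | chain A[,B] | resi 10-20[,30] | resname LYS[,ARG]
            | name CA[,P] | kind protein|dna|other | element N[,O]

    ``chain``/``resi``/``resname``/``kind`` filter residues; ``name`` and
    ``element`` filter atoms within the surviving residues.  Selection is
    idempotent and may be empty.
    """
    clauses = _parse_query(query)

    def residue_ok(r: Residue) -> bool:
        for key, arg in clauses:
            if key == "chain" and r.chain_id.upper() not in arg:
                return False
            if key == "resi" and r.number not in arg:
                return False
            if key == "resname" and r.name.upper() not in arg:
                return False
            if key == "kind" and r.kind != arg:
                return False
        return True

    def atom_ok(a: Atom) -> bool:
        for key, arg in clauses:
            if key == "name" and a.name.upper() not in arg:
                return False
            if key == "element" and a.element.upper() not in arg:
                return False
        return True

    out = Structure(id=s.id, metadata=dict(s.metadata))
    for cid, residues in s.chains.items():
        kept: list[Residue] = []
        for r in residues:
            if not residue_ok(r):
                continue
            atoms = [a.copy() for a in r.atoms if atom_ok(a)]
            if atoms:
                kept.append(Residue(r.chain_id, r.number, r.name, atoms,
                                    r.insertion_code, r.kind, r.is_solvent))
        if kept:
            out.chains[cid] = kept
    return out


def count_atoms(s: Structure, include_hydrogen: bool = False,
                include_solvent: bool = False) -> int:
    """Count retained atoms, by default excluding hydrogens and waters.

    Alternate-location conformers each count once, matching how deposited
    models report their atom totals.
    """
    n = 0
    for r, a in s.atoms():
        if r.is_solvent and not include_solvent:
            continue
        if a.is_hydrogen and not include_hydrogen:
            continue
        n += 1
    return n
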