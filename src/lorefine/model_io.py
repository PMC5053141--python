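"""Lightweight macromolecular model with PDB input/output.

The model keeps author numbering (chain id, residue number, insertion
code) exactly as found in the file, because external-restraint keyword
files address atoms that way.  Parsing and serialization are delegated
to :mod:`gemmi`; only the highest-occupancy alternate conformation is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "FormatError",
    "EmptyModelError",
    "read_structure",
    "write_structure",
    "extract_chain_sequence",
    "MAINCHAIN_ATOMS",
    "STANDARD_AA",
]

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Three-letter code -> one-letter code for the 20 standard amino acids.
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """File could not be parsed as a macromolecular model."""


class EmptyModelError(ValueError):
    """Model contains no polymer chain."""


@dataclass(frozen=True)
class Atom:
    """A single atom with author addressing.

    ``residue_seq`` is the author residue number; together with
    ``chain_id``, ``icode`` and ``name`` it identifies the atom.
    """

    name: str
    element: str
    pos: tuple[float, float, float]
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chain_id, residue_seq, icode, name) — unique within a model."""
        return (self.chain_id, self.residue_seq, self.icode, self.name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_polymer(self) -> bool:
        """Amino-acid residue: standard name, or backbone N/CA/C present."""
        if self.name in _WATER_NAMES:
            return False
        if self.name in STANDARD_AA:
            return True
        present = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= present

    @property
    def one_letter(self) -> str:
        return STANDARD_AA.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def is_polymer(self) -> bool:
        return len(self.polymer_residues) > 0

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.polymer_residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        out = []
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    if include_hydrogens or not a.is_hydrogen:
                        out.append(a)
        return out

    def atom_index(self) -> dict[tuple[str, int, str, str], Atom]:
        return {a.key: a for a in self.atoms()}

    def copy_with_coords(self, coords: np.ndarray,
                         atoms: Iterable[Atom] | None = None) -> "Structure":
        """Return a deep copy with the coordinates of ``atoms`` replaced.

        ``coords`` is (n, 3) aligned with ``atoms`` (default: all
        non-hydrogen atoms in traversal order).
        """
        atoms = list(atoms) if atoms is not None else self.atoms()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array does not match atom list")
        new_pos = {a.key: tuple(float(x) for x in xyz)
                   for a, xyz in zip(atoms, coords)}
        new_chains = []
        for c in self.chains:
            new_residues = []
            for r in c.residues:
                new_atoms = [
                    replace(a, pos=new_pos[a.key]) if a.key in new_pos else a
                    for a in r.atoms
                ]
                new_residues.append(Residue(r.name, r.seq, r.icode,
                                            r.chain_id, new_atoms))
            new_chains.append(Chain(c.id, new_residues))
        return Structure(self.id, new_chains)


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; tie -> lexicographically first altloc
    return max(group, key=lambda a: (a.occ, -ord(a.altloc or "A")))


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Keeps the highest-occupancy alternate location per atom, retains
    waters and ligands (flagged non-polymer), and raises
    :class:`EmptyModelError` when no polymer chain is present.
    """
    path = Path(path)
    try:
        gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(gst) == 0:
        raise FormatError(f"{path} contains no model")
    model = gst[0]
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(Atom(
                    name=name,
                    element=ga.element.name,
                    pos=(ga.pos.x, ga.pos.y, ga.pos.z),
                    residue_name=gres.name,
                    residue_seq=gres.seqid.num,
                    icode=gres.seqid.icode.strip() or "",
                    chain_id=gch.name,
                ))
            residues.append(Residue(gres.name, gres.seqid.num,
                                    gres.seqid.icode.strip() or "",
                                    gch.name, atoms))
        chains.append(Chain(gch.name, residues))
    st = Structure(path.stem, chains)
    for a in st.atoms(include_hydrogens=True):
        if not all(np.isfinite(a.pos)):
            raise FormatError(f"non-finite coordinate on atom {a.key}")
    if not st.polymer_chains:
        raise EmptyModelError(f"{path} contains no polymer chain")
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB file.

    Round-trips coordinates to the fixed-width 3-decimal precision.
    Residue numbers outside the PDB fixed-width range are rejected.
    """
    if not structure.chains or not structure.atoms(include_hydrogens=True):
        raise ValueError("refusing to write an empty structure")
    gst = gemmi.Structure()
    gst.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            if not (-999 <= res.seq <= 9999):
                raise ValueError(
                    f"residue number {res.seq} outside PDB fixed-width range")
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq, res.icode or " ")
            if not res.is_polymer:
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    gst.add_model(model)
    gst.setup_entities()
    gst.write_pdb(str(path))


def extract_chain_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a polymer chain; nonstandard residues -> 'X'."""
    chain = structure.chain(chain_id)  # KeyError on unknown id
    if not chain.is_polymer:
        raise KeyError(f"chain {chain_id!r} is not a polymer chain")
    return chain.sequence
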