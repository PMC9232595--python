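"""Peptide-receptor complex structures.

A pHLA complex is read from a standard PDB file into a flat, ordered list of
heavy atoms grouped by (chain, residue). Only ATOM records survive: waters,
other heteroatoms and hydrogens are dropped at parse time, mirroring the
usual crystal-structure preprocessing for this system. Residues are
re-indexed 1-based per chain in file order so downstream position mapping
(peptide position 1..P, N- to C-terminus) is deterministic regardless of
author numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Elements the built-in energy backend knows radii for.
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


@dataclass(frozen=True)
class Atom:
    """A single heavy atom.

    ``residue_index`` is 1-based within its chain, in file order — not the
    author-assigned PDB residue number.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOMS


@dataclass
class Structure:
    """An ordered collection of atoms with designated peptide/receptor chains."""

    atoms: list[Atom]
    peptide_chain: str
    receptor_chain: str
    _residue_keys: list[tuple[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.peptide_chain == self.receptor_chain:
            raise ValueError("peptide and receptor chains must differ")
        seen: set[tuple[str, int, str]] = set()
        keys: list[tuple[str, int]] = []
        for a in self.atoms:
            ident = (a.chain_id, a.residue_index, a.atom_name)
            if ident in seen:
                raise ValueError(f"duplicate atom {ident}")
            seen.add(ident)
            key = (a.chain_id, a.residue_index)
            if not keys or keys[-1] != key:
                if key in keys:
                    raise ValueError(f"residue {key} atoms are not contiguous")
                keys.append(key)
        self._residue_keys = keys
        if not any(c == self.peptide_chain for c, _ in keys):
            raise ValueError(f"peptide chain {self.peptide_chain!r} has no residues")

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered (chain_id, residue_index) pairs covering all atoms."""
        return list(self._residue_keys)

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for c, _ in self._residue_keys:
            if c not in out:
                out.append(c)
        return out

    def peptide_residues(self) -> list[tuple[str, int]]:
        return [k for k in self._residue_keys if k[0] == self.peptide_chain]

    def peptide_length(self) -> int:
        return len(self.peptide_residues())

    def peptide_sequence(self) -> str:
        """One-letter peptide sequence (X for non-canonical residue names)."""
        names: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == self.peptide_chain:
                names.setdefault(a.residue_index, a.residue_name)
        return "".join(
            THREE_TO_ONE.get(names[i], "X") for i in sorted(names)
        )

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        moved = [
            Atom(a.chain_id, a.residue_index, a.residue_name, a.atom_name,
                 a.element, tuple(R @ np.asarray(a.xyz) + t))
            for a in self.atoms
        ]
        return Structure(moved, self.peptide_chain, self.receptor_chain)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


def read_pdb(path: str | Path, peptide_chain: str | None = None) -> Structure:
    """Read a peptide-receptor complex from a PDB file.

    Only ATOM records are kept; waters, HETATM entries and hydrogens are
    skipped. For alternate locations the first altloc is kept. Residues with
    insertion codes are rejected (deterministic 1-based indexing would be
    ambiguous).

    Parameters
    ----------
    path
        PDB file with at least two chains of ATOM records.
    peptide_chain
        Chain id of the peptide. If omitted, the chain with the fewest
        residues is designated peptide (ties: first such chain in file order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = next(parser.get_structure("complex", str(path)).get_models())

    atoms: list[Atom] = []
    residues_per_chain: dict[str, int] = {}
    chain_order: list[str] = []
    for chain in model:
        idx = 0
        for residue in chain:
            hetflag, _resseq, icode = residue.id
            if hetflag != " " or residue.get_resname().strip() in _WATER_NAMES:
                continue  # HETATM / water
            if icode.strip():
                raise ValueError(
                    f"insertion code {icode!r} in chain {chain.id} is unsupported"
                )
            idx += 1
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]  # first altloc
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(Atom(
                    chain_id=chain.id,
                    residue_index=idx,
                    residue_name=residue.get_resname().strip(),
                    atom_name=atom.get_name().strip(),
                    element=element,
                    xyz=tuple(float(x) for x in atom.coord),
                ))
        if idx:
            residues_per_chain[chain.id] = idx
            chain_order.append(chain.id)

    if len(residues_per_chain) < 2:
        raise ValueError(
            f"fewer than two chains with ATOM records in {path.name} "
            f"(found {sorted(residues_per_chain)})"
        )
    if peptide_chain is None:
        peptide_chain = min(chain_order, key=lambda c: residues_per_chain[c])
    elif peptide_chain not in residues_per_chain:
        raise ValueError(
            f"peptide chain {peptide_chain!r} absent from {path.name} "
            f"(chains: {sorted(residues_per_chain)})"
        )
    receptor_chain = max(
        (c for c in chain_order if c != peptide_chain),
        key=lambda c: residues_per_chain[c],
    )
    return Structure(atoms, peptide_chain=peptide_chain, receptor_chain=receptor_chain)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ATOM records (3-decimal coordinates, standard fixed columns)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} {a.chain_id}"
            f"{a.residue_index:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
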