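"""Simplified per-residue energy backend and energy-table exchange.

The scoring protocol consumes a per-residue decomposition of whole-structure
energy terms: a residues x terms matrix whose column sums equal the
whole-structure totals by construction. Production users import that table
from an external all-atom scorer (``load_energy_table``); the built-in
backend here computes a deliberately simple, fully documented set of
distance-based terms directly from coordinates so the entire pipeline is
exercisable from bare PDB files. It populates 8 of the 19 default schema
terms (Lennard-Jones attraction/repulsion, screened electrostatics, a burial
proxy for solvation, and four hydrogen-bond channels); the remaining terms
are identically zero. It makes no claim of physical accuracy — its job is to
produce residue-resolved, geometry-dependent signal with the exact shape and
bookkeeping of a real decomposition.

Every genuinely two-body contribution is split 50/50 between the two
residues involved, so per-term column sums reproduce whole-structure totals
exactly. The burial proxy is one-body (an atom counts its foreign-residue
neighbours) and is assigned wholly to the counting atom's residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .schema import DEFAULT_SCHEMA, EnergySchema
from .structure import ELEMENT_RADII, Structure

#: Residue-class charge carried by the first side-chain atom of a residue.
SIDECHAIN_CLASS_CHARGE = {
    "ASP": -1.0, "GLU": -1.0,
    "LYS": 1.0, "ARG": 1.0,
    "HIS": 0.5,
}

BACKBONE_N_CHARGE = 0.35
BACKBONE_O_CHARGE = -0.55


@dataclass(frozen=True)
class BackendParams:
    """Tunable constants of the built-in backend (distances in Angstrom)."""

    lj_cutoff: float = 6.0
    lj_epsilon: float = 0.1
    lj_rep_cap: float = 10.0          # per-pair cap on the repulsive part
    elec_cutoff: float = 5.5
    elec_constant: float = 332.0      # kcal*A/(mol*e^2), Coulomb with eps=r
    burial_cutoff: float = 5.0
    burial_polar: float = 0.05        # per foreign neighbour of an N/O atom
    burial_carbon: float = -0.02      # per foreign neighbour of a C atom
    hbond_min: float = 2.2
    hbond_max: float = 3.5
    hbond_energy: float = -1.0
    hbond_bb_seq_sep: int = 4         # same-chain backbone sep for "short range"


@dataclass
class PerResidueEnergyTable:
    """Residues x terms matrix of unweighted energies plus per-term totals."""

    residue_keys: list[tuple[str, int]]
    values: np.ndarray
    schema: EnergySchema
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residue_keys), self.schema.n_terms):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.residue_keys)} residues x {self.schema.n_terms} terms"
            )
        # Totals are column sums by construction; recompute rather than trust.
        self.totals = self.values.sum(axis=0)

    def row(self, chain_id: str, residue_index: int) -> np.ndarray:
        try:
            i = self.residue_keys.index((chain_id, residue_index))
        except ValueError:
            raise KeyError(f"residue ({chain_id!r}, {residue_index}) not in table") from None
        return self.values[i]

    def chain_rows(self, chain_id: str) -> np.ndarray:
        mask = [k[0] == chain_id for k in self.residue_keys]
        return self.values[np.asarray(mask, dtype=bool)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.term_names))
        df.insert(0, "residue_index", [k[1] for k in self.residue_keys])
        df.insert(0, "chain", [k[0] for k in self.residue_keys])
        return df


def _atom_charges(s: Structure) -> np.ndarray:
    """Per-atom partial charges of the minimal electrostatics model."""
    charges = np.zeros(len(s.atoms))
    first_sidechain_seen: set[tuple[str, int]] = set()
    for i, a in enumerate(s.atoms):
        if a.is_backbone:
            if a.atom_name == "N":
                charges[i] = BACKBONE_N_CHARGE
            elif a.atom_name == "O":
                charges[i] = BACKBONE_O_CHARGE
        else:
            key = (a.chain_id, a.residue_index)
            if key not in first_sidechain_seen:
                first_sidechain_seen.add(key)
                charges[i] = SIDECHAIN_CLASS_CHARGE.get(a.residue_name, 0.0)
    return charges


def score_structure(
    s: Structure,
    schema: EnergySchema = DEFAULT_SCHEMA,
    params: BackendParams = BackendParams(),
) -> PerResidueEnergyTable:
    """Decompose the built-in energy terms onto residues of both chains.

    All interactions run over inter-residue atom pairs (both chains,
    intra-chain included); same-residue pairs contribute nothing. See the
    module docstring for the term definitions.
    """
    if not s.atoms:
        raise ValueError("empty structure")
    for a in s.atoms:
        if a.element not in ELEMENT_RADII:
            raise ValueError(
                f"unknown element {a.element!r} on atom {a.atom_name} "
                f"({a.chain_id}{a.residue_index}): no radius defined"
            )

    keys = s.residue_keys
    key_index = {k: i for i, k in enumerate(keys)}
    n_res = len(keys)
    T = schema.n_terms
    values = np.zeros((n_res, T))

    col = {name: schema.index(name) for name in (
        "fa_atr", "fa_rep", "fa_sol", "fa_elec",
        "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc",
    ) if name in schema.term_names}

    xyz = s.coordinates()
    radii = np.array([ELEMENT_RADII[a.element] for a in s.atoms])
    charges = _atom_charges(s)
    res_of = np.array([key_index[(a.chain_id, a.residue_index)] for a in s.atoms])
    elements = np.array([a.element for a in s.atoms])
    backbone = np.array([a.is_backbone for a in s.atoms])
    chain = np.array([a.chain_id for a in s.atoms])
    resix = np.array([a.residue_index for a in s.atoms])

    max_cutoff = max(params.lj_cutoff, params.elec_cutoff, params.burial_cutoff)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(max_cutoff, output_type="ndarray")
    if pairs.size:
        ii, jj = pairs[:, 0], pairs[:, 1]
        inter = res_of[ii] != res_of[jj]
        ii, jj = ii[inter], jj[inter]
        r = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
    else:
        ii = jj = np.zeros(0, dtype=int)
        r = np.zeros(0)

    def _split(term: str, i_res: np.ndarray, j_res: np.ndarray, e: np.ndarray) -> None:
        c = col[term]
        np.add.at(values[:, c], i_res, 0.5 * e)
        np.add.at(values[:, c], j_res, 0.5 * e)

    # Lennard-Jones 12-6, WCA-style split: below the minimum the excess over
    # -epsilon is repulsion (capped); attraction saturates at -epsilon.
    m = r <= params.lj_cutoff
    if np.any(m):
        sigma = radii[ii[m]] + radii[jj[m]]
        sr6 = (sigma / r[m]) ** 6
        v = params.lj_epsilon * (sr6 * sr6 - 2.0 * sr6)
        inside = r[m] < sigma
        rep = np.where(inside, np.minimum(v + params.lj_epsilon, params.lj_rep_cap), 0.0)
        atr = np.where(inside, -params.lj_epsilon, v)
        _split("fa_atr", res_of[ii[m]], res_of[jj[m]], atr)
        _split("fa_rep", res_of[ii[m]], res_of[jj[m]], rep)

    # Coulomb with distance-dependent dielectric (1/r^2 falloff).
    m = r <= params.elec_cutoff
    if np.any(m):
        qq = charges[ii[m]] * charges[jj[m]]
        nz = qq != 0.0
        if np.any(nz):
            e = params.elec_constant * qq[nz] / r[m][nz] ** 2
            _split("fa_elec", res_of[ii[m]][nz], res_of[jj[m]][nz], e)

    # Burial proxy: each atom counts foreign-residue neighbours; polar atoms
    # pay a desolvation penalty, carbons gain. One-body: full value to the
    # counting atom's residue (both pair members count independently).
    m = r <= params.burial_cutoff
    if np.any(m):
        for side in (ii[m], jj[m]):
            polar = np.isin(elements[side], ("N", "O"))
            carbon = elements[side] == "C"
            np.add.at(values[:, col["fa_sol"]], res_of[side][polar], params.burial_polar)
            np.add.at(values[:, col["fa_sol"]], res_of[side][carbon], params.burial_carbon)

    # Hydrogen bonds: donor-N / acceptor-O pairs inside the distance window,
    # routed to one of four channels by atom class and sequence separation.
    m = (r >= params.hbond_min) & (r <= params.hbond_max)
    if np.any(m):
        a_, b_ = ii[m], jj[m]
        no = (elements[a_] == "N") & (elements[b_] == "O")
        on = (elements[a_] == "O") & (elements[b_] == "N")
        hb = no | on
        a_, b_ = a_[hb], b_[hb]
        bb_both = backbone[a_] & backbone[b_]
        bb_one = backbone[a_] ^ backbone[b_]
        same_chain = chain[a_] == chain[b_]
        close_seq = np.abs(resix[a_] - resix[b_]) <= params.hbond_bb_seq_sep
        routes = {
            "hbond_sr_bb": bb_both & same_chain & close_seq,
            "hbond_lr_bb": bb_both & ~(same_chain & close_seq),
            "hbond_bb_sc": bb_one,
            "hbond_sc": ~backbone[a_] & ~backbone[b_],
        }
        for term, mask in routes.items():
            if np.any(mask):
                e = np.full(mask.sum(), params.hbond_energy)
                _split(term, res_of[a_][mask], res_of[b_][mask], e)

    return PerResidueEnergyTable(residue_keys=keys, values=values, schema=schema)


def total_energy(table: PerResidueEnergyTable) -> float:
    """Weighted whole-structure energy: sum over terms of weight * total."""
    w = table.schema.weights_array()
    if w.shape[0] != table.totals.shape[0]:
        raise ValueError("schema/table width mismatch")
    return float(w @ table.totals)


def binding_energy(e_complex: float, e_receptor: float, e_peptide: float) -> float:
    """Binding energy as the complex energy minus the separated-chain energies."""
    return e_complex - (e_receptor + e_peptide)


def binding_energy_from_structure(
    s: Structure,
    schema: EnergySchema = DEFAULT_SCHEMA,
    params: BackendParams = BackendParams(),
) -> float:
    """Score the complex and its rigidly separated chains, then difference.

    The separated chains are scored as-is (no relaxation); with purely
    inter-atomic terms this equals the complex energy minus each chain's
    internal energy.
    """
    e_complex = total_energy(score_structure(s, schema, params))
    parts = []
    for chain_id in (s.receptor_chain, s.peptide_chain):
        atoms = [a for a in s.atoms if a.chain_id == chain_id]
        # Single-chain scoring: reuse Structure with a dummy counterpart id.
        other = "_" if chain_id != "_" else "-"
        sub = Structure(atoms, peptide_chain=chain_id, receptor_chain=other)
        parts.append(total_energy(score_structure(sub, schema, params)))
    return binding_energy(e_complex, parts[0], parts[1])


def save_energy_table(table: PerResidueEnergyTable, path: str | Path) -> None:
    """Write the TSV exchange format: chain, residue_index, one column per term."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def load_energy_table(
    path: str | Path, schema: EnergySchema = DEFAULT_SCHEMA
) -> PerResidueEnergyTable:
    """Load a per-residue energy table from TSV (e.g. an external decomposition).

    Term columns are matched to the schema by name, order-insensitive; totals
    are recomputed as column sums.
    """
    df = pd.read_csv(path, sep="\t")
    for needed in ("chain", "residue_index"):
        if needed not in df.columns:
            raise ValueError(f"missing column {needed!r}")
    missing = [t for t in schema.term_names if t not in df.columns]
    if missing:
        raise ValueError(f"missing term column(s): {', '.join(missing)}")
    keys = list(zip(df["chain"].astype(str), df["residue_index"].astype(int)))
    if len(set(keys)) != len(keys):
        dup = pd.Series(keys)[pd.Series(keys).duplicated()].iloc[0]
        raise ValueError(f"duplicate residue key {dup}")
    block = df[list(schema.term_names)]
    try:
        values = block.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric energy cell: {exc}") from None
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite energy cell")
    return PerResidueEnergyTable(residue_keys=keys, values=values, schema=schema)
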