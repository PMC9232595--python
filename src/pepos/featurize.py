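"""Feature representations built from per-residue energy tables.

Three representations of the same decomposition feed the three scoring
routes: (1) the baseline single number (weighted total, handled in
``energy``), (2) the standard aggregated vector of per-term whole-complex
totals, and (3) the per-peptide-position matrix — one row of unweighted term
values per peptide residue, stacked row-major into the model input. Keeping
positions separate is the point of the protocol: anchor positions buried in
the HLA groove carry signal that aggregation across the peptide destroys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import PerResidueEnergyTable
from .schema import DEFAULT_SCHEMA, EnergySchema
from .structure import Structure

CANONICAL_PEPTIDE_LENGTH = 9

ANCHOR_POSITIONS = (1, 2, 3, 8, 9)
MIDDLE_POSITIONS = (4, 5, 6, 7)


@dataclass(frozen=True)
class PositionSubset:
    """A named subset of 1-based peptide positions (on the 9-row matrix)."""

    name: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        if not pos:
            raise ValueError("position subset must be non-empty")
        if pos[0] < 1 or pos[-1] > CANONICAL_PEPTIDE_LENGTH:
            raise ValueError(f"positions out of range 1..9: {pos}")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def named(cls, name: str) -> "PositionSubset":
        """Resolve 'all' / 'anchor' / 'middle', or a comma list like '1,2,9'."""
        if name == "all":
            return cls("all", tuple(range(1, CANONICAL_PEPTIDE_LENGTH + 1)))
        if name == "anchor":
            return cls("anchor", ANCHOR_POSITIONS)
        if name == "middle":
            return cls("middle", MIDDLE_POSITIONS)
        try:
            positions = tuple(int(x) for x in name.split(","))
        except ValueError:
            raise ValueError(f"unknown position subset {name!r}") from None
        return cls("custom", positions)

    def column_indices(self, n_terms: int) -> np.ndarray:
        """Stacked-vector column indices selected by this subset."""
        return np.concatenate(
            [np.arange((p - 1) * n_terms, p * n_terms) for p in self.positions]
        )


SUBSET_ALL = PositionSubset.named("all")
SUBSET_ANCHOR = PositionSubset.named("anchor")
SUBSET_MIDDLE = PositionSubset.named("middle")


@dataclass
class StandardFeatureVector:
    """Whole-complex per-term totals, in schema order."""

    values: np.ndarray
    schema_fingerprint: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class PerPositionFeatureMatrix:
    """Peptide positions x terms matrix of unweighted per-residue energies.

    Row p (1-based) is peptide position p, N- to C-terminus.
    """

    values: np.ndarray
    schema_fingerprint: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def peptide_length(self) -> int:
        return self.values.shape[0]


def standard_features(table: PerResidueEnergyTable) -> StandardFeatureVector:
    """Aggregate the complex table to one value per term (column totals)."""
    return StandardFeatureVector(
        values=table.totals.copy(),
        schema_fingerprint=table.schema.fingerprint(),
    )


def per_position_features(
    table: PerResidueEnergyTable, s: Structure
) -> PerPositionFeatureMatrix:
    """Extract the peptide-chain rows of a complex table, N- to C-terminus."""
    rows = []
    for key in s.peptide_residues():
        rows.append(table.row(*key))  # KeyError if the residue is missing
    return PerPositionFeatureMatrix(
        values=np.vstack(rows),
        schema_fingerprint=table.schema.fingerprint(),
    )


def stack(m: PerPositionFeatureMatrix | np.ndarray) -> np.ndarray:
    """Row-major flattening: position-1 terms first, length P*T."""
    values = m.values if isinstance(m, PerPositionFeatureMatrix) else np.asarray(m)
    return values.reshape(-1).copy()


def unstack(v: np.ndarray, n_terms: int) -> np.ndarray:
    """Inverse of :func:`stack` given the number of terms per position."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size % n_terms:
        raise ValueError(f"vector of length {v.size} is not a multiple of {n_terms}")
    return v.reshape(-1, n_terms)


def select_positions(
    m: PerPositionFeatureMatrix, subset: PositionSubset
) -> PerPositionFeatureMatrix:
    """Restrict to the subset's rows, order preserved."""
    if subset.positions[-1] > m.peptide_length:
        raise ValueError(
            f"position {subset.positions[-1]} out of range for a "
            f"{m.peptide_length}-mer"
        )
    idx = [p - 1 for p in subset.positions]
    return PerPositionFeatureMatrix(m.values[idx], m.schema_fingerprint)


def reduce_10mer(
    m: PerPositionFeatureMatrix | np.ndarray,
) -> PerPositionFeatureMatrix | np.ndarray:
    """Map a 10-position matrix onto the canonical 9 by dropping position 6.

    Anchors and termini keep their identity: original positions 1-5 stay
    1-5, positions 7-10 become 6-9. Middle positions tolerate the shift;
    anchor biology lives at the ends.
    """
    is_wrapped = isinstance(m, PerPositionFeatureMatrix)
    values = m.values if is_wrapped else np.atleast_2d(np.asarray(m, dtype=float))
    if values.shape[0] != 10:
        raise ValueError(f"reduce_10mer needs a 10-position matrix, got P={values.shape[0]}")
    reduced = np.delete(values, 5, axis=0)  # row index 5 == position 6
    if is_wrapped:
        return PerPositionFeatureMatrix(reduced, m.schema_fingerprint)
    return reduced


@dataclass
class FeatureDataset:
    """Per-complex records: id, allele, peptide, per-position matrix, affinity.

    ``matrices[i]`` is the P_i x T per-position matrix of record i (P_i is 9,
    or 10 before reduction). Standard features and the baseline score derive
    from it by aggregation. ``scaled`` is the regression target in [0, 1];
    ``ic50_nM`` may be NaN where only labels are known.
    """

    ids: list[str]
    alleles: list[str]
    peptides: list[str]
    matrices: list[np.ndarray]
    ic50_nM: np.ndarray
    scaled: np.ndarray
    schema: EnergySchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    is_binder: np.ndarray | None = None   # set on screening benchmarks

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.ic50_nM = np.asarray(self.ic50_nM, dtype=float)
        self.scaled = np.asarray(self.scaled, dtype=float)
        if not (len(self.alleles) == len(self.peptides) == len(self.matrices)
                == self.ic50_nM.size == self.scaled.size == n):
            raise ValueError("inconsistent record counts")
        self.matrices = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.matrices]
        if self.is_binder is not None:
            self.is_binder = np.asarray(self.is_binder, dtype=bool)
            if self.is_binder.size != n:
                raise ValueError("is_binder length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_terms(self) -> int:
        return self.schema.n_terms

    def subset(self, indices) -> "FeatureDataset":
        idx = np.asarray(indices, dtype=int)
        return FeatureDataset(
            ids=[self.ids[i] for i in idx],
            alleles=[self.alleles[i] for i in idx],
            peptides=[self.peptides[i] for i in idx],
            matrices=[self.matrices[i] for i in idx],
            ic50_nM=self.ic50_nM[idx],
            scaled=self.scaled[idx],
            schema=self.schema,
            is_binder=None if self.is_binder is None else self.is_binder[idx],
        )

    def allele_indices(self, allele: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.alleles) == allele)

    def unique_alleles(self) -> list[str]:
        seen: list[str] = []
        for a in self.alleles:
            if a not in seen:
                seen.append(a)
        return seen

    def stacked(self, reduce_long: bool = True) -> np.ndarray:
        """n x (9*T) matrix of stacked per-position features.

        10-position matrices are first mapped to 9 via :func:`reduce_10mer`
        when ``reduce_long``; any other length is an error.
        """
        rows = []
        for m in self.matrices:
            if m.shape[0] == 10 and reduce_long:
                m = reduce_10mer(m)
            if m.shape[0] != CANONICAL_PEPTIDE_LENGTH:
                raise ValueError(f"unsupported peptide length {m.shape[0]}")
            rows.append(m.reshape(-1))
        return np.vstack(rows) if rows else np.empty((0, 9 * self.n_terms))

    def standard_matrix(self) -> np.ndarray:
        """n x T matrix of column-summed (aggregated) features."""
        return np.vstack([m.sum(axis=0) for m in self.matrices])

    def baseline_scores(self) -> np.ndarray:
        """Weighted total energy per record (more negative = stronger)."""
        w = self.schema.weights_array()
        return np.array([float(m.sum(axis=0) @ w) for m in self.matrices])

    # -- CSV exchange ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """One row per complex; f_p{pos}_{term} columns in stacking order.

        Mixed peptide lengths pad short records with empty cells.
        """
        p_max = max((m.shape[0] for m in self.matrices), default=0)
        terms = self.schema.term_names
        cols = [f"f_p{p}_{t}" for p in range(1, p_max + 1) for t in terms]
        data = np.full((len(self), p_max * len(terms)), np.nan)
        for i, m in enumerate(self.matrices):
            data[i, : m.size] = m.reshape(-1)
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "scaled", self.scaled)
        df.insert(0, "ic50_nM", self.ic50_nM)
        df.insert(0, "peptide", self.peptides)
        df.insert(0, "allele", self.alleles)
        df.insert(0, "complex_id", self.ids)
        if self.is_binder is not None:
            df.insert(5, "is_binder", self.is_binder.astype(int))
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: EnergySchema = DEFAULT_SCHEMA
    ) -> "FeatureDataset":
        df = pd.read_csv(path)
        terms = schema.term_names
        matrices = []
        for _, row in df.iterrows():
            plen = len(str(row["peptide"]))
            vals = [row[f"f_p{p}_{t}"] for p in range(1, plen + 1) for t in terms]
            matrices.append(np.asarray(vals, dtype=float).reshape(plen, len(terms)))
        is_binder = (
            df["is_binder"].to_numpy(dtype=bool) if "is_binder" in df.columns else None
        )
        return cls(
            ids=df["complex_id"].astype(str).tolist(),
            alleles=df["allele"].astype(str).tolist(),
            peptides=df["peptide"].astype(str).tolist(),
            matrices=matrices,
            ic50_nM=df["ic50_nM"].to_numpy(dtype=float),
            scaled=df["scaled"].to_numpy(dtype=float),
            schema=schema,
            is_binder=is_binder,
        )

    @staticmethod
    def concatenate(parts: list["FeatureDataset"]) -> "FeatureDataset":
        first = parts[0]
        is_binder = None
        if all(p.is_binder is not None for p in parts):
            is_binder = np.concatenate([p.is_binder for p in parts])
        return FeatureDataset(
            ids=sum((p.ids for p in parts), []),
            alleles=sum((p.alleles for p in parts), []),
            peptides=sum((p.peptides for p in parts), []),
            matrices=sum((p.matrices for p in parts), []),
            ic50_nM=np.concatenate([p.ic50_nM for p in parts]),
            scaled=np.concatenate([p.scaled for p in parts]),
            schema=first.schema,
            is_binder=is_binder,
        )
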