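"""Energy-term schema.

The scoring protocol is agnostic to where per-residue energies come from
(the built-in simplified backend, or tables imported from an external
all-atom scorer); what matters is a stable, ordered roster of named terms.
The default roster is the 19 terms of Rosetta's ref2015 energy function,
so imported ref2015 decompositions drop straight in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

#: Canonical ref2015 term roster, in conventional order.
REF2015_TERMS: tuple[str, ...] = (
    "fa_atr",
    "fa_rep",
    "fa_sol",
    "fa_intra_rep",
    "fa_intra_sol_xover4",
    "lk_ball_wtd",
    "fa_elec",
    "pro_close",
    "hbond_sr_bb",
    "hbond_lr_bb",
    "hbond_bb_sc",
    "hbond_sc",
    "dslf_fa13",
    "omega",
    "fa_dun",
    "p_aa_pp",
    "yhh_planarity",
    "ref",
    "rama_prepro",
)


@dataclass(frozen=True)
class EnergySchema:
    """Ordered, named list of energy terms with per-term weights.

    Parameters
    ----------
    term_names
        Unique term names, order defines column order everywhere downstream.
    term_weights
        One weight per term, used only when collapsing a table to a single
        total energy. Defaults to all ones.
    """

    term_names: tuple[str, ...] = REF2015_TERMS
    term_weights: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(self.term_names)
        object.__setattr__(self, "term_names", names)
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")
        if self.term_weights is None:
            object.__setattr__(self, "term_weights", (1.0,) * len(names))
        else:
            weights = tuple(float(w) for w in self.term_weights)
            if len(weights) != len(names):
                raise ValueError(
                    f"{len(weights)} weights for {len(names)} terms"
                )
            object.__setattr__(self, "term_weights", weights)

    @property
    def n_terms(self) -> int:
        return len(self.term_names)

    def index(self, name: str) -> int:
        try:
            return self.term_names.index(name)
        except ValueError:
            raise KeyError(f"unknown energy term {name!r}") from None

    def weights_array(self) -> np.ndarray:
        return np.asarray(self.term_weights, dtype=float)

    def fingerprint(self) -> str:
        """Short stable hash of names+weights; stored with trained models so
        scoring can refuse features produced under a different schema."""
        payload = ";".join(self.term_names) + "|" + ",".join(
            f"{w:.12g}" for w in self.term_weights
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


#: Module-level default: 19 ref2015 terms, unit weights.
DEFAULT_SCHEMA = EnergySchema()
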