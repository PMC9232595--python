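"""Synthetic structures and feature-level datasets with known ground truth.

Real training corpora for this problem are tens of thousands of modeled pHLA
structures with an all-atom energy decomposition; neither is distributable
here. These generators emulate their statistical shape at desk scale:

- :func:`gen_toy_complex` builds a geometric stand-in for a pHLA complex (two
  backbone strands as groove walls, a peptide laid between them) to exercise
  the energy backend on realistic shapes.
- :func:`gen_feature_dataset` draws per-position energy-term matrices from
  allele-shifted distributions and plants a position-dependent, optionally
  non-additive affinity signal. The default ``threshold_interaction`` signal
  lives at the canonical anchor positions 2 and 9 and is deliberately
  destroyed by summing across positions — the property the per-position
  protocol exists to exploit.
- :func:`gen_screening_benchmark` and :func:`gen_crystal_like_set` mirror the
  compositions of a binder/decoy screening set (100 binders + 2000 decoys
  across 16 alleles) and a crystal-derived set (82 structures, 16 peptides,
  one allele, three 10-mers).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .affinity import scale_affinity, unscale_affinity
from .featurize import FeatureDataset
from .schema import DEFAULT_SCHEMA, EnergySchema
from .structure import ONE_TO_THREE, Atom, Structure, write_pdb

#: Per-term base distributions (mean, sd) of per-residue unweighted energies,
#: loosely shaped like real all-atom decompositions (attraction dominates and
#: is negative, repulsion/solvation positive, hbond channels small negative).
TERM_BASE: dict[str, tuple[float, float]] = {
    "fa_atr": (-2.5, 0.8),
    "fa_rep": (0.8, 0.3),
    "fa_sol": (1.2, 0.5),
    "fa_intra_rep": (0.4, 0.15),
    "fa_intra_sol_xover4": (0.3, 0.1),
    "lk_ball_wtd": (-0.3, 0.15),
    "fa_elec": (-0.8, 0.5),
    "pro_close": (0.1, 0.05),
    "hbond_sr_bb": (-0.3, 0.2),
    "hbond_lr_bb": (-0.2, 0.15),
    "hbond_bb_sc": (-0.15, 0.1),
    "hbond_sc": (-0.1, 0.1),
    "dslf_fa13": (0.0, 0.01),
    "omega": (0.2, 0.1),
    "fa_dun": (1.5, 0.6),
    "p_aa_pp": (-0.2, 0.15),
    "yhh_planarity": (0.02, 0.01),
    "ref": (0.5, 0.3),
    "rama_prepro": (0.1, 0.2),
}

#: Default allele roster cycled through by the generators.
ALLELE_ROSTER = (
    "HLA-A0201", "HLA-A0101", "HLA-A0301", "HLA-A1101", "HLA-A2402",
    "HLA-B0702", "HLA-B0801", "HLA-B1501", "HLA-B2705", "HLA-B3501",
    "HLA-B4001", "HLA-B5701", "HLA-C0401", "HLA-C0702", "HLA-C0501",
    "HLA-A6802",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed toy peptides (well-known HLA-A*02:01 epitopes) so toy-complex
#: energies depend on the seed only through coordinate jitter.
TOY_PEPTIDES = {9: "ILKEPVHGV", 10: "FLPSDFFPSV"}


@dataclass(frozen=True)
class SignalSpec:
    """Where and how the affinity signal enters the energy matrices.

    ``signal_positions`` carry the signal through ``signal_term``; all other
    entries are pure allele-shifted noise. ``nonlinearity``:

    - ``threshold_interaction`` (default): the first signal variable counts
      only when a gate variable is favourable — a non-additive interaction
      that column-summing across positions cannot represent;
    - ``saturating``: logistic squash of the summed signal variables;
    - ``linear``: affine in the summed signal variables.

    ``noise_sd`` is Gaussian noise on the scaled-affinity target;
    ``allele_shift_scale`` scales per-allele offsets of the term means (in
    units of each term's sd).
    """

    signal_positions: tuple[int, ...] = (2, 9)
    signal_term: str = "fa_atr"
    gate_term: str = "fa_elec"
    effect_size: float = 1.0
    nonlinearity: str = "threshold_interaction"
    noise_sd: float = 0.05
    allele_shift_scale: float = 0.3

    def __post_init__(self) -> None:
        if not self.signal_positions or not set(self.signal_positions) <= set(range(1, 10)):
            raise ValueError("signal_positions must be a non-empty subset of 1..9")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in ("threshold_interaction", "saturating", "linear"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @classmethod
    def anchor_signal(cls, **kw) -> "SignalSpec":
        """Signal at the canonical anchors 2 and 9 (the default)."""
        return cls(signal_positions=(2, 9), **kw)

    @classmethod
    def b0801_like(cls, **kw) -> "SignalSpec":
        """Signal concentrated at middle position 5, as for HLA-B*08:01
        binders, where position 5 dominates the binding motif."""
        return cls(signal_positions=(5,), **kw)


def _base_arrays(schema: EnergySchema) -> tuple[np.ndarray, np.ndarray]:
    mu = np.array([TERM_BASE.get(t, (0.0, 0.1))[0] for t in schema.term_names])
    sd = np.array([TERM_BASE.get(t, (0.0, 0.1))[1] for t in schema.term_names])
    return mu, sd


def _allele_shifts(n_alleles: int, spec: SignalSpec, schema: EnergySchema,
                   seed: int) -> np.ndarray:
    """Per-allele mean offsets (alleles x terms), in units of each term's sd."""
    _, sd = _base_arrays(schema)
    rng = np.random.default_rng([seed, 9001])
    return rng.normal(0.0, spec.allele_shift_scale, size=(n_alleles, schema.n_terms)) * sd


def signal_g(z: np.ndarray, w: np.ndarray, spec: SignalSpec) -> np.ndarray:
    """Noiseless scaled affinity from standardized signal variables.

    ``z``: (n, k) z-scores of the negated signal term at the signal positions
    (more favourable energy = larger z). ``w``: (n,) z-score of the negated
    gate term at the first signal position (used by the single-position
    threshold interaction).
    """
    e = spec.effect_size
    if spec.nonlinearity == "linear":
        return 0.5 + 0.18 * e * z.sum(axis=1) / max(1.0, np.sqrt(z.shape[1] / 2))
    if spec.nonlinearity == "saturating":
        return expit(0.9 * e * z.sum(axis=1) * np.sqrt(2.0 / max(2, z.shape[1])))
    # threshold interaction
    u = z[:, 0]
    v = z[:, 1] if z.shape[1] > 1 else w
    return np.clip(0.5 + 0.35 * e * u * (v > 0) + 0.15 * e * v, 0.0, 1.0)


def _encode_targets(y: np.ndarray, spec: SignalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Signal z-scores (n, k) and gate z-scores (n,) realizing noiseless g = y."""
    y = np.clip(np.asarray(y, dtype=float), 0.01, 0.99)
    k = len(spec.signal_positions)
    e = spec.effect_size
    if spec.nonlinearity == "linear":
        total = (y - 0.5) / (0.18 * e) * max(1.0, np.sqrt(k / 2))
        return np.tile((total / k)[:, None], (1, k)), np.ones_like(y)
    if spec.nonlinearity == "saturating":
        total = logit(y) / (0.9 * e * np.sqrt(2.0 / max(2, k)))
        return np.tile((total / k)[:, None], (1, k)), np.ones_like(y)
    # threshold interaction: open the gate (v = 1) and solve for u.
    u = (y - 0.5 - 0.15 * e) / (0.35 * e)
    z = np.ones((y.size, k))
    z[:, 0] = u
    if k > 1:
        z[:, 1] = 1.0
    return z, np.ones_like(y)


def _random_peptides(rng: np.random.Generator, n: int, length: int = 9) -> list[str]:
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(letters, size=length)) for _ in range(n)]


def gen_feature_dataset(
    n_alleles: int = 4,
    n_per_allele: int = 2000,
    spec: SignalSpec = SignalSpec(),
    seed: int = 0,
    schema: EnergySchema = DEFAULT_SCHEMA,
    return_truth: bool = False,
):
    """Draw a per-position feature dataset with a planted affinity signal.

    Each record is a 9 x T matrix whose entries follow allele-shifted normal
    distributions; the scaled affinity is ``clip(g(matrix) + noise, 0, 1)``
    where g depends only on the signal entries through the spec's
    nonlinearity. With ``return_truth`` the noiseless g values are returned
    alongside for oracle checks.
    """
    if n_per_allele < 20:
        raise ValueError("n_per_allele must be >= 20")
    mu, sd = _base_arrays(schema)
    shifts = _allele_shifts(n_alleles, spec, schema, seed)
    t_sig = schema.index(spec.signal_term)
    t_gate = schema.index(spec.gate_term)
    pos = [p - 1 for p in spec.signal_positions]

    parts: list[FeatureDataset] = []
    truths: list[np.ndarray] = []
    for a in range(n_alleles):
        allele = ALLELE_ROSTER[a % len(ALLELE_ROSTER)]
        rng = np.random.default_rng([seed, a])
        n = n_per_allele
        mats = rng.normal(mu + shifts[a], sd, size=(n, 9, schema.n_terms))
        # z-scores of the negated signal entries under the allele's own means.
        z = (mu[t_sig] + shifts[a, t_sig] - mats[:, pos, t_sig]) / sd[t_sig]
        w = (mu[t_gate] + shifts[a, t_gate] - mats[:, pos[0], t_gate]) / sd[t_gate]
        g = signal_g(z, w, spec)
        scaled = np.clip(g + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 1.0)
        # Keep IC50 invertible at the rails (the scale transform clamps there).
        ic50 = unscale_affinity(np.clip(scaled, 1e-6, 1.0))
        parts.append(FeatureDataset(
            ids=[f"{allele}_{i:05d}" for i in range(n)],
            alleles=[allele] * n,
            peptides=_random_peptides(rng, n),
            matrices=list(mats),
            ic50_nM=ic50,
            scaled=scaled,
            schema=schema,
        ))
        truths.append(g)
    data = FeatureDataset.concatenate(parts)
    if return_truth:
        return data, np.concatenate(truths)
    return data


def _matrices_for_targets(
    y: np.ndarray,
    spec: SignalSpec,
    schema: EnergySchema,
    rng: np.random.Generator,
    shift: np.ndarray,
    length: int = 9,
) -> list[np.ndarray]:
    """Base-distribution matrices whose signal entries encode noiseless g = y."""
    mu, sd = _base_arrays(schema)
    n = y.size
    mats = rng.normal(mu + shift, sd, size=(n, 9, schema.n_terms))
    z, w = _encode_targets(y, spec)
    t_sig = schema.index(spec.signal_term)
    t_gate = schema.index(spec.gate_term)
    pos = [p - 1 for p in spec.signal_positions]
    for j, p in enumerate(pos):
        mats[:, p, t_sig] = mu[t_sig] + shift[t_sig] - sd[t_sig] * z[:, j]
    if len(pos) == 1:  # single-position gate carries the interaction partner
        mats[:, pos[0], t_gate] = mu[t_gate] + shift[t_gate] - sd[t_gate] * w
    if length == 10:
        # Insert a signal-free middle row at position 6; anchors keep their
        # identity at the termini, matching how 10-mers are reduced.
        extra = rng.normal(mu + shift, sd, size=(n, 1, schema.n_terms))
        mats = np.concatenate([mats[:, :5], extra, mats[:, 5:]], axis=1)
    return list(mats)


def gen_screening_benchmark(
    n_binders: int = 100,
    n_decoys: int = 2000,
    n_alleles: int = 16,
    spec: SignalSpec = SignalSpec(),
    seed: int = 0,
    schema: EnergySchema = DEFAULT_SCHEMA,
) -> FeatureDataset:
    """Binder/decoy screening set emulating an epitope-discovery benchmark.

    Binders carry true scaled affinities at strong-binder level (>= the
    scaled value of 50 nM); decoys sit well below, so every binder's true
    affinity exceeds every decoy's. Alleles are assigned round-robin within
    each class.
    """
    if min(n_binders, n_decoys, n_alleles) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng([seed, 7])
    shifts = _allele_shifts(n_alleles, spec, schema, seed)
    y_bind = rng.uniform(scale_affinity(50.0), 0.98, size=n_binders)
    y_decoy = rng.uniform(0.02, 0.35, size=n_decoys)
    parts = []
    for y, is_binder, tag in ((y_bind, True, "binder"), (y_decoy, False, "decoy")):
        alleles = [ALLELE_ROSTER[i % n_alleles] for i in range(y.size)]
        mats: list[np.ndarray] = []
        for i, allele in enumerate(alleles):
            a = ALLELE_ROSTER.index(allele)
            mats.extend(_matrices_for_targets(
                y[i:i + 1], spec, schema, rng, shifts[a]))
        parts.append(FeatureDataset(
            ids=[f"{tag}_{i:04d}" for i in range(y.size)],
            alleles=alleles,
            peptides=_random_peptides(rng, y.size),
            matrices=mats,
            ic50_nM=unscale_affinity(y),
            scaled=y,
            schema=schema,
            is_binder=np.full(y.size, is_binder),
        ))
    return FeatureDataset.concatenate(parts)


def gen_crystal_like_set(
    spec: SignalSpec = SignalSpec(),
    seed: int = 0,
    schema: EnergySchema = DEFAULT_SCHEMA,
    structures_per_crystal_peptide: int = 7,
    jitter_sd: float = 0.10,
    allele: str = "HLA-A0201",
) -> FeatureDataset:
    """Single-allele set with repeated structures per peptide and 10-mers.

    Default composition mirrors a crystal-derived evaluation set: 11 peptides
    spanning strong ([0-5] nM), medium ([50-500] nM) and weak ([500-25000]
    nM) classes with several alternative structures each, plus 5 modeled
    non-binders with one structure each — 16 peptides, 82 structures, three
    of the crystal peptides being 10-mers. Alternative structures of a
    peptide are jittered copies of its base matrix (``jitter_sd`` in units of
    each term's sd), so within-peptide score spread stays below between-class
    differences for any faithful scorer.
    """
    rng = np.random.default_rng([seed, 13])
    mu, sd = _base_arrays(schema)
    a = ALLELE_ROSTER.index(allele) if allele in ALLELE_ROSTER else 0
    shift = _allele_shifts(max(a + 1, 1), spec, schema, seed)[a]

    ic50s: list[float] = []
    classes = [("strong", 0.5, 5.0, 4), ("medium", 50.0, 500.0, 4),
               ("weak", 500.0, 25_000.0, 3)]
    for _, lo, hi, count in classes:
        ic50s.extend(np.exp(rng.uniform(np.log(lo), np.log(hi), size=count)))
    n_crystal = len(ic50s)                       # 11 crystal-backed peptides
    ic50s.extend(rng.uniform(30_000.0, 49_000.0, size=5))  # modeled non-binders
    ic50s = np.asarray(ic50s)
    y = scale_affinity(ic50s)

    # Three of the crystal peptides are 10-mers: one per binder class.
    lengths = [9] * len(ic50s)
    for i in (0, 4, 8):
        lengths[i] = 10
    peptides = []
    for L in lengths:
        peptides.append(_random_peptides(rng, 1, length=L)[0])

    ids, alleles_out, peps, mats, ic50_out, scaled_out = [], [], [], [], [], []
    for i, (pep, L) in enumerate(zip(peptides, lengths)):
        n_structs = structures_per_crystal_peptide if i < n_crystal else 1
        base = _matrices_for_targets(
            np.array([y[i]]), spec, schema, rng, shift, length=L)[0]
        for k in range(n_structs):
            m = base + rng.normal(0.0, jitter_sd * sd, size=base.shape)
            ids.append(f"pep{i:02d}_s{k}")
            alleles_out.append(allele)
            peps.append(pep)
            mats.append(m)
            ic50_out.append(ic50s[i])
            scaled_out.append(y[i])
    return FeatureDataset(
        ids=ids, alleles=alleles_out, peptides=peps, matrices=mats,
        ic50_nM=np.asarray(ic50_out), scaled=np.asarray(scaled_out),
        schema=schema,
    )


# -- toy structures ------------------------------------------------------------


def gen_toy_complex(
    seed: int = 0,
    peptide_length: int = 9,
    perturbation_scale: float = 0.1,
    out: str | Path | None = None,
) -> Structure:
    """Geometric stand-in for a pHLA complex.

    Receptor chain A: two parallel backbone strands (groove walls) of 30
    residues each, ideal 3.8 A CA spacing, N/CA/C/O atoms. Peptide chain C:
    ``peptide_length`` residues laid along the groove axis between the walls,
    each with backbone atoms and one side-chain pseudo-atom (CB). All
    coordinates get Gaussian jitter of ``perturbation_scale`` (A). The
    peptide sequence is fixed per length so zero-jitter complexes are
    seed-independent.
    """
    if peptide_length not in TOY_PEPTIDES:
        raise ValueError(f"peptide_length must be one of {sorted(TOY_PEPTIDES)}")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []

    def backbone(cx: float, cy: float, cz: float, toward: float):
        """Backbone offsets with the carbonyl O tilted toward the groove."""
        return {
            "N": (cx - 1.2, cy + 0.4 * toward, cz),
            "CA": (cx, cy, cz),
            "C": (cx + 1.2, cy + 0.4 * toward, cz),
            "O": (cx + 1.4, cy + 1.5 * toward, cz + 0.3),
        }

    half_wall = 30
    groove = 4.2  # wall-to-axis distance; close enough for contacts
    res = 0
    for strand, ysign in ((0, -1.0), (1, +1.0)):
        for i in range(half_wall):
            res += 1
            for name, xyz in backbone(3.8 * i, ysign * groove, 0.6 * ysign, -ysign).items():
                jit = rng.normal(0.0, perturbation_scale, size=3)
                atoms.append(Atom("A", res, "GLY", name, name[0],
                                  tuple(np.asarray(xyz) + jit)))

    seq = TOY_PEPTIDES[peptide_length]
    x0 = 3.8 * (half_wall - peptide_length) / 2.0
    for i, aa in enumerate(seq):
        resname = ONE_TO_THREE[aa]
        coords = backbone(x0 + 3.8 * i, 0.0, 0.3, 1.0)
        coords["CB"] = (x0 + 3.8 * i, -0.4, 0.3 + 1.5 * (-1) ** i)
        for name, xyz in coords.items():
            jit = rng.normal(0.0, perturbation_scale, size=3)
            element = "C" if name in ("CA", "C", "CB") else name[0]
            atoms.append(Atom("C", i + 1, resname, name, element,
                              tuple(np.asarray(xyz) + jit)))

    s = Structure(atoms, peptide_chain="C", receptor_chain="A")
    if out is not None:
        write_pdb(s, out)
    return s
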