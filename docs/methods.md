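# Methods

## The scoring problem and the protocol

A pHLA complex is scored from a per-residue decomposition of its energy: a
residues × terms matrix `V` whose column sums are the whole-structure term
totals `T_t` (conservation holds by construction, to 1e−9). Three routes map
this decomposition to a binding score:

1. **Baseline energy score.** `E_binding = E_complex − (E_receptor +
   E_peptide)`, with each `E` the weighted sum `Σ_t w_t T_t`. The separated
   chains are scored rigidly as-is (no relaxation); since every modeled term
   is inter-atomic, this difference isolates the inter-chain contribution.
   Lower is stronger; for comparison with trained scores it is min–max
   normalized and inverted.
2. **Standard (aggregated) features.** The vector of whole-complex totals
   `(T_1 … T_19)`, fed to a learned regressor. This is the conventional
   "re-weight the terms for the system" protocol.
3. **Per-position features.** The peptide-chain rows of `V` only, as a
   9 × 19 matrix (positions N→C), stacked row-major into a 171-vector.
   Entries are *unweighted* per-residue term values — re-weighting is the
   learner's job. This is the package's reason to exist: anchor-position
   contributions interact non-additively with the groove, and column-summing
   destroys exactly that structure.

Position subsets support the ablation design: `anchor` = {1, 2, 3, 8, 9},
`middle` = {4, 5, 6, 7}, `all` = {1..9}, or any custom subset. 10-mer
peptides are mapped onto the canonical 9 rows by deleting position 6 (the
most central, least anchor-like residue): original rows 1–5 keep their
index, rows 7–10 become 6–9, so both termini — where anchor biology lives —
keep their identity. Ablation subsets are defined on the post-reduction
matrix.

## Affinity target

IC50 (nM, lower = stronger) maps to the regression target
`s = clamp(1 − log(IC50)/log(50000), 0, 1)`: 1 nM → 1, ≥ 50 µM → 0, strictly
decreasing in between; the log base cancels. Clamping is applied after the
transform (sub-nanomolar affinities saturate at 1). Binary labels use
inclusive thresholds at 50 nM (strong), 500 nM (strong+medium) and 25000 nM
(any binder); the printed class ranges ([0–5], [50–500], [500–25000] nM) are
closed, hence the inclusive boundary.

## Training protocol

Models are trained per allele (an `AlleleModel` records allele, position
subset, schema fingerprint, hyperparameters, CV record and seed):

- **Split.** 90/10 train/test, stratified *within* binders (IC50 ≤ 500 nM —
  the conventional binder cutoff) and non-binders separately: each class is
  cut into 10 affinity-quantile strata and 10% is drawn from each, so train
  and test carry equally distributed affinities. Strata smaller than 2
  collapse into a neighbour (logged). The 500 nM class boundary and the
  10-strata quantile binning are this package's concrete reading of
  "equally distributed affinities"; both are parameters of `SplitSpec`.
- **Folds.** Affinity-stratified 5-fold CV: records ordered by target,
  consecutive blocks of k dealt one-per-fold in random order. Fold sizes
  differ by ≤ 1 and per-fold affinity quartile counts by ≤ 1.
- **Search.** Randomized search (default 30 draws, without replacement;
  exhaustive if the grid is smaller) over trees {50, 100, 200, 400},
  features per split {sqrt, 0.3, 0.6, 1.0}, depth {∞, 8, 16, 32}, minimum
  leaf {1, 2, 5, 10}; scored by mean CV MAE (matching the split criterion);
  ties break toward fewer trees, then shallower depth.
- **Learner.** Random forest of CART trees with the absolute-error split
  criterion and bootstrap aggregation (scikit-learn
  `RandomForestRegressor(criterion="absolute_error")`). Predictions are the
  tree mean clamped to [0, 1]. Alternative regressors (linear, RBF-SVR,
  2-component PLS) run through the identical pipeline via
  `regressor_kind`; their settings are plain defaults, documented here
  rather than tuned.
- The estimator (`PositionEnergyRegressor`) is a scikit-learn
  `BaseEstimator`/`RegressorMixin`, so it clones, participates in pipelines
  and model selection, and exposes the featurization and position subset as
  ordinary hyperparameters. Everything is deterministic under fixed seeds.

For the comparison experiments shipped in the acceptance script and tests,
hyperparameters are fixed (100 trees, depth 16, sqrt features, leaf 2) and
shared across featurizations instead of searched per allele: at desk scale a
per-allele randomized search adds minutes of compute without changing the
comparison, and holding the learner constant is what isolates the
featurization effect. The search machinery itself is exercised at small
scale in the unit tests.

## Evaluation designs

- **Test-set regression/classification** (`evaluate_models`): per-allele
  |r|, |ρ| (signed values retained alongside), AUROC and AUPRC at a binder
  threshold; aggregate = unweighted mean over alleles where defined.
  Constant or single-class cells are reported missing (NaN), never 0. A
  leakage guard rejects test records whose complex id appears in training.
- **Virtual screening** (`screening_eval`): per-allele and pooled
  AUROC/AUPRC on a binder/decoy benchmark; single-class alleles are skipped
  with a warning. AUPRC is the headline metric under the ~5% binder
  prevalence.
- **Multi-threshold evaluation** (`threshold_eval`) labels one score set at
  50/500/25000 nM; `consistency_ranges` reports the per-peptide min/max/range
  of normalized scores across alternative structures of the same complex
  (smaller = more consistent).
- **Ablation** (`ablation_run`): identical split and seeds across position
  subsets, so reports differ only by which positions the model may see.

Metric conventions: AUROC is the Mann–Whitney probability (ties count half);
AUPRC is step-wise average precision, not trapezoidal interpolation, which
avoids optimistic interpolation between operating points; both are
implemented via scikit-learn and pinned against brute-force oracles in the
tests. Score normalization for cross-scorer comparison is min–max to [0, 1]
with inversion for lower-is-stronger scores (plain x/max is available as an
option); constant score vectors map to 0.5 with a warning.

## Built-in energy backend

The protocol is backend-agnostic — production use imports per-residue tables
from an external all-atom scorer through the TSV adapter, matched to the
19-term schema by column name. The built-in backend exists so the entire
pipeline runs from bare PDB files; it is deliberately simple, fully
specified, and populates 8 of the 19 terms (the rest are identically zero):

- **fa_atr / fa_rep**: 12–6 potential `V(r) = ε[(σ/r)¹² − 2(σ/r)⁶]` over
  inter-residue heavy-atom pairs within 6 Å; σ = sum of element radii
  (C 1.7, N 1.55, O 1.52, S 1.8 Å), ε = 0.1. Split at the minimum: for
  r < σ the excess over −ε is repulsion (capped at 10 per pair) and
  attraction saturates at −ε; outside, attraction is V and repulsion 0.
- **fa_elec**: `332·q_i·q_j/r²` within 5.5 Å (distance-dependent
  dielectric). Charges: backbone N +0.35, backbone O −0.55; the first
  side-chain atom of a residue carries a class charge (ASP/GLU −1, LYS/ARG
  +1, HIS +0.5, else 0). Toy complexes have exactly one side-chain
  pseudo-atom per residue, so the placement is exact there.
- **fa_sol**: burial proxy — each atom counts foreign-residue neighbours
  within 5 Å, +0.05 per neighbour for N/O atoms, −0.02 for C. This is a
  one-body count assigned wholly to the counting atom's residue; the 50/50
  pair split below applies only to the genuinely two-body terms.
- **hbond_(sr_bb | lr_bb | bb_sc | sc)**: −1.0 per donor-N/acceptor-O pair
  at 2.2–3.5 Å, routed by atom class: both backbone + same chain + sequence
  separation ≤ 4 → short-range backbone; both backbone otherwise →
  long-range; mixed → bb_sc; both side-chain → sc.

Every two-body contribution is split 50/50 between its residues, so column
sums equal whole-structure totals exactly, and all terms are functions of
interatomic distances only, so rigid motions change nothing (bounded at
1e−6 in the tests; observed ~1e−12). Parsing keeps ATOM records only
(waters, HETATM, hydrogens dropped; first altloc kept), re-indexes residues
1-based per chain in file order, rejects insertion codes, and auto-detects
the peptide as the chain with fewest residues (overridable). Default schema
weights are 1.0 for every term; imported tables may carry their own weight
configuration. No claim of physical accuracy is made — the backend's job is
residue-resolved, geometry-dependent signal with the bookkeeping of a real
decomposition.

## Synthetic data: what it emulates and what it does not

`gen_feature_dataset` draws 9 × 19 matrices from per-term normal
distributions (means/sds loosely shaped like real per-residue
decompositions) with per-allele mean offsets, and plants the affinity signal
at chosen positions of one term (default: `fa_atr` at anchors 2 and 9). The
default nonlinearity is a **threshold interaction**: with z-scores u, v of
the negated signal entries, `g = clamp(0.5 + 0.35·u·1[v>0] + 0.15·v)` — u
counts only when the partner anchor is favourable. The column sum over nine
positions is a noisy, interaction-blind proxy of (u, v), so aggregation
destroys the signal by construction; `saturating` and `linear` variants and
a single-position preset (signal at position 5, gated by a second term at
the same position, mimicking an HLA-B*08:01-like motif) support the
ablation designs. Targets are `clamp(g + N(0, 0.05²))`; IC50 follows by
inverting the affinity transform.

The screening generator writes matrices that *encode* prescribed targets
(gate opened, signal entry solved for y): binders uniform in scaled affinity
above the 50 nM level, decoys in [0.02, 0.35], alleles round-robin — 100
binders and 2000 decoys by default. The crystal-like generator emulates a
multi-structure evaluation set: one allele, 11 peptides spanning
strong/medium/weak classes with 7 jittered structure copies each plus 5
single-structure non-binders (82 structures, 16 peptides), three peptides
being 10-mers (10 × 19 matrices with a signal-free row inserted at position
6, exercising the reduction downstream). Matrix jitter (0.10 term-sd) stays
below between-class differences, so a faithful scorer shows small
per-peptide ranges.

These generators reproduce the *statistical shape* of the real problem —
position-resolved signal, allele heterogeneity, class imbalance, repeated
structures, mixed lengths — not its physics: real energy terms are
correlated within and across positions, real affinity distributions are not
uniform, and real modeling noise is structure- not feature-level. Passing
tests therefore demonstrate that the protocol recovers position-specific
non-additive signal when it exists and that every pipeline contract holds;
they do not certify accuracy on experimental pHLA data.

Toy structures (`gen_toy_complex`) provide geometry for the backend tests: a
60-residue two-strand groove (ideal 3.8 Å CA spacing), a 9- or 10-residue
peptide with one side-chain pseudo-atom per residue, Gaussian coordinate
jitter. The peptide sequence is fixed per length so zero-jitter complexes
are seed-independent.

## Numerical and design choices

- Correlations on constant input are *missing*, not zero; aggregates skip
  missing cells.
- Reported correlations are absolute values (rank quality, not direction);
  signed values are kept in `MetricReport.signed`.
- Search ties break toward the smaller model (fewer trees, then shallower).
- The test split apportions each class's test quota across affinity strata
  by largest remainder, so a 100-binder/100-non-binder allele yields exactly
  180/20.
- Model files carry the energy-schema fingerprint and position subset;
  scoring refuses features with a mismatched fingerprint, and 10-position
  inputs require explicit opt-in to the reduction (`reduce_long=True`).
- Problem sizes in the shipped experiments (4 alleles × 2000 records for
  the protocol comparison; 2 × 1200 for ablations; 100+2000 screening;
  82-structure crystal set) are desk-scale choices that keep the full suite
  in minutes while leaving all effects far from their decision margins.

## Known limitations

- The built-in backend is a stand-in: absolute energies are meaningless;
  only residue-resolved structure is faithful. Use the TSV adapter for real
  decompositions.
- Per-allele models cannot score alleles absent from training (a pan-allele
  model is out of scope); alleles with < 20 records are skipped.
- Only canonical amino acids, 9–10-mer peptides, and single-model PDB files
  without insertion codes are supported.
- Qualitative (binary-only) affinity data are not handled; IC50 is required
  for training targets and threshold labels.
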