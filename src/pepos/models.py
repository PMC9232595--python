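"""Per-allele affinity regressors and the training protocol.

The learner is a scikit-learn estimator over stacked per-position energy
features. Its ``featurization`` parameter decides what the trees actually
see: the full position-resolved vector (9 positions x T terms, optionally
restricted to a position subset) or the standard aggregated vector (T
per-term totals, obtained by summing position blocks). Both routes share
data, split, folds and hyperparameters, so any performance gap is
attributable to the featurization alone.

Training follows the per-allele protocol: a 90/10 split stratified within
binders and non-binders by scaled affinity, 5-fold affinity-stratified CV,
randomized hyperparameter search scored by mean CV MAE, and a final
bootstrap-aggregated ensemble of CART trees with the MAE split criterion.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

from .featurize import (
    CANONICAL_PEPTIDE_LENGTH,
    FeatureDataset,
    PerPositionFeatureMatrix,
    PositionSubset,
    stack,
)
from .schema import DEFAULT_SCHEMA

logger = logging.getLogger(__name__)

REGRESSOR_KINDS = ("random_forest", "linear", "svr", "pls")


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the binder/non-binder stratified train/test split."""

    test_fraction: float = 0.10
    binder_threshold_nM: float = 500.0
    n_strata: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")


@dataclass(frozen=True)
class SearchSpace:
    """Candidate grid for the randomized hyperparameter search.

    ``features_per_split`` entries are 'sqrt' or a fraction of the feature
    count; ``max_depth`` uses None for unlimited.
    """

    n_trees: tuple = (50, 100, 200, 400)
    features_per_split: tuple = ("sqrt", 0.3, 0.6, 1.0)
    max_depth: tuple = (None, 8, 16, 32)
    min_samples_leaf: tuple = (1, 2, 5, 10)
    n_iterations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "features_per_split", "max_depth", "min_samples_leaf"):
            if not getattr(self, name):
                raise ValueError(f"empty candidate set {name!r}")

    def grid(self) -> list[dict]:
        return [
            {"n_trees": a, "features_per_split": b, "max_depth": c, "min_samples_leaf": d}
            for a, b, c, d in itertools.product(
                self.n_trees, self.features_per_split, self.max_depth,
                self.min_samples_leaf)
        ]


class PositionEnergyRegressor(RegressorMixin, BaseEstimator):
    """Affinity regressor over stacked per-position energy features.

    Input ``X`` is always the stacked per-position layout
    (n_samples, 9 * n_terms); the estimator derives its working view from it
    according to ``featurization``:

    - ``"per_position"``: keep columns of the positions in ``positions``;
    - ``"standard"``: sum the nine position blocks into one total per term.

    Predictions are clamped to [0, 1] (the scaled-affinity range).

    Parameters
    ----------
    featurization : {"per_position", "standard"}
    positions : str
        Named subset ("all", "anchor", "middle") or comma list ("1,2,9");
        only consulted for per-position featurization.
    regressor_kind : {"random_forest", "linear", "svr", "pls"}
        Random forest is the reference learner (CART trees, MAE split
        criterion, bootstrap aggregation); the others are alternatives run
        through the identical pipeline.
    n_trees, features_per_split, max_depth, min_samples_leaf
        Forest hyperparameters (ignored by other kinds).
    n_terms : int
        Terms per position in the stacked layout.
    """

    def __init__(
        self,
        featurization: str = "per_position",
        positions: str = "all",
        regressor_kind: str = "random_forest",
        n_trees: int = 100,
        features_per_split="sqrt",
        max_depth=16,
        min_samples_leaf: int = 2,
        bootstrap: bool = True,
        n_terms: int = DEFAULT_SCHEMA.n_terms,
        random_state: int = 0,
    ):
        self.featurization = featurization
        self.positions = positions
        self.regressor_kind = regressor_kind
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.bootstrap = bootstrap
        self.n_terms = n_terms
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _view(self, X: np.ndarray) -> np.ndarray:
        if self.featurization == "standard":
            return X.reshape(X.shape[0], -1, self.n_terms).sum(axis=1)
        if self.featurization == "per_position":
            subset = PositionSubset.named(self.positions)
            return X[:, subset.column_indices(self.n_terms)]
        raise ValueError(f"unknown featurization {self.featurization!r}")

    def _make_regressor(self):
        if self.regressor_kind == "random_forest":
            mf = self.features_per_split
            return RandomForestRegressor(
                n_estimators=self.n_trees,
                criterion="absolute_error",
                max_features=mf if mf == "sqrt" else float(mf),
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                bootstrap=self.bootstrap,
                random_state=self.random_state,
                n_jobs=1,
            )
        if self.regressor_kind == "linear":
            return LinearRegression()
        if self.regressor_kind == "svr":
            return SVR(kernel="rbf", C=1.0, epsilon=0.05)
        if self.regressor_kind == "pls":
            return PLSRegression(n_components=2)
        raise ValueError(f"unknown regressor_kind {self.regressor_kind!r}")

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if X.shape[1] % self.n_terms:
            raise ValueError(
                f"{X.shape[1]} stacked features is not a multiple of "
                f"n_terms={self.n_terms}"
            )
        V = self._view(X)
        est = self._make_regressor()
        if self.regressor_kind == "pls":
            est.set_params(n_components=min(2, V.shape[1], max(1, X.shape[0] - 1)))
        self.estimator_ = est.fit(V, y)
        self.n_positions_in_ = X.shape[1] // self.n_terms
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        out = np.asarray(self.estimator_.predict(self._view(X)), dtype=float)
        return np.clip(out.ravel(), 0.0, 1.0)


@dataclass
class AlleleModel:
    """A fitted per-allele scorer plus its provenance record."""

    allele: str
    estimator: PositionEnergyRegressor
    schema_fingerprint: str
    hyperparameters: dict = field(default_factory=dict)
    cv_record: list = field(default_factory=list)
    seed: int = 0

    @property
    def position_subset(self) -> PositionSubset:
        return PositionSubset.named(self.estimator.positions)

    def predict(
        self, features, allele: str | None = None, reduce_long: bool = False
    ) -> np.ndarray:
        """Score stacked features, a per-position matrix, or a FeatureDataset.

        A 10-position matrix is rejected unless ``reduce_long`` opts in to
        the documented 10-mer reduction (drop position 6). A mismatched
        allele warns (models generalize poorly across alleles) but still
        scores.
        """
        if allele is not None and allele != self.allele:
            logger.warning("scoring %s features with the %s model", allele, self.allele)
        if isinstance(features, FeatureDataset):
            if features.schema.fingerprint() != self.schema_fingerprint:
                raise ValueError("energy schema fingerprint mismatch")
            X = features.stacked(reduce_long=reduce_long)  # raises on unreduced 10-mers
        elif isinstance(features, PerPositionFeatureMatrix):
            if features.peptide_length != CANONICAL_PEPTIDE_LENGTH:
                raise ValueError(
                    f"{features.peptide_length}-position matrix: apply reduce_10mer "
                    "before scoring"
                )
            X = stack(features)[None, :]
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        return self.estimator.predict(X)


# -- split / folds ------------------------------------------------------------


def _quantile_bins(values: np.ndarray, n_strata: int) -> list[np.ndarray]:
    """Indices grouped into ~equal contiguous bins of sorted `values`.

    Bins that would hold fewer than 2 records are collapsed into their
    neighbour (logged), mirroring how sparse affinity ranges are handled.
    """
    order = np.argsort(values, kind="stable")
    n = order.size
    k = min(n_strata, n)
    edges = np.linspace(0, n, k + 1).astype(int)
    bins = [order[edges[i]:edges[i + 1]] for i in range(k) if edges[i] < edges[i + 1]]
    merged: list[np.ndarray] = []
    for b in bins:
        if merged and b.size < 2:
            logger.info("collapsing stratum of size %d into its neighbour", b.size)
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    return merged


def stratified_split(
    data: FeatureDataset, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureDataset, FeatureDataset]:
    """Per-allele 90/10 split, stratified within binders and non-binders.

    Within each allele, binders (IC50 <= threshold) and non-binders are
    separately cut into affinity quantile strata and ``test_fraction`` is
    drawn from each stratum, so train and test carry equally distributed
    affinities. Records with unknown IC50 stratify as non-binders.
    """
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    for allele in data.unique_alleles():
        a_idx = data.allele_indices(allele)
        if a_idx.size < 20:
            raise ValueError(f"allele {allele}: {a_idx.size} records (< 20)")
        ic50 = data.ic50_nM[a_idx]
        is_binder = np.where(np.isnan(ic50), False, ic50 <= spec.binder_threshold_nM)
        for cls_mask in (is_binder, ~is_binder):
            cls_idx = a_idx[cls_mask]
            if cls_idx.size == 0:
                continue
            n_test_cls = int(round(spec.test_fraction * cls_idx.size))
            bins = _quantile_bins(data.scaled[cls_idx], spec.n_strata)
            # Largest-remainder apportionment of the class test quota.
            quota = np.array([b.size for b in bins]) * n_test_cls / cls_idx.size
            take = np.floor(quota).astype(int)
            rem = np.argsort(-(quota - take), kind="stable")
            for j in rem[: n_test_cls - take.sum()]:
                take[j] += 1
            for b, t in zip(bins, take):
                if t:
                    chosen = rng.choice(b, size=min(t, b.size), replace=False)
                    test_idx.extend(cls_idx[chosen].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(data)) if i not in test_set]
    return data.subset(train_idx), data.subset(sorted(test_idx))


def make_folds(scaled: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Affinity-stratified k-fold assignment.

    Records are ordered by scaled affinity and consecutive blocks of k are
    dealt one-per-fold (random order within each block), so every fold sees
    the full affinity range and fold sizes differ by at most one.
    """
    scaled = np.asarray(scaled, dtype=float)
    n = scaled.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"{n} records for {k} folds")
    rng = np.random.default_rng(seed)
    order = np.argsort(scaled, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        labels = rng.permutation(k)[: block.size]
        folds[block] = labels
    return folds


# -- hyperparameter search -----------------------------------------------------


def _cv_mae(est: PositionEnergyRegressor, X, y, folds) -> list[float]:
    scores = []
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        model = clone(est).fit(X[tr], y[tr])
        scores.append(float(np.mean(np.abs(model.predict(X[va]) - y[va]))))
    return scores


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    space: SearchSpace = SearchSpace(),
    base: PositionEnergyRegressor | None = None,
) -> tuple[dict, list[dict]]:
    """Randomized search over the space, scored by mean cross-validated MAE.

    Draws ``n_iterations`` distinct configurations with the space's seed
    (exhaustive if the grid is smaller). Ties break toward fewer trees, then
    shallower depth. Returns (best hyperparameters, per-configuration record).
    """
    base = base or PositionEnergyRegressor()
    grid = space.grid()
    rng = np.random.default_rng(space.seed)
    if space.n_iterations >= len(grid):
        candidates = grid
    else:
        pick = rng.choice(len(grid), size=space.n_iterations, replace=False)
        candidates = [grid[i] for i in pick]
    record = []
    for hp in candidates:
        est = clone(base).set_params(**hp)
        fold_scores = _cv_mae(est, X, y, folds)
        record.append({**hp, "cv_mae": fold_scores,
                       "mean_mae": float(np.mean(fold_scores))})

    def sort_key(r):
        depth = r["max_depth"]
        return (r["mean_mae"], r["n_trees"], np.inf if depth is None else depth)

    best = min(record, key=sort_key)
    hp = {k: best[k] for k in ("n_trees", "features_per_split", "max_depth",
                               "min_samples_leaf")}
    return hp, record


# -- per-allele training -------------------------------------------------------


def train_allele_model(
    train: FeatureDataset,
    allele: str,
    featurization: str = "per_position",
    positions: str = "all",
    regressor_kind: str = "random_forest",
    hyperparameters: dict | None = None,
    search: SearchSpace | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> AlleleModel:
    """Fit one allele's model; optionally tune on affinity-stratified CV first."""
    alien = [a for a in train.alleles if a != allele]
    if alien:
        raise ValueError(f"records from other alleles present: {sorted(set(alien))[:3]}")
    X = train.stacked()
    y = train.scaled
    base = PositionEnergyRegressor(
        featurization=featurization, positions=positions,
        regressor_kind=regressor_kind, n_terms=train.n_terms, random_state=seed,
    )
    cv_record: list = []
    hp = dict(hyperparameters or {})
    if search is not None:
        folds = make_folds(y, k=cv_folds, seed=seed)
        hp, cv_record = tune_hyperparameters(X, y, folds, space=search, base=base)
    est = clone(base)
    if hp:
        est.set_params(**hp)
    est.fit(X, y)
    return AlleleModel(
        allele=allele,
        estimator=est,
        schema_fingerprint=train.schema.fingerprint(),
        hyperparameters=hp or est.get_params(),
        cv_record=cv_record,
        seed=seed,
    )


def train_all(
    data: FeatureDataset,
    featurization: str = "per_position",
    positions: str = "all",
    regressor_kind: str = "random_forest",
    hyperparameters: dict | None = None,
    search: SearchSpace | None = None,
    min_records: int = 20,
    seed: int = 0,
) -> dict[str, AlleleModel]:
    """One model per allele present; alleles below ``min_records`` are skipped."""
    models: dict[str, AlleleModel] = {}
    for allele in data.unique_alleles():
        idx = data.allele_indices(allele)
        if idx.size < min_records:
            logger.warning("skipping allele %s: %d records < %d",
                           allele, idx.size, min_records)
            continue
        models[allele] = train_allele_model(
            data.subset(idx), allele,
            featurization=featurization, positions=positions,
            regressor_kind=regressor_kind, hyperparameters=hyperparameters,
            search=search, seed=seed,
        )
    return models


def predict(model: AlleleModel, features, allele: str | None = None) -> np.ndarray:
    """Module-level convenience over :meth:`AlleleModel.predict`."""
    return model.predict(features, allele=allele)


# -- persistence --------------------------------------------------------------


def save_models(models: dict[str, AlleleModel], directory: str | Path) -> None:
    """One joblib file per allele plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for allele, m in models.items():
        fname = f"{allele.replace('*', '').replace(':', '')}.joblib"
        joblib.dump(m, directory / fname)
        manifest[allele] = {
            "file": fname,
            "schema_fingerprint": m.schema_fingerprint,
            "positions": m.estimator.positions,
            "featurization": m.estimator.featurization,
            "regressor_kind": m.estimator.regressor_kind,
            "hyperparameters": {k: v for k, v in m.hyperparameters.items()},
            "cv_mean_mae": (min(r["mean_mae"] for r in m.cv_record)
                            if m.cv_record else None),
            "seed": m.seed,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def load_models(directory: str | Path) -> dict[str, AlleleModel]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return {allele: joblib.load(directory / meta["file"])
            for allele, meta in manifest.items()}
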