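import numpy as np
import pytest
from sklearn.base import clone

from pepos import (
    PositionEnergyRegressor,
    SearchSpace,
    SplitSpec,
    gen_feature_dataset,
    make_folds,
    pearson,
    stratified_split,
    train_all,
    train_allele_model,
    tune_hyperparameters,
)
from pepos.featurize import FeatureDataset, PerPositionFeatureMatrix
from pepos.schema import DEFAULT_SCHEMA

FAST_RF = {"n_trees": 20, "max_depth": 8}


def make_dataset(n, seed=0, allele="HLA-A0201", scaled=None):
    """Hand-rolled dataset: target linear in one stacked feature."""
    rng = np.random.default_rng(seed)
    mats = list(rng.normal(size=(n, 9, 19)))
    if scaled is None:
        scaled = np.clip(0.5 + 0.3 * np.array([m[1, 0] for m in mats]), 0, 1)
    ic50 = 50_000.0 ** (1.0 - scaled)
    return FeatureDataset(
        ids=[f"c{i}" for i in range(n)],
        alleles=[allele] * n,
        peptides=["AAAAAAAAA"] * n,
        matrices=mats,
        ic50_nM=ic50,
        scaled=np.asarray(scaled, dtype=float),
    )


class TestStratifiedSplit:
    def test_90_10_split_of_balanced_classes(self):
        # 100 binders + 100 non-binders -> 180 train / 20 test
        scaled = np.concatenate([
            np.linspace(0.45, 0.99, 100),   # ic50 below 500 nM
            np.linspace(0.01, 0.40, 100),   # above
        ])
        data = make_dataset(200, scaled=scaled)
        train, test = stratified_split(data, SplitSpec(seed=1))
        assert (len(train), len(test)) == (180, 20)
        # 10 test records from each class
        assert (test.ic50_nM <= 500).sum() == 10

    def test_partition_and_determinism(self, small_dataset):
        tr1, te1 = stratified_split(small_dataset, SplitSpec(seed=5))
        tr2, te2 = stratified_split(small_dataset, SplitSpec(seed=5))
        assert te1.ids == te2.ids and tr1.ids == tr2.ids
        assert set(tr1.ids) | set(te1.ids) == set(small_dataset.ids)
        assert not set(tr1.ids) & set(te1.ids)

    def test_different_seeds_move_members_not_sizes(self, small_dataset):
        _, te1 = stratified_split(small_dataset, SplitSpec(seed=1))
        _, te2 = stratified_split(small_dataset, SplitSpec(seed=2))
        assert len(te1) == len(te2)
        assert te1.ids != te2.ids

    def test_preconditions(self, small_dataset):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=0.0)
        with pytest.raises(ValueError, match="< 20"):
            stratified_split(make_dataset(10), SplitSpec())

    def test_test_set_spans_the_affinity_range(self, small_dataset):
        _, test = stratified_split(small_dataset, SplitSpec(seed=3))
        # equally distributed affinities: both tails must appear
        assert test.scaled.min() < 0.25 and test.scaled.max() > 0.75


class TestMakeFolds:
    def test_equal_fold_sizes(self):
        folds = make_folds(np.linspace(0, 1, 100), k=5, seed=0)
        assert sorted(np.bincount(folds)) == [20] * 5

    def test_partition_property(self):
        y = np.random.default_rng(0).uniform(size=83)
        folds = make_folds(y, k=5, seed=1)
        assert folds.size == 83
        sizes = np.bincount(folds, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_affinity_stratification(self):
        y = np.random.default_rng(2).uniform(size=200)
        folds = make_folds(y, k=5, seed=2)
        overall = y.mean()
        quartiles = np.quantile(y, [0.25, 0.5, 0.75])
        for f in range(5):
            yf = y[folds == f]
            assert abs(yf.mean() - overall) < 0.1
            counts = np.bincount(np.digitize(yf, quartiles), minlength=4)
            assert counts.max() - counts.min() <= 1

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_folds(np.ones(10), k=1)
        with pytest.raises(ValueError, match="records"):
            make_folds(np.ones(3), k=5)


class TestTuneHyperparameters:
    def test_single_point_space_returns_it(self):
        data = make_dataset(60, seed=3)
        X, y = data.stacked(), data.scaled
        folds = make_folds(y, k=3, seed=0)
        space = SearchSpace(n_trees=(10,), features_per_split=(1.0,),
                            max_depth=(4,), min_samples_leaf=(2,), n_iterations=5)
        hp, record = tune_hyperparameters(X, y, folds, space)
        assert hp == {"n_trees": 10, "features_per_split": 1.0,
                      "max_depth": 4, "min_samples_leaf": 2}
        assert len(record) == 1

    def test_better_configuration_wins_on_noiseless_data(self):
        # Depth-1 stumps cannot fit a linear target as well as deeper trees.
        data = make_dataset(150, seed=4)
        X, y = data.stacked(), data.scaled
        folds = make_folds(y, k=3, seed=0)
        space = SearchSpace(n_trees=(30,), features_per_split=(1.0,),
                            max_depth=(1, 12), min_samples_leaf=(1,),
                            n_iterations=10)
        hp, record = tune_hyperparameters(X, y, folds, space)
        assert hp["max_depth"] == 12
        maes = {r["max_depth"]: r["mean_mae"] for r in record}
        assert maes[12] < maes[1]

    def test_same_seed_same_draw_and_winner(self):
        data = make_dataset(60, seed=5)
        X, y = data.stacked(), data.scaled
        folds = make_folds(y, k=3, seed=0)
        space = SearchSpace(n_trees=(5, 10), features_per_split=(0.3, 1.0),
                            max_depth=(2, 4), min_samples_leaf=(1, 2),
                            n_iterations=4, seed=9)
        hp1, rec1 = tune_hyperparameters(X, y, folds, space)
        hp2, rec2 = tune_hyperparameters(X, y, folds, space)
        assert hp1 == hp2
        assert [r["mean_mae"] for r in rec1] == [r["mean_mae"] for r in rec2]

    def test_tie_breaks_toward_smaller_models(self):
        # Constant target: every configuration scores identically.
        data = make_dataset(40, seed=6, scaled=np.full(40, 0.5))
        X, y = data.stacked(), data.scaled
        folds = make_folds(y, k=2, seed=0)
        space = SearchSpace(n_trees=(50, 10), features_per_split=(1.0,),
                            max_depth=(None, 4), min_samples_leaf=(1,),
                            n_iterations=99)
        hp, _ = tune_hyperparameters(X, y, folds, space)
        assert hp["n_trees"] == 10 and hp["max_depth"] == 4


class TestTrainAlleleModel:
    def test_constant_target_predicts_the_constant(self):
        data = make_dataset(50, seed=7, scaled=np.full(50, 0.42))
        m = train_allele_model(data, "HLA-A0201", hyperparameters=FAST_RF, seed=0)
        np.testing.assert_allclose(m.predict(data), 0.42, atol=1e-9)

    def test_learns_a_noiseless_step_function(self):
        rng = np.random.default_rng(8)
        mats = list(rng.normal(size=(500, 9, 19)))
        scaled = np.array([0.8 if m[1, 0] > 0 else 0.2 for m in mats])
        data = FeatureDataset(
            ids=[f"c{i}" for i in range(500)], alleles=["HLA-A0201"] * 500,
            peptides=["AAAAAAAAA"] * 500, matrices=mats,
            ic50_nM=50_000.0 ** (1 - scaled), scaled=scaled)
        train, test = data.subset(range(400)), data.subset(range(400, 500))
        # full feature bagging so every tree can find the single signal column
        m = train_allele_model(
            train, "HLA-A0201",
            hyperparameters={"n_trees": 50, "features_per_split": 1.0,
                             "max_depth": None, "min_samples_leaf": 1},
            seed=0)
        assert pearson(m.predict(test), test.scaled) >= 0.95

    def test_determinism_under_fixed_seed(self):
        data = make_dataset(80, seed=9)
        m1 = train_allele_model(data, "HLA-A0201", hyperparameters=FAST_RF, seed=3)
        m2 = train_allele_model(data, "HLA-A0201", hyperparameters=FAST_RF, seed=3)
        np.testing.assert_array_equal(m1.predict(data), m2.predict(data))

    def test_rejects_foreign_alleles(self, small_dataset):
        with pytest.raises(ValueError, match="other alleles"):
            train_allele_model(small_dataset, small_dataset.alleles[0],
                               hyperparameters=FAST_RF)

    def test_memorization_with_a_single_unbagged_deep_tree(self):
        data = make_dataset(60, seed=10)
        m = train_allele_model(
            data, "HLA-A0201",
            hyperparameters={"n_trees": 1, "max_depth": None,
                             "min_samples_leaf": 1, "features_per_split": 1.0,
                             "bootstrap": False},
            seed=0)
        np.testing.assert_allclose(m.predict(data), data.scaled, atol=1e-12)


class TestTrainAllAndPredict:
    def test_one_model_per_allele(self):
        data = gen_feature_dataset(n_alleles=4, n_per_allele=30, seed=2)
        models = train_all(data, hyperparameters=FAST_RF, seed=0)
        assert sorted(models) == sorted(data.unique_alleles())
        assert len(models) == 4

    def test_small_alleles_are_skipped_with_warning(self, caplog):
        big = make_dataset(40, seed=11, allele="HLA-A0201")
        tiny = make_dataset(24, seed=12, allele="HLA-B0702").subset(range(5))
        data = FeatureDataset.concatenate([big, tiny])
        with caplog.at_level("WARNING", logger="pepos.models"):
            models = train_all(data, hyperparameters=FAST_RF)
        assert list(models) == ["HLA-A0201"]
        assert "skipping allele HLA-B0702" in caplog.text

    def test_predictions_live_in_unit_interval(self, small_dataset):
        allele = small_dataset.alleles[0]
        sub = small_dataset.subset(small_dataset.allele_indices(allele))
        m = train_allele_model(sub, allele, hyperparameters=FAST_RF)
        wild = np.random.default_rng(0).normal(scale=50, size=(10, 171))
        out = m.predict(wild)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_ten_mer_matrix_requires_reduction(self, small_dataset):
        allele = small_dataset.alleles[0]
        sub = small_dataset.subset(small_dataset.allele_indices(allele))
        m = train_allele_model(sub, allele, hyperparameters=FAST_RF)
        ten = PerPositionFeatureMatrix(np.zeros((10, 19)),
                                       DEFAULT_SCHEMA.fingerprint())
        with pytest.raises(ValueError, match="reduce_10mer"):
            m.predict(ten)

    def test_allele_mismatch_warns_but_scores(self, small_dataset, caplog):
        allele = small_dataset.alleles[0]
        sub = small_dataset.subset(small_dataset.allele_indices(allele))
        m = train_allele_model(sub, allele, hyperparameters=FAST_RF)
        with caplog.at_level("WARNING", logger="pepos.models"):
            out = m.predict(sub, allele="HLA-B9999")
        assert out.size == len(sub)
        assert "HLA-B9999" in caplog.text


class TestEstimatorContract:
    def test_clone_and_params_round_trip(self):
        est = PositionEnergyRegressor(positions="anchor", n_trees=10)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_standard_view_equals_summed_blocks(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 171))
        y = rng.uniform(size=20)
        est = PositionEnergyRegressor(featurization="standard", n_trees=5,
                                      max_depth=3).fit(X, y)
        V = est._view(X)
        np.testing.assert_allclose(V, X.reshape(20, 9, 19).sum(axis=1))

    def test_position_subset_view_selects_columns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 171))
        est = PositionEnergyRegressor(featurization="per_position", positions="middle")
        V = est._view(X)
        assert V.shape == (10, 4 * 19)

    @pytest.mark.parametrize("kind", ["linear", "svr", "pls"])
    def test_alternative_regressors_run_the_same_pipeline(self, kind):
        data = make_dataset(60, seed=13)
        m = train_allele_model(data, "HLA-A0201", regressor_kind=kind, seed=0)
        out = m.predict(data)
        assert out.shape == (60,)
        assert np.all((out >= 0) & (out <= 1))
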