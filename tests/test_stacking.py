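"""Stacking: OOF meta-features, weight extraction, fitness, size sweep."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

import hdestack as h
from hdestack.containers import MORPH, FeatureTable
from hdestack.hde import Param, ParamSpace
from hdestack.stacking import joint_param_space, split_assignment


def _blob_table(seed=0, n_per=20, n_classes=3, n_features=6, sep=2.0,
                centers_seed=12345):
    """Gaussian blobs; class centers are fixed by centers_seed so different
    ``seed`` values give fresh draws from the same population."""
    y = np.repeat(np.arange(n_classes), n_per)
    centers = np.random.default_rng(centers_seed).normal(
        0, sep, (n_classes, n_features)
    )
    x = centers[y] + np.random.default_rng(seed).normal(
        0, 1.0, (y.size, n_features)
    )
    return FeatureTable(x, [f"f{i}" for i in range(n_features)],
                        [MORPH] * n_features, y)


class TestOOFMetaFeatures:
    def test_dimension_arithmetic(self):
        train = _blob_table()
        bases = {"LR": LogisticRegression(max_iter=500),
                 "DT": DecisionTreeClassifier(random_state=0),
                 "KNN": KNeighborsClassifier(3)}
        meta, cols, hard = h.oof_meta_features(bases, train, n_folds=5, seed=0)
        assert meta.shape == (60, 3 * 3)
        assert len(cols) == 9 and cols[0] == "LR:p0"
        assert hard.shape == (3, 60)

    def test_no_leakage_for_memorizing_learner(self):
        """A 1-NN memorizer is perfect in-sample; OOF predictions are not."""
        train = _blob_table(seed=1, sep=0.3)  # heavily overlapping classes
        bases = {"KNN": KNeighborsClassifier(1)}
        _, _, hard = h.oof_meta_features(bases, train, n_folds=5, seed=0)
        oof_acc = np.mean(hard[0] == train.labels)
        insample = KNeighborsClassifier(1).fit(train.values, train.labels)
        assert np.mean(insample.predict(train.values) == train.labels) == 1.0
        assert oof_acc < 0.9

    def test_row_permutation_consistency(self):
        train = _blob_table(seed=2)
        bases = {"LR": LogisticRegression(max_iter=500)}
        meta_a, _, _ = h.oof_meta_features(bases, train, n_folds=5, seed=0)
        meta_b, _, _ = h.oof_meta_features(bases, train, n_folds=5, seed=0)
        assert np.array_equal(meta_a, meta_b)

    def test_single_perfect_learner_separates_meta_space(self):
        train = _blob_table(seed=3, sep=6.0)
        model = h.fit_stack(["LR"], None, train, n_folds=5, seed=0)
        test = _blob_table(seed=4, sep=6.0)
        assert model.evaluate(test)["accuracy"] >= 99.0


class TestExtractWeights:
    def test_zero_coefficient_base_gets_zero_weight(self):
        class Meta:
            coef_ = np.hstack([np.ones((3, 3)), np.zeros((3, 3))])

        w = h.extract_base_weights(Meta(), n_bases=2, n_classes=3)
        assert w[1] == 0.0 and w.sum() == pytest.approx(1.0)

    def test_symmetric_bases_get_equal_weights(self):
        class Meta:
            coef_ = np.hstack([np.full((2, 2), 0.5), np.full((2, 2), 0.5)])

        w = h.extract_base_weights(Meta(), n_bases=2, n_classes=2)
        assert np.allclose(w, 0.5)

    def test_hand_computed_two_base_matrix(self):
        class Meta:
            # base 0 block mean |coef| = 2.0, base 1 block mean = 1.0
            coef_ = np.array([[2.0, -2.0, 1.0, 1.0], [-2.0, 2.0, -1.0, 1.0]])

        w = h.extract_base_weights(Meta(), n_bases=2, n_classes=2)
        assert np.allclose(w, [2 / 3, 1 / 3])

    def test_coefficient_free_meta_gives_uniform(self):
        w = h.extract_base_weights(object(), n_bases=4, n_classes=3)
        assert np.allclose(w, 0.25)


class TestFitStack:
    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            h.fit_stack([], None, _blob_table())

    def test_weights_normalized(self):
        model = h.fit_stack(["LR", "DT", "KNN"], None, _blob_table(), n_folds=3, seed=0)
        assert model.base_weights.sum() == pytest.approx(1.0)
        assert np.all(model.base_weights >= 0)

    def test_prediction_deterministic(self):
        train = _blob_table(seed=5)
        test = _blob_table(seed=6)
        model = h.fit_stack(["LR", "DT"], None, train, n_folds=3, seed=0)
        assert np.array_equal(model.predict(test.values), model.predict(test.values))

    def test_single_base_close_to_raw_model(self):
        """A one-base stack is a calibrated version of that model."""
        diffs = []
        for seed in range(5):
            train = _blob_table(seed=seed, n_per=30, sep=1.5)
            test = _blob_table(seed=100 + seed, n_per=30, sep=1.5)
            stack = h.fit_stack(["LR"], None, train, n_folds=5, seed=0)
            raw = LogisticRegression(max_iter=1000).fit(train.values, train.labels)
            acc_stack = stack.evaluate(test)["accuracy"]
            acc_raw = 100 * np.mean(raw.predict(test.values) == test.labels)
            diffs.append(acc_stack - acc_raw)
        assert abs(np.mean(diffs)) <= 1.0

    def test_stack_not_worse_than_max_base_on_average(self):
        """Top-3 stack vs its strongest member, averaged over 5 seeds."""
        margins = []
        f1_margins = []
        for seed in range(5):
            train = _blob_table(seed=seed, n_per=30, sep=1.0, n_features=8)
            test = _blob_table(seed=200 + seed, n_per=30, sep=1.0, n_features=8)
            model = h.fit_stack(["LR", "DT", "MLP"], None, train, n_folds=5, seed=seed)
            stack_perf = model.evaluate(test)
            base_perf = [
                h.performance_metrics(
                    model.base_models[n].predict(test.values), test.labels
                )
                for n in model.base_names
            ]
            margins.append(stack_perf["accuracy"] - max(p["accuracy"] for p in base_perf))
            f1_margins.append(stack_perf["f1"] - np.mean([p["f1"] for p in base_perf]))
        assert np.mean(margins) >= -2.0
        assert np.mean(f1_margins) >= 0.0  # stack's macro-F1 beats the base mean


class TestCvFitness:
    def _setup(self):
        pool = h.default_candidate_pool(0)
        selection = ["LR", "DT"]
        space, _ = joint_param_space(pool, selection)
        return pool, selection, space

    def test_deterministic_and_bounded(self):
        pool, selection, space = self._setup()
        train = _blob_table(seed=7)
        g = np.full(len(space), 0.5)
        f1 = h.cv_fitness(selection, g, space, train, pool=pool, n_folds=3, seed=0)
        f2 = h.cv_fitness(selection, g, space, train, pool=pool, n_folds=3, seed=0)
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_separable_data_reaches_high_fitness(self):
        pool, selection, space = self._setup()
        train = _blob_table(seed=8, sep=6.0, n_features=2)
        g = np.full(len(space), 0.5)
        assert h.cv_fitness(selection, g, space, train, pool=pool, n_folds=3, seed=0) >= 0.95

    def test_genome_layout_roundtrip(self):
        pool, selection, space = self._setup()
        assignment = space.decode(np.full(len(space), 0.5))
        params = split_assignment(assignment, selection)
        assert set(params) == {"LR", "DT"}
        assert "C" in params["LR"] and "max_depth" in params["DT"]


class TestEnsembleSizeSweep:
    def test_table_shape_and_weak_candidate(self):
        """With one deliberately weak candidate the best K excludes it."""
        def weak(p):
            return DecisionTreeClassifier(max_depth=1, random_state=0)

        pool = h.default_candidate_pool(0)
        pool["WEAK"] = (weak, ParamSpace([Param("d", "integer", (1, 2))]))
        argmax_below_m = 0
        n_seeds = 6
        for seed in range(n_seeds):
            train = _blob_table(seed=seed, n_per=25, sep=1.2)
            test = _blob_table(seed=300 + seed, n_per=25, sep=1.2)
            rep = h.evaluate_candidates(
                train, pool=pool, candidates=["LR", "KNN", "DT", "WEAK"],
                n_folds=3, seed=seed,
            )
            sweep = h.ensemble_size_sweep(rep, train, test, pool=pool,
                                          n_folds=3, seed=seed)
            assert sweep.shape == (4, 4)
            argmax_below_m += sweep["accuracy"].idxmax() < 4
        assert argmax_below_m >= 0.5 * n_seeds

    def test_k1_matches_single_best(self):
        train = _blob_table(seed=11, n_per=25)
        test = _blob_table(seed=12, n_per=25)
        rep = h.evaluate_candidates(train, candidates=["LR", "DT", "KNN"],
                                    n_folds=3, seed=0)
        sweep = h.ensemble_size_sweep(rep, train, test, n_folds=3, seed=0)
        single = h.fit_stack([rep.ranking[0]], None, train, n_folds=3, seed=0)
        assert sweep.loc[1, "accuracy"] == pytest.approx(
            single.evaluate(test)["accuracy"], abs=5.0
        )


def test_hde_improves_stacking_fitness_over_defaults():
    """HDE tuning should match or beat default hyperparameters."""
    pool = h.default_candidate_pool(0)
    selection = ["LR", "DT"]
    space, _ = joint_param_space(pool, selection)
    wins = 0
    n_runs = 10
    for seed in range(n_runs):
        train = _blob_table(seed=seed, n_per=15, sep=0.9, n_features=4)
        objective = lambda g: h.cv_fitness(  # noqa: E731
            selection, g, space, train, pool=pool, n_folds=3, inner_folds=2, seed=seed
        )
        cfg = h.HDEConfig(np_pop=6, g_max=5, seed=seed)
        _, state = h.optimize(objective, space, cfg)
        default_params = {"LR": {}, "DT": {}}
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(train.values, train.labels):
            m = h.fit_stack(selection, default_params, train.take_rows(tr),
                            pool=pool, n_folds=2, seed=seed)
            accs.append(np.mean(m.predict(train.values[te]) == train.labels[te]))
        wins += state.f_best >= np.mean(accs) - 1e-12
    assert wins >= 0.9 * n_runs
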