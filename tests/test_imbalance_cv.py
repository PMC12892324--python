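import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon

from dockvote import imbalance_cv as icv
from dockvote import synthetic_data as sd

TINY_RF_GRID = {"n_estimators": [50], "max_depth": [10]}


def _labels(n_active, n_inactive, seed=0):
    y = np.r_[np.ones(n_active, int), np.zeros(n_inactive, int)]
    return np.random.default_rng(seed).permutation(y)


class TestFoldPlan:
    def test_basic_invariants(self):
        y = _labels(12, 108)
        plan = icv.make_fold_plan(y, outer_k=9, n_subsets=9, seed=0)
        assert sorted(np.unique(plan.outer_assignments)) == list(range(9))
        for fold in range(9):
            train_idx = plan.training_indices(fold)
            actives = set(train_idx[y[train_idx] == 1])
            fold_inactives = set(train_idx[y[train_idx] == 0])
            seen_inactives = []
            for subset in plan.balanced_subsets[fold]:
                subset = np.asarray(subset)
                # every balanced subset contains ALL fold actives
                assert actives <= set(subset)
                seen_inactives.append(set(subset[y[subset] == 0]))
            # disjoint and covering
            union = set().union(*seen_inactives)
            assert union == fold_inactives
            assert sum(len(s) for s in seen_inactives) == len(union)
            sizes = [len(s) for s in seen_inactives]
            assert max(sizes) - min(sizes) <= 1

    def test_18_inactives_9_subsets_of_2(self):
        y = np.r_[np.ones(3, int), np.zeros(18, int)]
        subsets = icv.split_inactive_subsets(y, n_subsets=9, seed=1)
        inactive_sizes = [int((y[s] == 0).sum()) for s in subsets]
        assert inactive_sizes == [2] * 9

    def test_1048_inactives_split(self):
        # 1048 = 9 * 116 + 4: four subsets of 117 and five of 116
        y = np.r_[np.ones(84, int), np.zeros(1048, int)]
        subsets = icv.split_inactive_subsets(y, n_subsets=9, seed=0)
        sizes = sorted((int((y[s] == 0).sum()) for s in subsets), reverse=True)
        assert sizes == [117] * 4 + [116] * 5

    def test_stratification(self):
        y = _labels(84, 1048, seed=3)
        plan = icv.make_fold_plan(y, seed=3)
        global_frac = y.mean()
        for fold in range(9):
            val = plan.validation_indices(fold)
            # per-fold active fraction within one compound of the global fraction
            assert abs(y[val].sum() - global_frac * len(val)) <= 1.0

    def test_too_few_inactives_rejected(self):
        y = np.r_[np.ones(5, int), np.zeros(9, int)]
        with pytest.raises(ValueError, match="inactives"):
            icv.make_fold_plan(y, outer_k=3, n_subsets=9, seed=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            icv.make_fold_plan(np.ones(20, int))

    def test_deterministic(self):
        y = _labels(10, 90)
        p1 = icv.make_fold_plan(y, seed=5)
        p2 = icv.make_fold_plan(y, seed=5)
        np.testing.assert_array_equal(p1.outer_assignments, p2.outer_assignments)
        for f in range(9):
            for a, b in zip(p1.balanced_subsets[f], p2.balanced_subsets[f]):
                np.testing.assert_array_equal(a, b)

    @settings(max_examples=15, deadline=None)
    @given(
        n_active=st.integers(6, 20),
        n_inactive=st.integers(30, 120),
        seed=st.integers(0, 10_000),
    )
    def test_partition_property(self, n_active, n_inactive, seed):
        y = _labels(n_active, n_inactive, seed=seed)
        plan = icv.make_fold_plan(y, outer_k=3, n_subsets=3, seed=seed)
        covered = np.zeros(len(y), int)
        for fold in range(3):
            covered[plan.validation_indices(fold)] += 1
        np.testing.assert_array_equal(covered, 1)  # outer folds partition


class TestHyperGrid:
    def test_grids_as_specified(self):
        assert icv.DEFAULT_GRIDS["RF"] == {
            "n_estimators": [50, 100, 200],
            "max_depth": [None, 10, 20],
        }
        assert icv.DEFAULT_GRIDS["SVM"] == {"C": [0.1, 1, 10], "kernel": ["linear", "rbf"]}
        assert icv.DEFAULT_GRIDS["XGB"] == {
            "n_estimators": [50, 100, 200],
            "max_depth": [3, 5, 7],
        }

    def test_combination_order_simplest_first(self):
        combos = icv.grid_combinations("RF")
        assert combos[0] == {"n_estimators": 50, "max_depth": 10}
        assert combos[-1] == {"n_estimators": 200, "max_depth": None}
        combos = icv.grid_combinations("SVM")
        assert combos[0] == {"C": 0.1, "kernel": "linear"}

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            icv.build_estimator("MLP", {})


class TestTuneHyperparameters:
    def test_single_combination_returned(self):
        y = _labels(10, 10)
        X = np.random.default_rng(0).normal(size=(20, 3)) + y[:, None]
        params = icv.tune_hyperparameters(X, y, "RF", grid=TINY_RF_GRID, seed=0)
        assert params == {"n_estimators": 50, "max_depth": 10}

    def test_separable_data_tiebreaks_to_simplest(self):
        # every combination scores MCC 1.0 -> the simplest wins
        y = _labels(15, 15, seed=1)
        X = np.zeros((30, 2))
        X[:, 0] = y * 10.0  # perfectly separable
        params = icv.tune_hyperparameters(X, y, "RF", seed=0)
        assert params == {"n_estimators": 50, "max_depth": 10}

    def test_degenerate_fold_error(self):
        y = np.r_[np.ones(1, int), np.zeros(30, int)]
        X = np.random.default_rng(0).normal(size=(31, 2))
        with pytest.raises(ValueError, match="degenerate"):
            icv.tune_hyperparameters(X, y, "RF", grid=TINY_RF_GRID, inner_k=5, seed=0)

    def test_parity_signal_prefers_deeper_trees(self):
        """4-bit parity has no low-order structure: depth-3 boosted trees
        cannot fit it, deeper ones can.  Oracle = exhaustive grid scoring."""
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 2, size=(240, 4)).astype(float)
            y = X.sum(axis=1).astype(int) % 2
            params = icv.tune_hyperparameters(
                X, y, "XGB", grid={"n_estimators": [50], "max_depth": [3, 5]}, seed=seed
            )
            if params["max_depth"] > 3:
                wins += 1
        assert wins >= 2


class TestModalParams:
    def test_identical_sets(self):
        sets = [{"n_estimators": 100, "max_depth": 10}] * 9
        assert icv.modal_params(sets, "RF") == {"n_estimators": 100, "max_depth": 10}

    def test_strict_mode(self):
        sets = [{"n_estimators": 100}] * 5 + [{"n_estimators": 200}] * 4
        assert icv.modal_params(sets, "RF") == {"n_estimators": 100}

    def test_tie_resolves_to_shallower_finite_depth(self):
        # 4 x depth 10, 4 x None, 1 x 20: tie between 10 and None -> 10
        sets = (
            [{"max_depth": 10}] * 4 + [{"max_depth": None}] * 4 + [{"max_depth": 20}]
        )
        assert icv.modal_params(sets, "RF") == {"max_depth": 10}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            icv.modal_params([])


class TestRunNestedCV:
    def _small(self, effect_size, seed=0):
        spec = sd.SyntheticSpec(
            n_active=12, n_inactive=48, n_features=5, effect_size=effect_size, seed=seed
        )
        matrix, y = sd.gen_descriptors(spec)
        return matrix.features, y

    def test_no_signal_mcc_near_zero(self):
        X, y = self._small(0.0, seed=1)
        plan = icv.make_fold_plan(y, outer_k=3, n_subsets=3, seed=1)
        report, _ = icv.run_nested_cv(
            X, y, "RF", plan, grid=TINY_RF_GRID, inner_k=3, seed=1
        )
        assert abs(report.mean_mcc) < 0.35

    def test_strong_signal_high_ba(self):
        X, y = self._small(3.0, seed=2)
        plan = icv.make_fold_plan(y, outer_k=3, n_subsets=3, seed=2)
        report, modal = icv.run_nested_cv(
            X, y, "RF", plan, grid=TINY_RF_GRID, inner_k=3, seed=2
        )
        assert report.mean_ba > 0.9
        assert len(modal) == 3 and all("n_estimators" in m for m in modal)

    def test_validation_folds_stay_imbalanced(self):
        X, y = self._small(1.0, seed=3)
        plan = icv.make_fold_plan(y, outer_k=3, n_subsets=3, seed=3)
        global_frac = y.mean()
        for fold in range(3):
            val = plan.validation_indices(fold)
            assert abs(y[val].mean() - global_frac) < 0.1

    def test_default_params_mode(self):
        X, y = self._small(2.0, seed=4)
        plan = icv.make_fold_plan(y, outer_k=3, n_subsets=3, seed=4)
        report, modal = icv.run_nested_cv(
            X, y, "RF", plan, tune=False,
            default_params={"n_estimators": 50, "max_depth": 10}, seed=4,
        )
        assert all(m == {"n_estimators": 50, "max_depth": 10} for m in modal)
        assert len(report.fold_mcc) == 3

    def test_report_aggregates_recomputable(self):
        report = icv.CVReport(fold_mcc=[0.1, 0.2, 0.3], fold_ba=[0.5, 0.6, 0.7])
        assert report.mean_mcc == pytest.approx(0.2)
        assert report.sd_mcc == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))


class TestMajorityVote:
    def test_no_tie_with_nine_voters(self):
        for votes in range(10):
            assert icv.majority_label(votes, 9) == (1 if votes >= 5 else 0)

    def test_boundary(self):
        assert icv.majority_label(4, 9) == 0
        assert icv.majority_label(5, 9) == 1


class TestRetrainFinal:
    def test_nine_members_all_actives_each(self, small_dataset):
        matrix, y, _ = small_dataset
        model = icv.retrain_final(
            matrix.features, y, "RF", {"n_estimators": 50, "max_depth": 10}, seed=0
        )
        assert model.n_members == 9
        subsets = icv.split_inactive_subsets(y, n_subsets=9, seed=0)
        actives = set(np.flatnonzero(y == 1))
        for s in subsets:
            assert actives <= set(s)

    def test_members_agree_on_separable_data(self, small_dataset):
        matrix, y, _ = small_dataset
        model = icv.retrain_final(
            matrix.features, y, "RF", {"n_estimators": 50, "max_depth": 10}, seed=0
        )
        spec = sd.SyntheticSpec(
            n_active=20, n_inactive=80, n_features=10, effect_size=3.0, seed=99
        )
        held, _ = sd.gen_descriptors(spec)
        preds = np.vstack([m.predict(held.features) for m in model.members])
        agree = (preds == preds[0]).all(axis=0).mean()
        assert agree > 0.95

    def test_params_from_grid_required_shape(self, small_dataset):
        matrix, y, _ = small_dataset
        model = icv.retrain_final(
            matrix.features, y, "SVM", {"C": 1, "kernel": "linear"}, n_subsets=3, seed=0
        )
        assert model.n_members == 3
        assert model.algorithm == "SVM"


class TestComparePairedMetrics:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert icv.compare_paired_metrics([0.1] * 9, [0.1] * 9) == 1.0

    def test_shifted_pairs_significant(self):
        a = np.linspace(0.1, 0.9, 9)
        b = a + 1.0
        p = icv.compare_paired_metrics(a, b)
        # exact signed-rank for n=9, all one-sided: p = 2 / 2^9
        assert p == pytest.approx(2 / 512)
        assert p < 0.05

    def test_matches_scipy_directly(self, rng):
        a = rng.normal(size=9)
        b = a + rng.normal(scale=0.5, size=9)
        assert icv.compare_paired_metrics(a, b) == pytest.approx(
            wilcoxon(a, b, alternative="two-sided").pvalue
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            icv.compare_paired_metrics([1, 2], [1, 2, 3])


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, small_dataset):
        matrix, y, _ = small_dataset
        model = icv.retrain_final(
            matrix.features, y, "RF", {"n_estimators": 50, "max_depth": 10},
            n_subsets=3, seed=0,
        )
        icv.save_ensemble(model, tmp_path / "bundle")
        loaded = icv.load_ensemble(tmp_path / "bundle")
        assert loaded.algorithm == model.algorithm
        assert loaded.params == model.params
        assert loaded.training_signature == model.training_signature
        np.testing.assert_array_equal(
            np.vstack([m.predict(matrix.features) for m in loaded.members]),
            np.vstack([m.predict(matrix.features) for m in model.members]),
        )
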