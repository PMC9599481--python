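import itertools

import numpy as np
import pandas as pd
import pytest

from liprom.core import GroupDesign, TableError
from liprom.ann import AnnSpec, GaussianMLP, train_ann
from liprom.classifier import (
    ScreeningResult,
    SplitSpec,
    auc_one_vs_rest,
    evaluate,
    greedy_leading_search,
    run_classification_stage,
    screen_predictors,
    split_train_test,
)


def _design(sizes: dict[str, int]) -> GroupDesign:
    assignment = {}
    for g, n in sizes.items():
        for i in range(n):
            assignment[f"{g}{i:02d}"] = g
    return GroupDesign(pd.Series(assignment))


class TestSplit:
    def test_cohort_102_44(self):
        design = _design({"HC": 36, "HT": 32, "HL": 28, "HG": 29, "NL": 21})
        train, test = split_train_test(design, SplitSpec(seed=0))
        assert len(train) == 102
        assert len(test) == 44
        assert set(train) | set(test) == set(design.assignment.index)
        assert set(train) & set(test) == set()

    def test_largest_remainder_tie_by_group_order(self):
        design = _design({"HC": 5, "NL": 5})
        train, test = split_train_test(design, SplitSpec(train_fraction=0.70))
        assert len(train) == 7
        by_group = pd.Series(
            {s: design.assignment[s] for s in train}
        ).value_counts()
        assert by_group["HC"] == 4  # tie broken in favour of first group
        assert by_group["NL"] == 3

    def test_same_seed_identical(self):
        design = _design({"HC": 10, "NL": 10})
        s = SplitSpec(seed=42)
        assert split_train_test(design, s) == split_train_test(design, s)

    def test_degenerate_fraction_rejected(self):
        design = _design({"HC": 3, "NL": 3})
        with pytest.raises(TableError):
            split_train_test(design, SplitSpec(train_fraction=0.99))

    def test_unstratified_counts(self):
        design = _design({"HC": 10, "NL": 10})
        train, test = split_train_test(
            design, SplitSpec(stratified=False, seed=1)
        )
        assert len(train) == 14 and len(test) == 6


def _signal_data(n_per_class=30, n_noise=10, seed=0):
    rng = np.random.default_rng(seed)
    labels, rows = [], []
    for k, cls in enumerate(["A", "B", "C"]):
        for _ in range(n_per_class):
            informative = rng.normal(loc=3.0 * k, scale=0.5, size=2)
            noise = rng.normal(size=n_noise)
            rows.append(np.concatenate([informative, noise]))
            labels.append(cls)
    cols = ["inf1", "inf2"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(rows, columns=cols), np.array(labels)


class TestScreening:
    def test_planted_informative_in_pool(self):
        X, y = _signal_data()
        res = screen_predictors(X, y, cycles=20, per_cycle_top=3, pool_size=4,
                                seed=0, n_trees=25)
        assert {"inf1", "inf2"} <= set(res.pool)
        assert res.table.loc["inf1", "frequency"] >= 19

    def test_frequencies_bounded_by_cycles(self):
        X, y = _signal_data(n_per_class=10)
        res = screen_predictors(X, y, cycles=5, per_cycle_top=3, pool_size=4,
                                seed=1, n_trees=10)
        assert res.table["frequency"].between(0, 5).all()

    def test_cycles_one_is_single_forest_topk(self):
        X, y = _signal_data(n_per_class=10)
        res = screen_predictors(X, y, cycles=1, per_cycle_top=4, pool_size=4,
                                seed=2, n_trees=10)
        assert (res.table["frequency"] == 1).sum() == 4
        assert set(res.pool) == set(
            res.table.index[res.table["frequency"] == 1]
        )

    def test_pure_noise_near_uniform(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            rng.normal(size=(60, 12)), columns=[f"f{i}" for i in range(12)]
        )
        y = np.array(["A", "B"] * 30)
        res = screen_predictors(X, y, cycles=40, per_cycle_top=6, pool_size=6,
                                seed=3, n_trees=10)
        freq = res.table["frequency"]
        # every feature gets picked sometimes; no feature dominates
        assert freq.max() - freq.min() < 40 * 0.8

    def test_column_order_invariance(self):
        X, y = _signal_data(n_per_class=15, seed=5)
        res1 = screen_predictors(X, y, cycles=10, per_cycle_top=3, pool_size=3,
                                 seed=7, n_trees=20)
        res2 = screen_predictors(
            X[list(reversed(X.columns))], y, cycles=10, per_cycle_top=3,
            pool_size=3, seed=7, n_trees=20,
        )
        assert {"inf1", "inf2"} <= set(res1.pool)
        assert {"inf1", "inf2"} <= set(res2.pool)

    def test_single_class_rejected(self):
        X, _ = _signal_data(n_per_class=5)
        with pytest.raises(TableError):
            screen_predictors(X, np.array(["A"] * len(X)), cycles=2)


class TestGaussianMLP:
    def test_separable_two_class_perfect_training(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(-3, 0.3, size=(20, 2)), rng.normal(3, 0.3, size=(20, 2))]
        )
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        model = GaussianMLP(hidden_nodes=5, restarts=2, seed=0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_seed_reproducibility(self):
        X, y = _signal_data(n_per_class=10)
        arr = X[["inf1", "inf2"]].to_numpy()
        m1 = GaussianMLP(seed=5, restarts=2).fit(arr, y)
        m2 = GaussianMLP(seed=5, restarts=2).fit(arr, y)
        assert np.array_equal(m1._theta, m2._theta)
        assert np.array_equal(m1.predict_proba(arr), m2.predict_proba(arr))

    def test_duplicate_predictor_not_worse(self):
        X, y = _signal_data(n_per_class=15, seed=2)
        arr1 = X[["inf1"]].to_numpy()
        arr2 = X[["inf1", "inf1"]].to_numpy()
        acc1 = (GaussianMLP(seed=0, restarts=3).fit(arr1, y).predict(arr1) == y).mean()
        acc2 = (GaussianMLP(seed=0, restarts=3).fit(arr2, y).predict(arr2) == y).mean()
        assert acc2 >= acc1 - 0.05  # fit tolerance

    def test_gaussian_activation_used(self):
        # hidden activations are exp(-z^2): bounded in (0, 1]
        X, y = _signal_data(n_per_class=8)
        arr = X[["inf1", "inf2"]].to_numpy()
        model = GaussianMLP(seed=1).fit(arr, y)
        Xs = (arr - model._mean) / model._sd
        W1, b1, _, _ = model._unpack(model._theta, 2, 3)
        H = np.exp(-((Xs @ W1 + b1) ** 2))
        assert H.max() <= 1.0 and H.min() > 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            GaussianMLP().fit(np.ones((4, 2)), np.array(["A"] * 4))

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            GaussianMLP().fit(X, np.array(["A", "B"]))


def brute_force_auc(scores, is_pos):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, p in zip(scores, is_pos) if p]
    neg = [s for s, p in zip(scores, is_pos) if not p]
    if not pos or not neg:
        return float("nan")
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return conc / total


class TestEvaluate:
    def test_auc_worked_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        is_pos = np.array([True, True, False, False])
        assert auc_one_vs_rest(scores, is_pos) == pytest.approx(0.75)

    def test_auc_matches_pair_counting(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
            is_pos = rng.random(n) < 0.4
            if is_pos.all() or not is_pos.any():
                continue
            assert auc_one_vs_rest(scores, is_pos) == pytest.approx(
                brute_force_auc(scores, is_pos), abs=1e-12
            )

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(8)
        aucs = [
            auc_one_vs_rest(rng.random(200), rng.random(200) < 0.5)
            for _ in range(50)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_perfect_classifier(self):
        X, y = _signal_data(n_per_class=20, seed=9)
        arr = X[["inf1", "inf2"]].to_numpy()
        model = GaussianMLP(seed=0, restarts=2).fit(arr, y)
        ev = evaluate(model, arr, y)
        if ev.overall_accuracy == 1.0:
            assert all(a == pytest.approx(1.0) for a in ev.per_class_auc.values())
        assert int(np.trace(ev.confusion_matrix.to_numpy())) == int(
            ev.overall_accuracy * len(y)
        )

    def test_confusion_row_sums_are_class_counts(self):
        X, y = _signal_data(n_per_class=12, seed=10)
        arr = X[["inf1", "noise0"]].to_numpy()
        model = GaussianMLP(seed=0).fit(arr, y)
        ev = evaluate(model, arr, y)
        row_sums = ev.confusion_matrix.sum(axis=1)
        for cls in np.unique(y):
            assert row_sums[cls] == (y == cls).sum()

    def test_absent_class_auc_nan(self):
        X, y = _signal_data(n_per_class=10, seed=11)
        arr = X[["inf1", "inf2"]].to_numpy()
        model = GaussianMLP(seed=0).fit(arr, y)
        ev = evaluate(model, arr[y != "C"], y[y != "C"])
        assert np.isnan(ev.per_class_auc["C"])


@pytest.fixture(scope="module")
def data():
    return _signal_data(n_per_class=20, n_noise=2, seed=12)


class TestGreedySearch:

    def test_pool_of_one(self, data):
        X, y = data
        trace = greedy_leading_search(
            ["inf1"], X, y, selection_mode="cv", cv_folds=3, restarts=1,
            max_iter=100, seed=0,
        )
        assert trace.best_predictors == ["inf1"]
        assert len(trace.runs) == 1

    def test_traces_monotone(self, data):
        X, y = data
        trace = greedy_leading_search(
            ["inf1", "inf2", "noise0", "noise1"], X, y,
            selection_mode="cv", cv_folds=3, restarts=1, max_iter=100, seed=0,
        )
        for run in trace.runs:
            accs = [s["accuracy"] for s in run["steps"]]
            assert all(b > a for a, b in zip(accs, accs[1:]))

    def test_best_at_least_single_predictor(self, data):
        X, y = data
        pool = ["inf1", "inf2", "noise0", "noise1"]
        trace = greedy_leading_search(
            pool, X, y, selection_mode="cv", cv_folds=3, restarts=1,
            max_iter=100, seed=0,
        )
        singles = [run["steps"][0]["accuracy"] for run in trace.runs]
        assert trace.best_accuracy >= max(singles)

    def test_exhaustive_oracle_tiny_pool(self, data):
        X, y = data
        pool = ["inf1", "inf2", "noise0", "noise1"]
        trace = greedy_leading_search(
            pool, X, y, selection_mode="cv", cv_folds=3, restarts=1,
            max_iter=100, seed=0,
        )
        from liprom.classifier import _cv_accuracy
        from liprom.ann import AnnSpec

        all_accs = []
        for k in range(1, 5):
            for subset in itertools.combinations(pool, k):
                spec = AnnSpec(predictors=subset, restarts=1, max_iter=100, seed=0)
                all_accs.append(
                    _cv_accuracy(X, y, list(subset), spec, 3, 0)
                )
        assert trace.best_accuracy >= np.median(all_accs)

    def test_paper_mode_requires_test_set(self, data):
        X, y = data
        with pytest.raises(TableError, match="test set"):
            greedy_leading_search(["inf1"], X, y, selection_mode="paper")

    def test_empty_pool_rejected(self, data):
        X, y = data
        with pytest.raises(TableError, match="empty"):
            greedy_leading_search([], X, y)


class TestStage:
    def test_end_to_end_on_separable_cohort(self, demo_imputed):
        _, table, design, _ = demo_imputed
        report = run_classification_stage(
            table, design, cycles=10, pool_size=4, restarts=1, max_iter=120,
            cv_folds=3, n_trees=20, seed=3,
        )
        assert report.train_eval.overall_accuracy > 0.4
        assert len(report.trace.best_predictors) >= 1
        assert set(report.train_ids) & set(report.test_ids) == set()
        curve = report.trace.accuracy_curve()
        assert (curve["n_predictors"] >= 1).all()

    def test_deterministic_rerun(self, demo_imputed):
        _, table, design, _ = demo_imputed
        kwargs = dict(cycles=5, pool_size=3, restarts=1, max_iter=80,
                      cv_folds=3, n_trees=10, seed=4)
        r1 = run_classification_stage(table, design, **kwargs)
        r2 = run_classification_stage(table, design, **kwargs)
        assert r1.trace.best_predictors == r2.trace.best_predictors
        assert r1.test_eval.overall_accuracy == r2.test_eval.overall_accuracy

    def test_missing_values_rejected(self, demo_cohort):
        _, table, design, _ = demo_cohort
        if not table.values.isna().any().any():
            pytest.skip("demo cohort has no missing cells")
        with pytest.raises(TableError, match="imputed"):
            run_classification_stage(table, design, cycles=1)
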