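"""Cross-validation harness, OneR, discretization and CFS selection."""

import numpy as np
import pandas as pd
import pytest

from rrespstate.ml_harness import (
    CFSProblem,
    OneRClassifier,
    cfs_select,
    confusion,
    default_algorithms,
    majority_baseline,
    mdlp_cut_points,
    run_cv,
    symmetrical_uncertainty,
)

LABELS = ("Relax-RResp", "Basal-RResp", "Stress-RResp")


def threshold_table(n=150, n_noise=3, seed=0):
    """Label is a thresholding of feature x0, with a margin between classes
    so any train split places a separating cut correctly."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    x0 = y + rng.uniform(0.1, 0.9, n)  # class k occupies (k+0.1, k+0.9)
    table = pd.DataFrame({"x0": x0})
    for j in range(n_noise):
        table[f"noise{j}"] = rng.standard_normal(n)
    table["label"] = np.asarray(LABELS)[y]
    return table


class TestOneR:
    def test_learns_single_feature_rule(self):
        table = threshold_table()
        model = OneRClassifier().fit(
            table[["x0", "noise0"]].to_numpy(), table["label"].to_numpy()
        )
        assert model.feature_ == 0
        pred = model.predict(table[["x0", "noise0"]].to_numpy())
        assert np.mean(pred == table["label"].to_numpy()) > 0.95

    def test_constant_feature_majority_fallback(self):
        X = np.zeros((20, 1))
        y = np.array(["a"] * 14 + ["b"] * 6)
        model = OneRClassifier().fit(X, y)
        assert (model.predict(X) == "a").all()


class TestRunCV:
    def test_separable_table_perfect_tree(self):
        table = threshold_table()
        algs = {"DT": default_algorithms(0)["DT"]}
        (res,) = run_cv(table, algs, runs=2, folds=5, seed=1)
        assert res.accuracy.size == 10
        np.testing.assert_allclose(res.accuracy, 1.0)
        np.testing.assert_allclose(res.f1, 1.0)
        np.testing.assert_allclose(res.auc, 1.0)

    def test_permuted_labels_hit_chance(self):
        """Destroying the labels drives accuracy to the 1/3 chance level."""
        rng = np.random.default_rng(2)
        table = threshold_table(n=300)
        table["label"] = rng.permutation(table["label"].to_numpy())
        algs = {k: v for k, v in default_algorithms(0).items() if k in ("DT", "NB")}
        results = run_cv(table, algs, runs=2, folds=5, seed=3)
        for res in results:
            assert res.mean_accuracy == pytest.approx(1 / 3, abs=0.08)

    def test_same_seed_reproduces_metrics(self):
        table = threshold_table(n=90)
        algs = {"RF": default_algorithms(5)["RF"]}
        (a,) = run_cv(table, algs, runs=2, folds=3, seed=9)
        (b,) = run_cv(table, algs, runs=2, folds=3, seed=9)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        np.testing.assert_array_equal(a.auc, b.auc)

    def test_paired_design_shares_partitions(self):
        """Identical per-run class totals across algorithms prove the fold
        composition is shared."""
        table = threshold_table(n=90)
        algs = {k: v for k, v in default_algorithms(0).items() if k in ("DT", "NB")}
        res = run_cv(table, algs, runs=2, folds=3, seed=4)
        for run in range(2):
            np.testing.assert_array_equal(
                res[0].confusions[run].sum(axis=1),
                res[1].confusions[run].sum(axis=1),
            )

    def test_class_smaller_than_folds_rejected(self):
        table = threshold_table(n=30)
        table.loc[table["label"] == LABELS[2], "label"] = LABELS[1]
        table.loc[table.index[:2], "label"] = LABELS[2]
        with pytest.raises(ValueError, match="instances per class"):
            run_cv(table, runs=1, folds=5, seed=0)


class TestConfusion:
    def test_perfect_classifier_is_diagonal(self):
        table = threshold_table()
        (res,) = run_cv(
            table, {"DT": default_algorithms(0)["DT"]}, runs=2, folds=5, seed=1
        )
        cm = confusion(res)
        off_diag = cm.to_numpy() - np.diag(np.diag(cm.to_numpy()))
        assert np.all(off_diag == 0)

    def test_entries_sum_to_instance_count(self):
        table = threshold_table(n=120)
        (res,) = run_cv(
            table, {"NB": default_algorithms(0)["NB"]}, runs=3, folds=4, seed=2
        )
        assert confusion(res).to_numpy().sum() == pytest.approx(len(table))

    def test_majority_baseline(self):
        table = threshold_table(n=120)
        top = table["label"].value_counts(normalize=True).iloc[0]
        assert majority_baseline(table) == pytest.approx(top)


class TestDiscretization:
    def test_informative_feature_gets_cuts(self):
        table = threshold_table(n=200)
        y = pd.factorize(table["label"])[0]
        cuts = mdlp_cut_points(table["x0"].to_numpy(), y, 3)
        assert 1 <= len(cuts) <= 4
        assert any(abs(c - 1.0) < 0.15 for c in cuts)
        assert any(abs(c - 2.0) < 0.15 for c in cuts)

    def test_noise_feature_gets_none(self):
        table = threshold_table(n=200)
        y = pd.factorize(table["label"])[0]
        assert mdlp_cut_points(table["noise0"].to_numpy(), y, 3) == []

    def test_symmetrical_uncertainty_bounds(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 500)
        assert symmetrical_uncertainty(a, a) == pytest.approx(1.0)
        b = rng.integers(0, 3, 500)
        assert symmetrical_uncertainty(a, b) < 0.05
        assert symmetrical_uncertainty(a, np.zeros_like(a)) == 0.0


class TestCFS:
    def test_perfect_feature_selected_alone(self):
        rng = np.random.default_rng(1)
        n = 150
        y = rng.integers(0, 3, n)
        table = pd.DataFrame(
            {
                "perfect": y + 0.01 * rng.standard_normal(n),
                "noise0": rng.standard_normal(n),
                "noise1": rng.standard_normal(n),
                "label": np.asarray(LABELS)[y],
            }
        )
        assert cfs_select(table) == ["perfect"]

    def test_redundant_copy_not_selected_twice(self):
        """Two identical informative features: the redundancy penalty keeps
        exactly one, matching exhaustive merit maximization."""
        rng = np.random.default_rng(2)
        n = 200
        y = rng.integers(0, 3, n)
        informative = y + 0.05 * rng.standard_normal(n)
        table = pd.DataFrame(
            {
                "info_a": informative,
                "info_b": informative.copy(),
                "noise0": rng.standard_normal(n),
                "label": np.asarray(LABELS)[y],
            }
        )
        problem = CFSProblem.from_table(table)
        selected = cfs_select(table, problem=problem)
        assert len(selected) == 1 and selected[0] in ("info_a", "info_b")
        # exhaustive check over all 7 non-empty subsets
        from itertools import chain, combinations

        subsets = chain.from_iterable(
            combinations(range(3), k) for k in (1, 2, 3)
        )
        best = max(subsets, key=problem.merit)
        assert problem.merit(best) == pytest.approx(
            problem.merit([problem.feature_names.index(selected[0])])
        )

    def test_best_subset_beats_singletons(self):
        table = threshold_table(n=200)
        problem = CFSProblem.from_table(table)
        selected = cfs_select(table, problem=problem)
        idx = [problem.feature_names.index(f) for f in selected]
        best_single = max(problem.merit([j]) for j in range(4))
        assert problem.merit(idx) >= best_single - 1e-12
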