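import numpy as np
import pandas as pd
import pytest

from idrw.activity import PathwayActivityMatrix
from idrw.evaluate import (
    CVPlan,
    cross_validate,
    fit_predict_logistic,
    metrics,
    rank_pathways,
    select_top_k,
    subsample_sensitivity,
    _stratified_subsample,
)
from idrw.types import GOOD, POOR, SampleLabels

from conftest import make_labels


def activity_from_array(arr, samples, ids=None):
    ids = ids or [f"PW{i:03d}" for i in range(len(arr))]
    values = pd.DataFrame(np.asarray(arr, dtype=float), index=ids, columns=samples)
    membership = pd.DataFrame(
        {"n_total": 1, "n_exp_sig": 1, "n_cna_sig": 0}, index=values.index
    )
    return PathwayActivityMatrix(values, membership)


class TestRankPathways:
    def test_planted_pathway_ranks_first(self):
        labels = make_labels(10, 10)
        rng = np.random.default_rng(0)
        signal = np.where(labels.poor_mask(labels.samples), 1.0, -1.0)
        arr = rng.normal(size=(5, 20)) * 0.5
        arr[3] = signal + rng.normal(size=20) * 0.05
        ranked = rank_pathways(activity_from_array(arr, labels.samples), labels)
        assert ranked.index[0] == "PW003"
        assert ranked["p_value"].is_monotonic_increasing

    def test_label_permutation_destroys_planted_ranking(self):
        labels = make_labels(10, 10)
        rng = np.random.default_rng(1)
        signal = np.where(labels.poor_mask(labels.samples), 1.0, -1.0)
        arr = rng.normal(size=(10, 20)) * 0.5
        arr[3] = signal + rng.normal(size=20) * 0.05
        act = activity_from_array(arr, labels.samples)
        top_hits = 0
        for _ in range(20):
            perm = rng.permutation(20)
            perm_labels = SampleLabels(
                pd.Series(
                    np.asarray(labels.labels)[perm], index=labels.samples, name="group"
                )
            )
            ranked = rank_pathways(act, perm_labels)
            top_hits += ranked.index[0] == "PW003"
        assert top_hits < 10  # planted pathway no longer reliably first

    def test_tie_break_is_deterministic(self):
        labels = make_labels(5, 5)
        arr = np.tile(np.linspace(-1, 1, 10), (4, 1))  # identical rows, all tied
        act = activity_from_array(arr, labels.samples)
        r1 = rank_pathways(act, labels)
        r2 = rank_pathways(act, labels)
        assert list(r1.index) == list(r2.index) == sorted(r1.index)

    def test_excluded_pathways_never_ranked(self):
        labels = make_labels(5, 5)
        act = activity_from_array(np.random.default_rng(0).normal(size=(3, 10)), labels.samples)
        act = PathwayActivityMatrix(act.values, act.membership, frozenset({"PW001"}))
        ranked = rank_pathways(act, labels)
        assert "PW001" not in ranked.index


class TestSelectTopK:
    def test_first_k_of_ranking(self):
        ranked = pd.DataFrame(index=[f"PW{i}" for i in range(8)])
        assert select_top_k(ranked, 3) == ["PW0", "PW1", "PW2"]
        assert select_top_k(ranked, 8) == list(ranked.index)

    def test_oversized_k_clamps(self):
        ranked = pd.DataFrame(index=["PW0", "PW1"])
        assert select_top_k(ranked, 50) == ["PW0", "PW1"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(pd.DataFrame(index=["PW0"]), 0)


class TestLogistic:
    def test_separable_training_is_perfect(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = np.array([False, False, False, True, True, True])
        pred, prob, _ = fit_predict_logistic(X, y, X)
        assert (pred == y).all()

    def test_midpoint_probability_half(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([False, False, True, True])
        _, prob, _ = fit_predict_logistic(X, y, np.array([[0.0]]))
        assert prob[0] == pytest.approx(0.5, abs=1e-3)

    def test_coefficients_match_reference_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = rng.uniform(size=40) < 1 / (1 + np.exp(-logits))
        _, _, model = fit_predict_logistic(X, y, X)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        ref = sm.Logit(y, sm.add_constant((X - mu) / sd)).fit(disp=False)
        assert np.allclose(model.intercept_[0], ref.params[0], atol=1e-4)
        assert np.allclose(model.coef_[0], ref.params[1:], atol=1e-4)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([True, False, True])
        assert metrics(y, y) == (1.0, 1.0, 1.0, 1.0)

    def test_confusion_matrix_hand_example(self):
        # TP=3, FP=1, FN=1, TN=5
        truth = np.array([True] * 4 + [False] * 6)
        pred = np.array([True, True, True, False, True] + [False] * 5)
        acc, prec, rec, f1 = metrics(pred, truth)
        assert (acc, prec, rec, f1) == (0.8, 0.75, 0.75, 0.75)

    def test_all_negative_predictions_zero_recall(self):
        truth = np.array([True, True, False])
        pred = np.zeros(3, bool)
        acc, prec, rec, f1 = metrics(pred, truth)
        assert prec == rec == f1 == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(np.array([], bool), np.array([], bool))

    def test_agrees_with_brute_force_counts(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = rng.integers(1, 30)
            pred = rng.uniform(size=n) < 0.5
            truth = rng.uniform(size=n) < 0.5
            acc, prec, rec, f1 = metrics(pred, truth)
            tp = sum(p and t for p, t in zip(pred, truth))
            fp = sum(p and not t for p, t in zip(pred, truth))
            fn = sum(not p and t for p, t in zip(pred, truth))
            assert acc == (pred == truth).mean()
            assert prec == (tp / (tp + fp) if tp + fp else 0.0)
            assert rec == (tp / (tp + fn) if tp + fn else 0.0)
            pr = prec + rec
            assert f1 == (2 * prec * rec / pr if pr else 0.0)
            assert all(0 <= m <= 1 for m in (acc, prec, rec, f1))


class TestCVPlan:
    def test_repeated_kfold_counts(self):
        labels = make_labels(25, 25)
        plan = CVPlan(scheme="repeated_kfold", n_folds=5, repeats=50, seed=0)
        splits = list(plan.splits(labels, labels.samples))
        assert len(splits) == 250

    def test_folds_partition_and_stratify(self):
        labels = make_labels(30, 20)
        plan = CVPlan(n_folds=5, repeats=1, seed=3)
        for _, _, train, test in plan.splits(labels, labels.samples):
            assert sorted(train + test) == sorted(labels.samples)
            assert not set(train) & set(test)
            poor = labels.poor_mask(test)
            assert 2 <= poor.sum() <= 6  # 20 POOR over 5 folds -> 4 each +-2

    def test_loocv_counts(self):
        labels = make_labels(4, 4)
        plan = CVPlan(scheme="loocv")
        splits = list(plan.splits(labels, labels.samples))
        assert len(splits) == 8
        assert all(len(test) == 1 for _, _, _, test in splits)


class TestCrossValidate:
    def test_planted_cohort_high_accuracy(self, mini_cohort):
        expr, cna, labels, pathways, edges, truth = mini_cohort
        report = cross_validate(
            expr, labels, pathways, edges=edges, cna=cna, method="idrw",
            plan=CVPlan(repeats=2, seed=0), k_grid=(2,),
        )
        assert report.n_evaluations == 10
        assert report.summary().loc[2, "mean_accuracy"] >= 0.9

    def test_report_reproducible_for_fixed_seed(self, mini_cohort):
        expr, cna, labels, pathways, edges, _ = mini_cohort
        kwargs = dict(
            edges=edges, cna=cna, method="idrw",
            plan=CVPlan(repeats=1, seed=5), k_grid=(2,),
        )
        r1 = cross_validate(expr, labels, pathways, **kwargs)
        r2 = cross_validate(expr, labels, pathways, **kwargs)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_no_leakage_from_test_samples(self, mini_cohort):
        """Replacing held-out sample values with noise must leave per-fold
        training (ranking and fitted predictions on training data) unchanged."""
        from idrw.types import LayerKind, OmicsMatrix

        expr, cna, labels, pathways, edges, _ = mini_cohort
        plan = CVPlan(repeats=1, seed=9)
        rep, fold, train_s, test_s = next(iter(plan.splits(labels, expr.samples)))
        rng = np.random.default_rng(0)

        def run(e_matrix):
            sub_tr = e_matrix.subset_samples(train_s)
            from idrw.evaluate import _ActivityModel, _build_graph

            graph = _build_graph(edges, e_matrix, cna)
            model = _ActivityModel("idrw", pathways, graph, 0.7, 1e-10, "welch")
            act = model.fit(
                [sub_tr, cna.subset_samples(train_s)], labels.subset(train_s)
            )
            ranked = rank_pathways(act, labels.subset(train_s))
            return list(ranked.index), act.values.to_numpy()

        noisy_vals = expr.values.copy()
        noisy_vals.loc[:, test_s] = rng.normal(size=(len(expr.genes), len(test_s)))
        # rebuild with the same memory layout as the original so that float
        # reductions are bit-identical and any difference signals real leakage
        noisy = OmicsMatrix(
            LayerKind.MICROARRAY,
            pd.DataFrame(
                np.ascontiguousarray(noisy_vals.to_numpy()),
                index=noisy_vals.index,
                columns=noisy_vals.columns,
            ),
        )
        rank_a, act_a = run(expr)
        rank_b, act_b = run(noisy)
        assert rank_a == rank_b
        assert (act_a == act_b).all()

    def test_paper_mode_runs_and_reports_all_folds(self, mini_cohort):
        expr, cna, labels, pathways, edges, _ = mini_cohort
        report = cross_validate(
            expr, labels, pathways, edges=edges, cna=cna, method="idrw",
            plan=CVPlan(repeats=1, seed=0), k_grid=(2, 4), paper_mode=True,
        )
        assert report.n_evaluations == 5
        assert set(report.records["k"]) == {2, 4}

    @pytest.mark.parametrize("method", ["plage", "zscore"])
    def test_baseline_methods_run_without_graph(self, method, mini_cohort):
        expr, _, labels, pathways, _, _ = mini_cohort
        report = cross_validate(
            expr, labels, pathways, method=method,
            plan=CVPlan(repeats=1, seed=0), k_grid=(2,),
        )
        assert report.n_evaluations == 5
        assert ((report.records["accuracy"] >= 0) & (report.records["accuracy"] <= 1)).all()


class TestSubsample:
    def test_seventy_percent_of_1648_is_1153(self):
        labels = make_labels(908, 740)  # good/poor split of a 1648-sample cohort
        rng = np.random.default_rng(0)
        chosen = _stratified_subsample(labels, labels.samples, 0.7, rng)
        assert len(chosen) == 1153
        assert len(set(chosen)) == 1153

    def test_subsample_preserves_class_balance(self):
        labels = make_labels(100, 60)
        rng = np.random.default_rng(1)
        chosen = _stratified_subsample(labels, labels.samples, 0.8, rng)
        poor = labels.poor_mask(chosen)
        assert poor.sum() == 48 and (~poor).sum() == 80

    def test_fraction_one_uses_all_samples(self, mini_cohort):
        expr, cna, labels, pathways, edges, _ = mini_cohort
        plan = CVPlan(repeats=1, seed=2)
        full = cross_validate(
            expr, labels, pathways, edges=edges, cna=cna, plan=plan, k_grid=(2,)
        )
        sens = subsample_sensitivity(
            expr, labels, pathways, cna=cna, fractions=(1.0,), seed=2,
            min_per_class=5, edges=edges, plan=plan, k_grid=(2,),
        )
        pd.testing.assert_frame_equal(sens[1.0].records, full.records)

    def test_too_small_subsample_rejected(self, mini_cohort):
        expr, cna, labels, pathways, edges, _ = mini_cohort
        with pytest.raises(ValueError, match="fewer than"):
            subsample_sensitivity(
                expr, labels, pathways, cna=cna, fractions=(0.7,), seed=0,
                min_per_class=100, edges=edges, plan=CVPlan(repeats=1), k_grid=(2,),
            )
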