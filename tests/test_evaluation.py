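"""Metrics, ROC/AUC, Hanley–McNeil, cross-validation, comparison harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aednns as A
from aednns.evaluation import f_measure
from aednns.risk_model import _labels_from_table


def _auc_pair_oracle(scores, y):
    """Brute-force Mann–Whitney pair counting, ties worth one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_computed_counts(self):
        y_true = [1] * 4 + [0] * 6
        y_pred = [1, 1, 1, 0] + [1, 0, 0, 0, 0, 0]  # tp=3 fn=1 fp=1 tn=5
        m = A.confusion_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.f_measure == pytest.approx(0.75)

    def test_perfect_prediction(self):
        m = A.confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (m.accuracy, m.precision, m.recall, m.specificity, m.f_measure) == (
            1, 1, 1, 1, 1
        )

    def test_zero_denominator_is_flagged_null(self):
        m = A.confusion_metrics([0, 0, 1], [0, 0, 0])  # no positive predictions
        assert m.precision is None
        assert "precision" in m.undefined
        assert m.recall == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 60), st.integers(0, 10**6))
    def test_matches_brute_force_recount(self, n, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        m = A.confusion_metrics(y_true, y_pred)
        c = m.counts
        assert c.tp == sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        assert c.n == n
        assert m.accuracy == pytest.approx((c.tp + c.tn) / n)


class TestFMeasureConsistency:
    @pytest.mark.parametrize(
        "precision, recall, printed",
        [(0.9137, 0.8290, 0.8691), (0.8150, 0.8881, 0.8499)],
    )
    def test_harmonic_mean_matches_printed_value(self, precision, recall, printed):
        # published precision/recall are rounded to 4 decimals
        assert f_measure(precision, recall) == pytest.approx(printed, abs=0.0005)


class TestROCAUC:
    def test_perfect_separation(self):
        auc, fpr, tpr = A.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _, _ = A.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_hand_counted_pairs(self):
        auc, _, _ = A.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            A.roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        _, fpr, tpr = A.roc_auc(scores, y)
        assert (np.diff(fpr) >= 0).all()
        assert (np.diff(tpr) >= 0).all()

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 201))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.normal(size=n), 2)  # induces ties
            auc, _, _ = A.roc_auc(scores, y)
            assert auc == pytest.approx(_auc_pair_oracle(scores, y), abs=1e-12)


class TestHanleyMcNeil:
    def test_null_auc(self):
        rep = A.hanley_mcneil(0.5, 30, 30)
        assert rep.z == 0.0
        assert rep.p_value == 1.0

    def test_hand_evaluated_example(self):
        rep = A.hanley_mcneil(0.8, 50, 50)
        assert rep.se == pytest.approx(0.044502, abs=1e-5)
        assert rep.z == pytest.approx(6.741, abs=0.005)

    def test_se_shrinks_with_n(self):
        ses = [A.hanley_mcneil(0.8, n, n).se for n in (20, 80, 320)]
        assert ses[0] > ses[1] > ses[2]

    def test_matches_closed_form_on_grid(self):
        for a in np.linspace(0.05, 0.95, 10):
            for n_pos, n_neg in [(5, 7), (40, 60), (200, 100)]:
                rep = A.hanley_mcneil(a, n_pos, n_neg)
                q1 = a / (2 - a)
                q2 = 2 * a * a / (1 + a)
                se = np.sqrt(
                    (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
                    / (n_pos * n_neg)
                )
                assert rep.se == pytest.approx(se, abs=1e-10)
                assert rep.z == pytest.approx((a - 0.5) / se, abs=1e-10)
                assert rep.p_value == pytest.approx(2 * stats.norm.sf(abs(rep.z)), abs=1e-12)
                assert rep.ci95[0] == pytest.approx(max(0, a - 1.96 * se), abs=1e-10)

    def test_degenerate_auc_one(self):
        rep = A.hanley_mcneil(1.0, 10, 10)
        assert rep.se == 0.0
        assert rep.p_value == 0.0


class _ConstantTrainer:
    """Always predicts the majority class of its training labels."""

    def fit(self, train, seed=0):
        y = _labels_from_table(train)
        majority = int(y.mean() >= 0.5)

        class Model:
            def predict_proba(self, rows):
                return np.full(len(rows), 0.5 + 0.001 * (2 * majority - 1))

            def predict_label(self, rows):
                return np.full(len(rows), majority, dtype=int)

        return Model()


class TestCrossValidate:
    def test_constant_classifier_scores_majority_fraction(self, small_cohort):
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 5, y, seed=2)
        report = A.cross_validate(_ConstantTrainer(), small_cohort, folds, seed=2)
        majority_frac = max(y.mean(), 1 - y.mean())
        assert report.mean_metric("accuracy") == pytest.approx(majority_frac, abs=0.02)

    def test_fold_metrics_match_saved_predictions(self, small_cohort):
        # bookkeeping oracle: recompute each fold's metrics from the
        # per-fold prediction records
        trainer = A.SklearnTrainer("DT")
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 4, y, seed=5)
        report = A.cross_validate(trainer, small_cohort, folds, seed=5)
        for f in range(4):
            sub = report.predictions[report.predictions["fold"] == f]
            m = A.confusion_metrics(sub["y_true"], sub["y_pred"])
            assert m.accuracy == report.fold_metrics[f].accuracy
            auc = _auc_pair_oracle(sub["score"].to_numpy(), sub["y_true"].to_numpy())
            assert report.fold_auc[f].auc == pytest.approx(auc, abs=1e-12)

    def test_mean_roc_endpoints_and_monotonicity(self, small_cohort):
        trainer = A.SklearnTrainer("NB")
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 3, y, seed=1)
        report = A.cross_validate(trainer, small_cohort, folds, seed=1)
        grid, mean_tpr = report.mean_roc
        assert mean_tpr[0] == 0.0 and mean_tpr[-1] == 1.0
        assert (np.diff(grid) >= 0).all()

    def test_dnn_trainer_beats_chance_on_synthetic_cohort(self, small_cohort):
        trainer = A.SingleDNNTrainer(A.DNNSpec(epochs=60))
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 3, y, seed=4)
        report = A.cross_validate(trainer, small_cohort, folds, seed=4)
        assert all(r.auc > 0.5 for r in report.fold_auc)


class TestRunComparison:
    def test_single_method_single_row(self, small_cohort):
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 3, y, seed=0)
        table = A.run_comparison(small_cohort, folds, ["DT"], seed=0)
        assert list(table.index) == ["DT"]

    def test_table_columns_follow_report_layout(self, small_cohort):
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 3, y, seed=0)
        table = A.run_comparison(small_cohort, folds, ["NB", "RF"], seed=0)
        assert list(table.columns) == [
            "accuracy", "precision", "recall", "specificity", "f_measure",
            "auc", "p_value", "ci_low", "ci_high",
        ]
        assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()

    def test_knn_grid_search_config(self, small_cohort):
        sub = small_cohort.sample(300, random_state=0).reset_index(drop=True)
        y = _labels_from_table(sub)
        table = A.run_comparison(
            sub,
            A.make_folds(300, 2, y, seed=0),
            ["KNN"],
            configs={"KNN": {"param_grid": {"n_neighbors": [3, 9, 19]}}},
            seed=0,
        )
        assert table.loc["KNN", "accuracy"] > 0.5

    def test_pca_variant_is_backend_swap_only(self):
        trainer = A.make_trainer("PCA-DNNs")
        assert isinstance(trainer, A.AEDNNTrainer)
        assert trainer.backend_kind == "pca"
        assert trainer.use_re_feature  # everything but the backend unchanged
        assert A.make_trainer("AE-DNNs").backend_kind == "autoencoder"

    def test_unknown_method_rejected(self, small_cohort):
        y = _labels_from_table(small_cohort)
        folds = A.make_folds(len(small_cohort), 2, y, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            A.run_comparison(small_cohort, folds, ["XGB"], seed=0)


class TestAblation:
    def test_ladder_order_and_entries(self, small_cohort):
        result = A.ablation_auc(
            small_cohort.sample(300, random_state=1).reset_index(drop=True),
            2,
            [0],
            A.AutoencoderSpec(epochs=15),
            A.DNNSpec(epochs=15),
        )
        assert result["order"] == ["single_dnn", "routed_dnns", "routed_dnns_re"]
        assert set(result["mean_auc"]) == set(result["order"])
        for v in result["mean_auc"].values():
            assert 0.0 <= v <= 1.0
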