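"""Leave-one-session-out evaluation, imbalance handling, interpretability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

from comfortfuse import evaluate as ev
from comfortfuse.features import FeatureSchema
from comfortfuse.pipeline import process_bundle, build_feature_matrix
from comfortfuse.streams import COMFORTABLE, UNCOMFORTABLE
from comfortfuse.synth import (
    SynthConfig,
    generate_cohort,
    sound_driven_config,
    strongly_separated_config,
)

SCHEMA = FeatureSchema.default()


def _matrix_from(config):
    return build_feature_matrix(
        [process_bundle(b) for b, _ in generate_cohort(config)]
    )


class TestFolds:
    def test_cohort_of_18_with_8_single_class_yields_10_valid_folds(self, cohort_matrix):
        folds = ev.loso_folds(cohort_matrix)
        assert len(folds) == 18
        assert sum(f.valid for f in folds) == 10

    def test_skipped_sessions_still_train_every_other_fold(self, cohort_matrix):
        folds = ev.loso_folds(cohort_matrix)
        skipped = [f.test_session for f in folds if not f.valid]
        assert skipped
        for f in folds:
            for s in skipped:
                if s != f.test_session:
                    assert s in f.train_sessions

    def test_all_mixed_cohort_has_all_folds_valid(self):
        matrix = _matrix_from(SynthConfig(
            n_sessions=4, session_duration_s=720.0,
            single_class_fraction=0.0, seed=17,
        ))
        folds = ev.loso_folds(matrix)
        assert all(f.valid for f in folds)


class TestFitEval:
    def test_strong_separation_yields_high_f1_every_fold(self):
        """With ≥3 SD state effects every unambiguous window separates;
        windows straddling a lap transition carry mixed-state signal, so
        they are excluded via the transition buffer."""
        from comfortfuse.pipeline import SessionOptions

        config = strongly_separated_config(
            n_sessions=6, session_duration_s=900.0,
            single_class_fraction=0.0, seed=29,
        )
        opts = SessionOptions(transition_buffer_s=30.0)
        matrix = build_feature_matrix(
            [process_bundle(b, opts) for b, _ in generate_cohort(config)]
        )
        results, _ = ev.run_loso(matrix, ("random_forest",), smote=True, seed=5)
        for fr in results["random_forest"]:
            assert fr.metrics["f1_macro"] > 0.9, fr.held_out_session

    def test_shuffled_labels_give_chance_level_f1(self, cohort_matrix):
        """Permutation null: breaking the label-feature link within each
        session drives mean F1 macro to chance."""
        rng = np.random.default_rng(99)
        shuffled = cohort_matrix.copy()
        shuffled["label"] = (
            shuffled.groupby("session_id")["label"]
            .transform(lambda s: rng.permutation(s.to_numpy()))
        )
        results, _ = ev.run_loso(shuffled, ("random_forest",), smote=True, seed=5)
        mean_f1 = np.mean([fr.metrics["f1_macro"] for fr in results["random_forest"]])
        assert abs(mean_f1 - 0.5) < 0.15

    def test_smote_never_touches_test_rows(self, cohort_matrix):
        folds = [f for f in ev.loso_folds(cohort_matrix) if f.valid]
        with_s = ev.fit_eval_fold(cohort_matrix, folds[0], "random_forest",
                                  smote=True, seed=3)
        without = ev.fit_eval_fold(cohort_matrix, folds[0], "random_forest",
                                   smote=False, seed=3)
        assert with_s.n_test == without.n_test
        np.testing.assert_array_equal(with_s.y_true, without.y_true)

    def test_fold_evaluation_is_deterministic(self, cohort_matrix):
        folds = [f for f in ev.loso_folds(cohort_matrix) if f.valid]
        a = ev.fit_eval_fold(cohort_matrix, folds[1], "xgboost", smote=True, seed=11)
        b = ev.fit_eval_fold(cohort_matrix, folds[1], "xgboost", smote=True, seed=11)
        assert a.metrics == b.metrics

    def test_all_four_model_specs_fit(self, cohort_matrix):
        folds = [f for f in ev.loso_folds(cohort_matrix) if f.valid]
        for spec in ev.MODEL_SPECS:
            fr = ev.fit_eval_fold(cohort_matrix, folds[0], spec, smote=True, seed=1)
            for v in fr.metrics.values():
                assert np.isnan(v) or 0.0 <= v <= 1.0


def _fake_result(y_true, y_pred, session="s", spec="random_forest"):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ev.FoldResult(
        held_out_session=session, train_sessions=["t"], model_spec=spec,
        n_test=len(y_true),
        class_counts={COMFORTABLE: int((y_true == 0).sum()),
                      UNCOMFORTABLE: int((y_true == 1).sum())},
        metrics={m: 0.5 for m in ev.METRIC_NAMES},
        y_true=y_true, y_pred=y_pred, scores=y_pred.astype(float),
    )


class TestSummarise:
    def test_single_fold_reports_zero_sd(self):
        fr = _fake_result([0, 1], [0, 1])
        fr.metrics["f1_macro"] = 0.7
        table = ev.summarise({"random_forest": [fr]})
        assert table.loc[0, "f1_macro_mean"] == 0.7
        assert table.loc[0, "f1_macro_sd"] == 0.0

    def test_two_folds_average(self):
        a = _fake_result([0, 1], [0, 1]); a.metrics["f1_macro"] = 0.4
        b = _fake_result([0, 1], [0, 1]); b.metrics["f1_macro"] = 0.6
        table = ev.summarise({"random_forest": [a, b]})
        assert table.loc[0, "f1_macro_mean"] == pytest.approx(0.5)

    def test_one_row_per_model(self, cohort_matrix):
        results, _ = ev.run_loso(cohort_matrix, ev.MODEL_SPECS, seed=2)
        table = ev.summarise(results)
        assert sorted(table["model"]) == sorted(ev.MODEL_SPECS)


class TestCombinedConfusion:
    def test_pooled_counts_and_accuracy_arithmetic(self):
        """118 uncomfortable test windows of which 47 are caught, 116
        comfortable with 97 predicted uncomfortable overall: pooled
        accuracy works out to 48.3%."""
        tp, fn = 47, 71
        fp = 97 - tp
        tn = 116 - fp
        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        cm = ev.combined_confusion([_fake_result(y_true, y_pred)])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (47, 50, 71, 66)
        assert cm.total == 234
        assert cm.accuracy == pytest.approx(0.483, abs=0.0005)

    def test_sum_equals_total_test_windows(self, cohort_matrix):
        results, _ = ev.run_loso(cohort_matrix, ("random_forest",), seed=4)
        frs = results["random_forest"]
        cm = ev.combined_confusion(frs)
        assert cm.total == sum(fr.n_test for fr in frs)

    def test_matrix_metrics_match_stored_predictions(self, cohort_matrix):
        results, _ = ev.run_loso(cohort_matrix, ("random_forest",), seed=4)
        frs = results["random_forest"]
        cm = ev.combined_confusion(frs)
        y_true = np.concatenate([fr.y_true for fr in frs])
        y_pred = np.concatenate([fr.y_pred for fr in frs])
        assert cm.accuracy == pytest.approx(float(np.mean(y_true == y_pred)))
        recall_pos = cm.tp / (cm.tp + cm.fn)
        assert recall_pos == pytest.approx(
            np.sum((y_true == 1) & (y_pred == 1)) / np.sum(y_true == 1)
        )


class TestLeakage:
    def test_audit_passes_on_clean_run(self, cohort_matrix):
        results, _ = ev.run_loso(cohort_matrix, ("naive_bayes",), seed=6)
        ev.audit_no_leakage(results)

    def test_audit_catches_contamination(self):
        fr = _fake_result([0, 1], [0, 1], session="s")
        fr.train_sessions = ["s", "t"]
        with pytest.raises(ev.FoldError, match="leakage"):
            ev.audit_no_leakage({"random_forest": [fr]})


@pytest.fixture(scope="module")
def sound_importance():
    matrix = _matrix_from(sound_driven_config(
        n_sessions=8, session_duration_s=900.0,
        single_class_fraction=0.25, seed=41,
    ))
    model, _ = ev.fit_full_model(matrix, "random_forest", seed=8)
    return ev.shap_layer_importance(model, matrix, n_permutations=24, seed=8)


class TestLayerImportance:
    def test_planted_acoustic_driver_ranks_first_by_layer(self, sound_importance):
        assert sound_importance.per_layer.index[0] == "acoustic"

    def test_planted_driver_features_in_top_three(self, sound_importance):
        top3 = sound_importance.ranking[:3]
        assert any(f.startswith("sound_") for f in top3)

    def test_layer_value_is_mean_of_member_features(self, sound_importance):
        per_feature = sound_importance.per_feature
        for layer, value in sound_importance.per_layer.items():
            members = [n for n in SCHEMA.names if SCHEMA.report_layer_of(n) == layer]
            assert value == pytest.approx(per_feature[members].mean(), rel=1e-12)

    def test_non_tree_model_is_rejected(self, cohort_matrix):
        model, _ = ev.fit_full_model(cohort_matrix, "naive_bayes", seed=0)
        with pytest.raises(TypeError, match="random_forest"):
            ev.shap_layer_importance(model, cohort_matrix)
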