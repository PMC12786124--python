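"""Metrics, LOSOCV integrity, grid search and ablation plumbing."""

import numpy as np
import pytest

from eegfuse.evaluation import (GridPoint, VARIABLE_COLUMNS, compute_metrics,
                                grid_search, losocv, pooled_auc,
                                subject_differences, verify_no_leakage)
from eegfuse.features import fit_demographic_stats
from eegfuse.models import ModelConfig
from eegfuse.preprocess import EMOTIONS


def metrics_oracle(y_true, y_pred):
    """Hand-rolled per-class precision/recall/F1 by direct counting."""
    out = {}
    for c in range(3):
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1)
    return out


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[y]
        m = compute_metrics(y, y, scores)
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["macro_auc"] == 1.0
        np.testing.assert_array_equal(np.diag(m["confusion"]), 2)

    def test_hand_enumerated_example(self):
        # tp/fp/fn by hand: class0 (1,1,1), class1 (1,0,1), class2 (2,1,0)
        y_pred = np.array([0, 0, 1, 2, 2, 2])
        y_true = np.array([0, 1, 1, 2, 2, 0])
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(4 / 6)
        f1s = [m["per_class_f1"][e] for e in EMOTIONS]
        np.testing.assert_allclose(f1s, [0.5, 2 / 3, 0.8])
        assert m["macro_f1"] == pytest.approx((0.5 + 2 / 3 + 0.8) / 3, abs=1e-4)

    def test_constant_predictor_on_balanced_truths(self):
        y_true = np.repeat([0, 1, 2], 10)
        y_pred = np.ones(30, dtype=int)
        assert compute_metrics(y_true, y_pred)["accuracy"] == pytest.approx(1 / 3)

    def test_confusion_row_sums_are_class_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        m = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(m["confusion"].sum(axis=1),
                                      np.bincount(y_true, minlength=3))

    def test_agrees_with_hand_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y_true = rng.integers(0, 3, 40)
            y_pred = rng.integers(0, 3, 40)
            m = compute_metrics(y_true, y_pred)
            oracle = metrics_oracle(y_true, y_pred)
            for c, emo in enumerate(EMOTIONS):
                prec, rec, f1 = oracle[c]
                assert m["per_class_precision"][emo] == pytest.approx(prec,
                                                                      abs=1e-10)
                assert m["per_class_recall"][emo] == pytest.approx(rec, abs=1e-10)
                assert m["per_class_f1"][emo] == pytest.approx(f1, abs=1e-10)


@pytest.fixture(scope="module")
def cheap_config():
    return ModelConfig.for_architecture("gnn", epochs=2)


class TestLOSOCV:
    def test_fold_per_subject_and_disjointness(self, small_dataset, cheap_config):
        results = losocv(small_dataset, cheap_config, approach="baseline", seed=0)
        assert len(results) == 6
        tested = [f.test_subject_id for f in results]
        assert sorted(tested) == sorted(small_dataset.subjects)
        for f in results:
            assert set(f.train_subjects) & {f.test_subject_id} == set()
        verify_no_leakage(small_dataset, results, view="win")

    def test_two_subject_minimal_case(self, small_dataset, cheap_config):
        import copy
        ds = copy.copy(small_dataset)
        keep = np.isin(ds.win_subjects, ["CHI01", "FRE01"])
        ds.X_win, ds.y_win = ds.X_win[keep], ds.y_win[keep]
        ds.win_subjects = ds.win_subjects[keep]
        ds.win_sessions = ds.win_sessions[keep]
        ds.win_trials = ds.win_trials[keep]
        ds.win_indices = ds.win_indices[keep]
        ds.demographics = ds.demographics[
            ds.demographics["subject_id"].isin(["CHI01", "FRE01"])]
        results = losocv(ds, cheap_config, approach="baseline", seed=0)
        assert [f.test_subject_id for f in results] == ["CHI01", "FRE01"]

    def test_extended_demo_stats_from_training_folds_only(self, small_dataset):
        config = ModelConfig.for_architecture("gnn_transformer", epochs=1,
                                              sequence_length=3)
        results = losocv(small_dataset, config, approach="extended", seed=0)
        verify_no_leakage(small_dataset, results, view="seq")
        table = small_dataset.demographics
        for f in results:
            train_table = table[table["subject_id"].isin(f.train_subjects)]
            expect = fit_demographic_stats(train_table)
            np.testing.assert_allclose(f.demo_stats[0], expect.mean, atol=1e-12)
            np.testing.assert_allclose(f.demo_stats[1], expect.sd, atol=1e-12)

    def test_traces_captured_on_test_fold(self, small_dataset):
        config = ModelConfig.for_architecture("gnn_transformer", epochs=1,
                                              sequence_length=3)
        results = losocv(small_dataset, config, approach="extended", seed=0)
        for f in results:
            assert f.trace is not None
            assert set(f.trace.subject_ids) == {f.test_subject_id}

    def test_subject_differences_alignment(self, small_dataset, cheap_config):
        config = ModelConfig.for_architecture("gnn_transformer", epochs=1,
                                              sequence_length=3)
        base = losocv(small_dataset, config, approach="baseline", seed=0)
        ext = losocv(small_dataset, config, approach="extended", seed=0)
        diffs = subject_differences(ext, base, small_dataset.demographics)
        assert len(diffs) == 6
        assert diffs["overall"].between(-1, 1).all()
        assert {"negative", "neutral", "positive", "age_group"} <= set(diffs.columns)


class TestGridSearch:
    def test_single_point_returned(self, small_dataset):
        best, table = grid_search(small_dataset, "gnn", learning_rates=(1e-2,),
                                  weight_decays=(0.0,), epochs=1)
        assert isinstance(best, GridPoint)
        assert (best.learning_rate, best.weight_decay) == (1e-2, 0.0)
        assert len(table) == 1

    def test_default_grid_is_4x5(self, small_dataset):
        best, table = grid_search(small_dataset, "gnn", epochs=1)
        assert len(table) == 20
        assert best.score == table["score"].max()

    def test_argmax_consistent_with_table(self, small_dataset):
        best, table = grid_search(small_dataset, "gnn",
                                  learning_rates=(1e-3, 1e-2),
                                  weight_decays=(0.0, 1e-2), epochs=2)
        assert best.score == pytest.approx(table["score"].max())
        # deterministic tie-break: first (lowest lr, then wd) among maxima
        top = table[table["score"] == table["score"].max()]
        top = top.sort_values(["learning_rate", "weight_decay"]).iloc[0]
        assert best.learning_rate == top["learning_rate"]
        assert best.weight_decay == top["weight_decay"]


class TestAblation:
    def test_variable_column_widths(self):
        assert len(VARIABLE_COLUMNS["age"]) == 1
        assert len(VARIABLE_COLUMNS["sex"]) == 1
        assert len(VARIABLE_COLUMNS["nationality"]) == 2

    def test_rows_and_demo_widths(self, small_dataset):
        from eegfuse.evaluation import ablate_demographics
        config = ModelConfig.for_architecture("gnn_transformer", epochs=1,
                                              sequence_length=3)
        table = ablate_demographics(small_dataset, config=config, seed=0)
        assert list(table.index) == ["all", "-age", "-sex", "-nationality"]
        assert table.loc["all", "demo_width"] == 4
        assert table.loc["-age", "demo_width"] == 3
        assert table.loc["-nationality", "demo_width"] == 2
        for col in ["auc_negative", "auc_neutral", "auc_positive", "auc_overall"]:
            assert table[col].between(0, 1).all()

    def test_unknown_variable_rejected(self, small_dataset):
        from eegfuse.evaluation import ablate_demographics
        with pytest.raises(ValueError, match="height"):
            ablate_demographics(small_dataset, variables=("height",))


def test_pooled_auc_perfect_scores(small_dataset, cheap_config):
    results = losocv(small_dataset, cheap_config, approach="baseline", seed=0)
    # overwrite with oracle scores: pooled AUC must be exactly 1
    for f in results:
        f.scores = np.eye(3)[f.y_true]
    auc = pooled_auc(results)
    for v in auc.values():
        assert v == pytest.approx(1.0)


def test_trial_level_majority_vote(small_dataset, cheap_config):
    from eegfuse.evaluation import trial_level_results
    config = ModelConfig.for_architecture("gnn_transformer", epochs=1,
                                          sequence_length=3)
    results = losocv(small_dataset, config, approach="baseline", seed=0)
    table = trial_level_results(results, small_dataset)
    # one sequence per trial here: granularities coincide
    n_trials = len(np.unique(small_dataset.sample_uids("seq")))
    assert len(table) == n_trials
    assert (table["n_sequences"] == 1).all()
    seq_acc = np.concatenate([f.y_true == f.y_pred for f in results]).mean()
    assert table.attrs["accuracy"] == pytest.approx(seq_acc)


def test_majority_vote_tie_breaks_to_smallest_class():
    from eegfuse.evaluation import trial_level_results
    import copy
    # synthetic two-sequence trial with a 1-1 tie between classes 2 and 0
    class F: pass
    fold = F()
    fold.test_subject_id = "s"
    fold.y_true = np.array([1, 1])
    fold.y_pred = np.array([2, 0])
    ds = copy.copy
    import pandas as pd
    from eegfuse.pipeline import FeatureDataset
    dataset = FeatureDataset(
        X_seq=np.zeros((2, 1, 62, 5), np.float32), y_seq=np.array([1, 1]),
        seq_subjects=np.array(["s", "s"]), seq_sessions=np.array([1, 1]),
        seq_trials=np.array([7, 7]),
        X_win=np.zeros((1, 62, 5), np.float32), y_win=np.zeros(1, int),
        win_subjects=np.array(["s"]), win_sessions=np.array([1]),
        win_trials=np.array([7]), win_indices=np.array([0]),
        demographics=pd.DataFrame({"subject_id": ["s"], "age": [20],
                                   "sex": ["M"], "nationality": ["Chinese"]}),
        sequence_length=1)
    table = trial_level_results([fold], dataset)
    assert len(table) == 1
    assert table.loc[0, "y_pred"] == 0
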