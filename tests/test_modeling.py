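"""Grid enumeration, metric formulas, constrained selection, CV, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from xoscreen.dataset import stratified_split
from xoscreen.fingerprints import FingerprintScheme
from xoscreen.modeling import (
    FingerprintClassifierModel,
    FingerprintClassifierResults,
    GridConfig,
    HyperparameterPoint,
    REDUCED_GRID,
    auc_midrank,
    confusion_metrics,
    cross_validate,
    enumerate_grid,
)
from xoscreen.synthetic import SyntheticConfig, generate_library


def pairwise_auc_oracle(y, scores):
    """Concordant active/inactive pairs (ties half) over all pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestGrid:
    def test_default_grid_has_11340_points(self):
        assert len(enumerate_grid(GridConfig())) == 7 * 9 * 3 * 3 * 5 * 4

    def test_single_value_axes_give_one_point(self):
        grid = GridConfig(n_estimators=(50,), max_depth=(4,), learning_rate=(0.1,),
                          colsample_bytree=(0.7,), reg_lambda=(1,), min_child_weight=(9,))
        assert len(enumerate_grid(grid)) == 1

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty grid axis"):
            GridConfig(learning_rate=())

    def test_deterministic_order(self):
        assert enumerate_grid(REDUCED_GRID) == enumerate_grid(REDUCED_GRID)

    @pytest.mark.parametrize("kwargs", [
        {"n_estimators": 3}, {"n_estimators": 300}, {"max_depth": 1},
        {"max_depth": 12}, {"learning_rate": 0.5}, {"colsample_bytree": 1.0},
        {"reg_lambda": 5}, {"min_child_weight": 2},
    ])
    def test_out_of_range_hyperparameters_rejected(self, kwargs):
        base = dict(n_estimators=50, max_depth=4, learning_rate=0.1,
                    colsample_bytree=0.7, reg_lambda=0.1, min_child_weight=9)
        base.update(kwargs)
        with pytest.raises(ValueError):
            HyperparameterPoint(**base)


class TestMetrics:
    def test_worked_confusion_table(self):
        # TP=3, FP=1, TN=4, FN=2
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05])
        report = confusion_metrics(y, p)
        assert (report.tp, report.fp, report.tn, report.fn) == (3, 1, 4, 2)
        assert report.accuracy == pytest.approx(0.7)
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.6)
        assert report.f1 == pytest.approx(6 / 9)

    def test_printed_orientation_swaps_denominators(self):
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05])
        swapped = confusion_metrics(y, p, printed_orientation=True)
        assert swapped.precision == pytest.approx(0.6)   # TP/(TP+FN)
        assert swapped.recall == pytest.approx(0.75)     # TP/(TP+FP)

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        report = confusion_metrics(y, p)
        assert report.accuracy == report.f1 == report.auc == 1.0

    def test_equal_probabilities_give_auc_half(self):
        y = np.array([1, 0, 1, 0])
        assert auc_midrank(y, np.full(4, 0.3)) == pytest.approx(0.5)

    def test_single_class_auc_absent_other_metrics_present(self):
        report = confusion_metrics(np.ones(5), np.linspace(0, 1, 5))
        assert report.auc is None and report.accuracy is not None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))

    @given(st.integers(0, 2**31 - 1), st.integers(10, 200))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_random_tables_match_direct_confusion_and_f1_identity(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties included
        report = confusion_metrics(y, p)
        pred = (p >= 0.5).astype(int)
        assert report.tp == int(((pred == 1) & (y == 1)).sum())
        assert report.n == n
        assert report.accuracy == pytest.approx(float((pred == y).mean()))
        if report.precision and report.recall:
            assert report.f1 == pytest.approx(
                2 * report.precision * report.recall
                / (report.precision + report.recall)
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_auc_matches_pairwise_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        p = rng.choice(np.linspace(0, 1, 7), size=n)
        ours = auc_midrank(y, p)
        assert ours == pytest.approx(pairwise_auc_oracle(y, p), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestConstrainedTraining:
    def test_selected_point_respects_spread_constraint(self, noise0_models):
        for results in noise0_models:
            selected = [e for e in results.selection_log
                        if e["disposition"] == "selected"]
            assert len(selected) == 1
            assert selected[0]["spread"] <= 0.05
            assert HyperparameterPoint(**selected[0]["params"]) == results.params

    def test_every_discarded_point_violates_constraint(self, noise0_models):
        for results in noise0_models:
            for entry in results.selection_log:
                if entry["disposition"] == "discarded":
                    assert entry["spread"] > 0.05
                else:
                    assert entry["spread"] <= 0.05

    def test_selection_log_covers_whole_grid(self, noise0_models):
        assert all(len(r.selection_log) == len(enumerate_grid(REDUCED_GRID))
                   for r in noise0_models)

    def test_refit_same_inputs_same_selection(self, noise0_library, noise0_split):
        scheme = FingerprintScheme("MACCS", 167)
        fit = lambda: FingerprintClassifierModel(
            noise0_library, noise0_split, scheme).fit(grid=REDUCED_GRID, seed=3)
        a, b = fit(), fit()
        assert a.params == b.params
        assert a.selection_log == b.selection_log

    def test_impossible_constraint_raises(self, noise0_library, noise0_split):
        model = FingerprintClassifierModel(
            noise0_library, noise0_split, FingerprintScheme("ECFP4", 1024))
        with pytest.raises(RuntimeError, match="constraint"):
            model.fit(grid=REDUCED_GRID, seed=3, max_accuracy_spread=-0.01)

    def test_single_class_training_rejected(self, noise0_split):
        actives_only = generate_library(
            SyntheticConfig(n_molecules=40, active_fraction=0.45, seed=2))
        for m in actives_only:
            m.label = "active"
        split = type(noise0_split)(
            train_ids=[m.id for m in actives_only[:30]],
            validation_ids=[m.id for m in actives_only[30:35]],
            test_ids=[m.id for m in actives_only[35:]], seed=0)
        with pytest.raises(ValueError, match="single class"):
            FingerprintClassifierModel(actives_only, split,
                                       FingerprintScheme("MACCS", 167))

    def test_serialization_round_trip_preserves_predictions(
            self, noise0_models, noise0_library, tmp_path):
        results = noise0_models[0]
        probe = noise0_library[:40]
        results.save(tmp_path / "model")
        restored = FingerprintClassifierResults.load(tmp_path / "model")
        np.testing.assert_array_equal(results.predict_proba(probe),
                                      restored.predict_proba(probe))
        assert restored.params == results.params

    def test_summary_mentions_scheme_and_constraint(self, noise0_models):
        text = noise0_models[0].summary()
        assert "MACCS-167" in text and "5%" in text


class TestCrossValidate:
    PARAMS = HyperparameterPoint(n_estimators=50, max_depth=3, learning_rate=0.1,
                                 colsample_bytree=0.9, reg_lambda=0.1,
                                 min_child_weight=7)

    def test_fold_stratification_arithmetic(self):
        library = generate_library(
            SyntheticConfig(n_molecules=100, active_fraction=0.5, seed=21))
        reports, mean_acc, _ = cross_validate(library, FingerprintScheme("MACCS", 167),
                                              self.PARAMS, k=10, seed=4)
        assert len(reports) == 10
        for r in reports:
            assert r.n == 10
            assert r.tp + r.fn == 5  # 5 actives per fold

    def test_class_smaller_than_k_rejected(self):
        library = generate_library(
            SyntheticConfig(n_molecules=20, active_fraction=0.3, seed=1))
        with pytest.raises(ValueError, match="fewer members"):
            cross_validate(library, FingerprintScheme("MACCS", 167), self.PARAMS, k=10)

    def test_noise_free_rule_data_recovered(self, noise0_library):
        _, mean_acc, _ = cross_validate(noise0_library,
                                        FingerprintScheme("ECFP4", 1024),
                                        self.PARAMS, k=10, seed=4)
        assert mean_acc >= 0.9
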