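"""Label assignment, splitting, tuning, scoring and metrics."""

import numpy as np
import pandas as pd
import pytest

from thzburn.containers import SiteLabel
from thzburn.errors import (
    ConfigurationError,
    LabelError,
    PartitionError,
    UndefinedMetricError,
)
from thzburn.model import (
    FeatureCache,
    LabelScheme,
    TuningGrid,
    assign_labels,
    evaluate,
    observation_classes,
    run_experiment,
    score_observations,
    split_observations,
    tune_and_train,
)
from thzburn.pipeline import FeatureConfig


def _label(dermal, reepi=50.0, etiology="scald"):
    return SiteLabel("s", etiology, dermal, reepi)


class TestLabelAssignment:
    @pytest.mark.parametrize(
        "dermal,expected",
        [(45.0, "SPT"), (59.9, "SPT"), (60.0, "DPT"), (90.0, "DPT"), (90.1, "FT"), (100.0, "FT")],
    )
    def test_severity_thresholds(self, dermal, expected):
        assert assign_labels(_label(dermal))[0] == expected

    def test_healthy_etiology_overrides_depth(self):
        assert assign_labels(_label(0.0, etiology="healthy"))[0] == "H"

    @pytest.mark.parametrize("reepi,expected", [(100.0, "FR"), (99.0, "NPR"), (0.0, "NPR")])
    def test_healing_threshold(self, reepi, expected):
        assert assign_labels(_label(45.0, reepi=reepi))[1] == expected

    def test_out_of_range_percentage_rejected(self):
        bad = SiteLabel.__new__(SiteLabel)
        object.__setattr__(bad, "site_id", "s")
        object.__setattr__(bad, "etiology", "scald")
        object.__setattr__(bad, "dermal_burn_pct", 140.0)
        object.__setattr__(bad, "reepi_pct_day28", 50.0)
        with pytest.raises(LabelError):
            assign_labels(bad)

    def test_scheme_validation(self):
        with pytest.raises(ConfigurationError):
            LabelScheme(spt_upper=95.0, dpt_upper=90.0)


class TestSplitting:
    def test_fraction_arithmetic(self):
        y = np.array(["a"] * 50 + ["b"] * 50)
        train, test = split_observations(y, 0.8, seed=1)
        assert train.size == 80 and test.size == 20

    def test_seeded_reproducibility(self):
        y = np.array(["a"] * 30 + ["b"] * 30)
        s1 = split_observations(y, 0.8, seed=9)
        s2 = split_observations(y, 0.8, seed=9)
        np.testing.assert_array_equal(s1[0], s2[0])

    def test_stratification_within_one_observation(self):
        y = np.array(["a"] * 60 + ["b"] * 25 + ["c"] * 15)
        train, _ = split_observations(y, 0.8, seed=3)
        for cls, global_count in (("a", 60), ("b", 25), ("c", 15)):
            got = int(np.sum(y[train] == cls))
            assert abs(got - 0.8 * global_count) <= 1.0

    def test_starved_class_rejected(self):
        with pytest.raises(PartitionError):
            split_observations(np.array(["a"] * 10 + ["b"]), 0.8, seed=0)


class TestTuningGrid:
    def test_level_outside_8_13_rejected(self):
        with pytest.raises(ConfigurationError):
            TuningGrid(levels=(7,))
        with pytest.raises(ConfigurationError):
            TuningGrid(levels=(14,))

    def test_polynomial_order_outside_2_20_rejected(self):
        with pytest.raises(ConfigurationError):
            TuningGrid(polynomial_order=(1,))
        with pytest.raises(ConfigurationError):
            TuningGrid(polynomial_order=(21,))

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            TuningGrid(kernel_scale=())

    def test_default_grid_matches_search_space(self):
        g = TuningGrid()
        assert g.polynomial_order == tuple(range(2, 21))
        assert g.wavelets == tuple(range(1, 11))
        assert g.levels == tuple(range(8, 14))

    def test_candidate_enumeration(self):
        g = TuningGrid(
            kernels=("gaussian", "polynomial"),
            kernel_scale=(1.0,),
            box_constraint=(1.0,),
            polynomial_order=(2, 3),
            coding=("one-vs-one",),
        )
        # binary: 1 gaussian + 2 polynomial
        assert len(g.svm_candidates("healing")) == 3


@pytest.fixture(scope="module")
def tuned(demo_observations, demo_features_config):
    observations, air_gated = demo_observations
    y = observation_classes(observations, "severity")
    cache = FeatureCache(observations, air_gated, demo_features_config)
    grid = TuningGrid(
        kernels=("gaussian",), kernel_scale=(1.0, 10.0), box_constraint=(1.0, 10.0),
        wavelets=(1,), levels=(8,), coding=("one-vs-all",),
    )
    train_idx, test_idx = split_observations(y, 0.8, seed=5)
    model = tune_and_train(
        observations, train_idx, y, grid, "severity", cache,
        seed=5, keep_candidate_cv=True,
    )
    return observations, air_gated, y, cache, model, train_idx, test_idx


class TestTuneAndTrain:
    def test_single_candidate_grid_chooses_it(self, demo_observations, demo_features_config):
        observations, air_gated = demo_observations
        y = observation_classes(observations, "healing")
        cache = FeatureCache(observations, air_gated, demo_features_config)
        grid = TuningGrid(
            kernels=("gaussian",), kernel_scale=(2.0,), box_constraint=(3.0,),
            wavelets=(2,), levels=(8,),
        )
        train_idx, _ = split_observations(y, 0.8, seed=1)
        model = tune_and_train(observations, train_idx, y, grid, "healing", cache, seed=1)
        assert model.chosen["wavelet"] == "db2"
        assert model.chosen["kernel_scale"] == 2.0
        assert model.chosen["box_constraint"] == 3.0

    def test_winner_has_best_cv_accuracy(self, tuned):
        """The selection rule is internally consistent: no candidate beats
        the winner's cross-validation accuracy."""
        *_, model, _, _ = tuned
        assert model.candidate_cv is not None
        assert model.cv_accuracy >= model.candidate_cv["cv_accuracy"].max() - 1e-9

    def test_one_vs_all_uses_four_binary_learners(self, tuned):
        *_, model, _, _ = tuned
        assert model.n_binary_learners() == 4

    def test_one_vs_one_uses_six_binary_learners(self, demo_observations, demo_features_config):
        observations, air_gated = demo_observations
        y = observation_classes(observations, "severity")
        cache = FeatureCache(observations, air_gated, demo_features_config)
        grid = TuningGrid(
            kernels=("gaussian",), kernel_scale=(1.0,), box_constraint=(1.0,),
            wavelets=(1,), levels=(8,), coding=("one-vs-one",),
        )
        train_idx, _ = split_observations(y, 0.8, seed=2)
        model = tune_and_train(observations, train_idx, y, grid, "severity", cache, seed=2)
        assert model.n_binary_learners() == 6


class TestScoring:
    def test_probabilities_normalised_and_argmax_consistent(self, tuned):
        observations, _, y, cache, model, _, test_idx = tuned
        X = cache.matrix(1, 8)
        proba, predicted, classes = score_observations(model, None, X=X[test_idx])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(predicted, classes[np.argmax(proba, axis=1)])

    def test_training_duplicates_score_their_own_label(self, tuned):
        """Well-separated training observations are reproduced at large margin."""
        observations, _, y, cache, model, train_idx, _ = tuned
        X = cache.matrix(1, 8)
        _, predicted, _ = score_observations(model, None, X=X[train_idx])
        assert np.mean(predicted == y[train_idx]) > 0.95

    def test_feature_dimension_mismatch_rejected(self, tuned):
        *_, model, _, test_idx = tuned
        with pytest.raises(ConfigurationError):
            score_observations(model, None, X=np.zeros((3, 2)))


class TestMetrics:
    def test_hand_computed_confusion(self):
        """TP=8, FN=2, TN=9, FP=1 -> sens 80, spec 90, acc 85."""
        y = np.array(["pos"] * 10 + ["neg"] * 10)
        proba = np.zeros((20, 2))  # columns: neg, pos
        # 8 true positives, 2 false negatives, 1 false positive
        proba[:8, 1] = 0.9
        proba[8:10, 0] = 0.9
        proba[10, 1] = 0.9
        proba[11:, 0] = 0.9
        proba = proba / proba.sum(axis=1, keepdims=True)
        df = evaluate(y, proba, np.array(["neg", "pos"]), positive="pos")
        row = df.iloc[0]
        assert row["sensitivity"] == pytest.approx(80.0)
        assert row["specificity"] == pytest.approx(90.0)
        assert row["accuracy"] == pytest.approx(85.0)

    def test_perfect_ranking_auc(self):
        y = np.array(["n"] * 5 + ["p"] * 5)
        p_pos = np.concatenate([np.linspace(0.0, 0.4, 5), np.linspace(0.6, 1.0, 5)])
        proba = np.column_stack([1 - p_pos, p_pos])
        df = evaluate(y, proba, np.array(["n", "p"]), positive="p")
        assert df.iloc[0]["roc_auc"] == pytest.approx(100.0)

    def test_tied_probabilities_auc_is_chance(self):
        y = np.array(["n"] * 6 + ["p"] * 6)
        proba = np.full((12, 2), 0.5)
        df = evaluate(y, proba, np.array(["n", "p"]), positive="p")
        assert df.iloc[0]["roc_auc"] == pytest.approx(50.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            evaluate(np.array(["p", "p"]), np.full((2, 2), 0.5), np.array(["n", "p"]))


class TestExperiment:
    def test_report_layout_and_aggregate_consistency(self, demo_observations, demo_features_config):
        observations, air_gated = demo_observations
        grid = TuningGrid(
            kernels=("gaussian",), kernel_scale=(1.0,), box_constraint=(1.0,),
            wavelets=(1,), levels=(8,),
        )
        report = run_experiment(
            observations, air_gated, grid, "healing", demo_features_config,
            n_iterations=3, seed=17,
        )
        df = report.per_iteration
        test_rows = df[(df["subset"] == "test")]
        assert len(test_rows) == 3  # one positive-class row per iteration
        agg = report.aggregates()
        manual = test_rows["accuracy"].mean()
        got = agg[(agg["subset"] == "test")]["accuracy_mean"].iloc[0]
        assert got == pytest.approx(manual)
        assert ((df["accuracy"] >= 0) & (df["accuracy"] <= 100)).all()
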