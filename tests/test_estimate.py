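"""Feature matrix assembly, training protocol, prediction, tuning."""

import numpy as np
import pandas as pd
import pytest

from piezobp import FEATURE_COLUMNS, ModelConfig, build_feature_matrix, predict, train
from piezobp.errors import ConfigurationError, DataError
from piezobp.estimate import DEFAULT_SPACE, compare_algorithms, tune_hyperparameters
from piezobp.workbench import make_benchmark_table


@pytest.fixture(scope="module")
def small_table():
    return make_benchmark_table(n_windows=300, noise_sd=3.0, seed=11)


@pytest.fixture(scope="module")
def design(small_table):
    return build_feature_matrix(small_table)


class TestBuildFeatureMatrix:
    def test_shapes_and_manifest(self, small_table):
        X, y_sbp, y_dbp = build_feature_matrix(small_table)
        assert X.shape == (300, len(FEATURE_COLUMNS))
        assert list(X.columns) == list(FEATURE_COLUMNS)
        assert y_sbp.shape == y_dbp.shape == (300,)

    def test_missing_value_reported_with_row_index(self, small_table):
        bad = small_table.copy()
        bad.loc[7, "pwv"] = np.nan
        with pytest.raises(DataError, match="7"):
            build_feature_matrix(bad)

    def test_too_few_rows_rejected(self, small_table):
        with pytest.raises(DataError):
            build_feature_matrix(small_table.head(5))

    def test_sex_labels_encoded(self, small_table):
        relabeled = small_table.copy()
        relabeled["sex"] = np.where(relabeled["sex"] == 0, "male", "female")
        X, _, _ = build_feature_matrix(relabeled)
        assert set(X["sex"].unique()) <= {0.0, 1.0}


class TestTrain:
    def test_linear_target_recovered_near_noise_floor(self):
        """SBP = linear map of 3 features + N(0, 3): held-out SD <= 4.5 mmHg.

        Oracle: ordinary least squares on the same design reaches the
        3 mmHg noise floor; the tree ensemble must come close.
        """
        table = make_benchmark_table(n_windows=2000, noise_sd=3.0, seed=5)
        X, y_sbp, y_dbp = build_feature_matrix(table)
        model = train(X, y_sbp, y_dbp, ModelConfig(seed=5))
        holdout = model.cv_report.query("split == 'holdout' and target == 'sbp'")
        assert float(holdout["sd"].iloc[0]) <= 4.5
        # OLS oracle on the generative features
        A = np.column_stack([np.ones(len(X)), X["pwv"], X["st"], X["augmentation_index"]])
        coef, *_ = np.linalg.lstsq(A, y_sbp, rcond=None)
        resid_sd = np.std(y_sbp - A @ coef, ddof=4)
        assert resid_sd == pytest.approx(3.0, abs=0.3)

    def test_constant_labels_predicted_exactly(self, design):
        X, y_sbp, y_dbp = design
        const_s, const_d = np.full(len(X), 120.0), np.full(len(X), 80.0)
        model = train(X, const_s, const_d, ModelConfig(seed=0))
        holdout = model.cv_report.query("split == 'holdout'")
        assert (holdout["mae"] < 0.5).all()

    def test_seeded_determinism(self, design):
        X, y_sbp, y_dbp = design
        a = train(X, y_sbp, y_dbp, ModelConfig(seed=3))
        b = train(X, y_sbp, y_dbp, ModelConfig(seed=3))
        pd.testing.assert_frame_equal(a.cv_report, b.cv_report)
        assert a.fingerprint == b.fingerprint

    def test_fingerprint_order_independent(self, small_table):
        X1, s1, d1 = build_feature_matrix(small_table)
        shuffled = small_table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        X2, s2, d2 = build_feature_matrix(shuffled)
        from piezobp.estimate import _data_fingerprint

        assert _data_fingerprint(X1, s1, d1) == _data_fingerprint(X2, s2, d2)

    def test_fewer_rows_than_folds_rejected(self, design):
        X, y_sbp, y_dbp = design
        with pytest.raises(ConfigurationError):
            train(X.head(3), y_sbp[:3], y_dbp[:3], ModelConfig(n_folds=5))

    def test_generative_features_rank_high(self):
        """PWV, ST and augmentation index drive the labels: top-5 importances."""
        table = make_benchmark_table(n_windows=1500, noise_sd=3.0, seed=8)
        X, y_sbp, _ = build_feature_matrix(table)
        model = train(X, y_sbp, y_sbp, ModelConfig(seed=8))
        imp = pd.Series(model.sbp_model.feature_importances_, index=FEATURE_COLUMNS)
        top5 = set(imp.nlargest(5).index)
        assert {"pwv", "st", "augmentation_index"} <= top5


class TestPredict:
    def test_overfit_model_reproduces_training_rows(self, design):
        X, y_sbp, y_dbp = design
        cfg = ModelConfig(max_depth=12, n_estimators=300, learning_rate=0.3,
                          gamma=0.0, reg_alpha=0.0, seed=1)
        model = train(X, y_sbp, y_dbp, cfg)
        pairs = predict(model, X.head(20))
        ref = y_sbp[:20]
        assert np.mean(np.abs([p.sbp for p in pairs] - ref)) < 2.0

    def test_empty_input_gives_empty_output(self, design):
        X, y_sbp, y_dbp = design
        model = train(X, y_sbp, y_dbp, ModelConfig(seed=0))
        assert predict(model, X.head(0)) == []

    def test_manifest_mismatch_rejected(self, design):
        X, y_sbp, y_dbp = design
        model = train(X, y_sbp, y_dbp, ModelConfig(seed=0))
        with pytest.raises(DataError):
            predict(model, X[list(reversed(X.columns))])

    def test_sbp_prediction_beats_dbp_in_ordering(self, design):
        X, y_sbp, y_dbp = design
        model = train(X, y_sbp, y_dbp, ModelConfig(seed=0))
        pairs = predict(model, X.head(50))
        assert all(p.sbp > p.dbp for p in pairs)


class TestTuning:
    def test_collapsed_space_returns_that_point(self, design):
        X, y_sbp, _ = design
        space = {"max_depth": (6, 6, True, False)}
        cfg, trace = tune_hyperparameters(X, y_sbp, space=space, budget=10)
        assert cfg.max_depth == 6
        assert len(trace) == 10

    def test_tuned_never_worse_than_default(self, design):
        """The incumbent default config is in the trace, so best <= default."""
        X, y_sbp, _ = design
        cfg, trace = tune_hyperparameters(X, y_sbp, budget=10)
        default_rmse = trace["cv_rmse"].iloc[0]  # first evaluation is the default
        assert trace["cv_rmse"].min() <= default_rmse + 1e-9

    def test_empty_space_rejected(self, design):
        X, y_sbp, _ = design
        with pytest.raises(ConfigurationError):
            tune_hyperparameters(X, y_sbp, space={}, budget=10)


def test_algorithm_comparison_report(design):
    """All four algorithms produce a held-out report; ordering is informative only."""
    X, y_sbp, y_dbp = design
    report = compare_algorithms(X, y_sbp, y_dbp, seed=2)
    assert set(report["algorithm"]) == {"xgboost", "knn", "svr", "adaboost"}
    assert (report["rmse"] > 0).all()
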