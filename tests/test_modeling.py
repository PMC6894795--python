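"""VIF screening, model-kind rule, splitting, fitting, prediction."""

import math

import numpy as np
import pytest

from sumroc import (
    SimulatedPopulation,
    choose_model_kind,
    compute_vif,
    fit_risk_model,
    pair_count_auroc,
    predict_risk,
    simulate_population,
    split_population,
)

from conftest import make_study


def make_pop(features, labels, coding="dominant"):
    return SimulatedPopulation(
        features=np.asarray(features, dtype=np.uint8),
        labels=np.asarray(labels, dtype=np.int8),
        coding=coding,
    )


class TestVIF:
    def test_independent_columns_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(10000, 2))
        vifs = compute_vif(X)
        assert np.all(vifs >= 1.0) and np.all(vifs < 1.1)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=2000)
        vifs = compute_vif(np.column_stack([x, x, rng.integers(0, 2, 2000)]))
        assert np.isinf(vifs[0]) and np.isinf(vifs[1])
        assert np.isfinite(vifs[2])

    def test_constant_column_infinite(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(100), rng.integers(0, 2, 100)])
        assert np.isinf(compute_vif(X)[0])

    def test_two_predictor_closed_form(self):
        # for two predictors VIF = 1/(1 - r^2) with r the sample correlation
        rng = np.random.default_rng(3)
        z = rng.normal(size=5000)
        x = z + 0.5 * rng.normal(size=5000)
        y = z + 0.5 * rng.normal(size=5000)
        r = np.corrcoef(x, y)[0, 1]
        vifs = compute_vif(np.column_stack([x, y]))
        assert vifs[0] == pytest.approx(1.0 / (1.0 - r**2), rel=1e-9)
        assert vifs[1] == pytest.approx(vifs[0], rel=1e-9)

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            compute_vif(np.ones((10, 1)))


class TestChooseModelKind:
    @pytest.mark.parametrize(
        "vifs,expected",
        [
            ([1.2, 1.3, 5.0], "standard"),
            ([np.inf, np.inf, 1.0], "ridge"),
            ([np.inf, 1.0], "standard"),  # one inflated entry is not enough
        ],
    )
    def test_at_least_two_infinite_rule(self, vifs, expected):
        assert choose_model_kind(vifs) == expected


class TestSplit:
    def test_stratified_counts(self):
        rng = np.random.default_rng(0)
        pop = make_pop(np.zeros((2000, 1)), np.r_[np.zeros(1000), np.ones(1000)])
        train, test = split_population(pop, 0.7, rng)
        assert (train.labels == 1).sum() == 700
        assert (train.labels == 0).sum() == 700
        assert (test.labels == 1).sum() == 300

    def test_same_seed_identical(self):
        pop = make_pop(
            np.arange(400).reshape(-1, 1) % 2, np.r_[np.zeros(200), np.ones(200)]
        )
        a = split_population(pop, 0.7, np.random.default_rng(5))
        b = split_population(pop, 0.7, np.random.default_rng(5))
        assert np.array_equal(a[0].features, b[0].features)
        assert np.array_equal(a[1].labels, b[1].labels)

    def test_odd_counts_within_one_of_half(self):
        pop = make_pop(np.zeros((2000, 1)), np.r_[np.zeros(1001), np.ones(999)])
        train, _ = split_population(pop, 0.5, np.random.default_rng(1))
        assert abs((train.labels == 0).sum() - 500.5) <= 1
        assert abs((train.labels == 1).sum() - 499.5) <= 1

    def test_tiny_class_errors(self):
        pop = make_pop(np.zeros((6, 1)), np.r_[np.zeros(3), np.ones(3)])
        with pytest.raises(ValueError):
            split_population(pop, 0.9, np.random.default_rng(0))


class TestFit:
    def test_single_snp_mle_matches_two_cell_closed_form(self):
        # carriers: 60% of cases, 20% of controls; the two-cell logistic
        # MLE reproduces the empirical class rates exactly
        n = 1000
        x_ctrl = np.r_[np.ones(200), np.zeros(800)]
        x_case = np.r_[np.ones(600), np.zeros(400)]
        pop = make_pop(
            np.r_[x_ctrl, x_case].reshape(-1, 1), np.r_[np.zeros(n), np.ones(n)]
        )
        model = fit_risk_model(pop, "standard", rng=np.random.default_rng(0))
        risk_carrier = predict_risk(model, [[1]])[0]
        risk_non = predict_risk(model, [[0]])[0]
        assert risk_carrier == pytest.approx(0.6 / (0.6 + 0.2), abs=1e-6)
        assert risk_non == pytest.approx(0.4 / (0.4 + 0.8), abs=1e-6)
        assert model.coefficients[0] > 0
        assert model.model_kind == "standard"

    def test_all_zero_column_gets_zero_coefficient_under_ridge(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 1000)
        pop = make_pop(
            np.column_stack([x, np.zeros(1000)]),
            (rng.random(1000) < 0.3 + 0.3 * x).astype(int),
        )
        model = fit_risk_model(
            pop, "ridge", penalty_grid=[1.0], rng=np.random.default_rng(2)
        )
        assert model.coefficients[1] == pytest.approx(0.0, abs=1e-8)

    def test_null_study_cv_auroc_near_half(self):
        study = make_study("null", 5000, 5000, [(1.0, 0.3), (1.0, 0.5)])
        pop = simulate_population(study, rng=np.random.default_rng(3))
        model = fit_risk_model(pop, "standard", rng=np.random.default_rng(4))
        assert model.cv_auroc == pytest.approx(0.5, abs=0.02)

    def test_separation_falls_back_to_ridge(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        pop = make_pop(y.reshape(-1, 1), y)  # feature == label: separation
        model = fit_risk_model(pop, "standard", rng=np.random.default_rng(0))
        assert model.model_kind == "ridge"
        assert "separation_fallback" in model.warnings

    def test_coefficient_consistent_with_simulated_carrier_or(self):
        study = make_study("big", 10000, 10000, [(2.0, 0.3)])
        pop = simulate_population(study, rng=np.random.default_rng(11))
        p_ctrl = pop.features[pop.labels == 0, 0].mean()
        p_case = pop.features[pop.labels == 1, 0].mean()
        carrier_log_or = math.log(
            (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
        )
        model = fit_risk_model(pop, "standard", rng=np.random.default_rng(12))
        assert model.coefficients[0] == pytest.approx(carrier_log_or, abs=0.05)

    def test_ridge_on_duplicated_panel_matches_standard_on_dedup(self):
        study = make_study("dup", 5000, 5000, [(2.0, 0.3)])
        pop = simulate_population(study, rng=np.random.default_rng(21))
        train, test = split_population(pop, 0.7, np.random.default_rng(22))
        dup_train = make_pop(
            np.column_stack([train.features[:, 0]] * 2), train.labels
        )
        m_std = fit_risk_model(train, "standard", rng=np.random.default_rng(23))
        m_ridge = fit_risk_model(dup_train, "ridge", rng=np.random.default_rng(23))
        auc_std = pair_count_auroc(predict_risk(m_std, test.features), test.labels)
        dup_test = np.column_stack([test.features[:, 0]] * 2)
        auc_ridge = pair_count_auroc(predict_risk(m_ridge, dup_test), test.labels)
        assert auc_ridge == pytest.approx(auc_std, abs=0.005)

    def test_nested_cv_estimate_is_honest_on_null(self):
        # on pure-noise features with many penalties to tune, the nested
        # estimate must not drift optimistically above chance
        rng = np.random.default_rng(31)
        pop = make_pop(
            rng.integers(0, 2, size=(2000, 8)),
            np.r_[np.zeros(1000), np.ones(1000)],
        )
        model = fit_risk_model(pop, "ridge", rng=np.random.default_rng(32))
        assert model.cv_auroc < 0.54


class TestPredict:
    def test_zero_model_gives_half(self):
        from sumroc import FittedRiskModel

        model = FittedRiskModel(0.0, np.zeros(1), "standard")
        assert predict_risk(model, [[0], [1]]) == pytest.approx([0.5, 0.5])

    def test_direct_arithmetic(self):
        from sumroc import FittedRiskModel

        model = FittedRiskModel(-1.0, np.array([2.0]), "standard")
        assert predict_risk(model, [[1]])[0] == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-12
        )

    def test_monotone_in_positive_coefficient(self):
        from sumroc import FittedRiskModel

        model = FittedRiskModel(0.3, np.array([1.7, -0.4]), "standard")
        assert predict_risk(model, [[1, 1]])[0] >= predict_risk(model, [[0, 1]])[0]

    def test_width_mismatch_errors(self):
        from sumroc import FittedRiskModel

        model = FittedRiskModel(0.0, np.zeros(2), "standard")
        with pytest.raises(ValueError):
            predict_risk(model, [[1]])
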