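"""Risk model: design construction, logistic fit, performance metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from riskhte import (
    RiskModel,
    Variable,
    VariableSchema,
    brier_score,
    build_design,
    c_statistic,
    calibration,
    fit_logistic,
    generate_trial,
    ist3_schema,
)
from riskhte.errors import (
    DegenerateDesignError,
    SeparationError,
    UndefinedMetricError,
)

from conftest import make_table, small_config


def intercept_design(n):
    return pd.DataFrame({"intercept": np.ones(n)})


class TestBuildDesign:
    def test_binary_predictor_single_indicator(self, small_schema):
        table = make_table(
            small_schema,
            ["control", "treated"] * 3,
            [0, 1, 0, 1, 0, 1],
            age=[60.0, 70, 80, 65, 75, 85],
            sex=["Female", "Male", "Male", "Female", "Male", "Female"],
        )
        X = build_design(table)
        assert list(X.columns) == ["intercept", "age", "sex=Male"]
        assert X["sex=Male"].tolist() == [0, 1, 1, 0, 1, 0]

    def test_multilevel_predictor_indicator_per_nonreference_level(self):
        X_cols = [
            c
            for c in build_design(
                generate_trial(
                    __import__("riskhte").default_ist3_config(n_patients=300, seed=2)
                )
            ).columns
        ]
        assert X_cols.count("stroke_subtype=PACI") == 1
        assert X_cols.count("stroke_subtype=POCI") == 1
        assert X_cols.count("stroke_subtype=TACI") == 1
        assert "stroke_subtype=LACI" not in X_cols  # reference level
        assert len(X_cols) == 22  # intercept + 21 predictor terms

    def test_single_observed_level_degenerate(self, small_schema):
        table = make_table(
            small_schema,
            ["control"] * 4 + ["treated"],
            [0, 1, 0, 1, 1],
            age=[60.0, 70, 80, 65, 75],
            sex=["Female"] * 5,
        )
        with pytest.raises(DegenerateDesignError, match="sex"):
            build_design(table)

    def test_constant_continuous_degenerate(self, small_schema):
        table = make_table(
            small_schema,
            ["control", "treated"] * 2,
            [0, 1, 0, 1],
            age=[70.0] * 4,
            sex=["Female", "Male", "Male", "Female"],
        )
        with pytest.raises(DegenerateDesignError, match="age"):
            build_design(table)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        """25 successes of 100: the MLE intercept is logit(0.25)."""
        y = np.array([1] * 25 + [0] * 75)
        res = fit_logistic(intercept_design(100), y)
        assert np.isclose(res.params.iloc[0], np.log(25 / 75), atol=1e-8)

    def test_two_by_two_closed_form(self):
        """Cell counts (20,80 ; 40,60): slope equals log[(40/60)/(20/80)]."""
        x = np.array([0] * 100 + [1] * 100)
        y = np.array([1] * 20 + [0] * 80 + [1] * 40 + [0] * 60)
        X = pd.DataFrame({"intercept": np.ones(200), "x": x})
        res = fit_logistic(X, y)
        assert np.isclose(res.params.iloc[1], np.log(8 / 3), atol=1e-6)
        assert np.isclose(res.params.iloc[0], np.log(20 / 80), atol=1e-6)

    def test_separation_detected(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(int)  # perfectly separable
        X = pd.DataFrame({"intercept": np.ones(40), "x": x})
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_logistic(intercept_design(10), np.ones(10))

    def test_more_terms_than_rows_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(DegenerateDesignError):
            fit_logistic(X, np.array([0, 1, 0]))


@pytest.fixture(scope="module")
def fitted():
    table = generate_trial(small_config(n=3000, seed=5, intercept=-0.3))
    return RiskModel(table).fit()


class TestRiskModelResults:
    def test_probability_is_expit_of_lp(self, fitted):
        assert np.allclose(
            fitted.predicted_probability, expit(fitted.linear_predictor)
        )

    def test_gradient_vanishes_at_optimum(self, fitted):
        assert np.abs(fitted.score_vector()).max() < 1e-6

    def test_treatment_blindness(self):
        """Permuting treatment labels leaves every fit field unchanged."""
        table = generate_trial(small_config(n=500, seed=9))
        res_a = RiskModel(table).fit()
        permuted = table.copy()
        rng = np.random.default_rng(0)
        permuted.data["treatment"] = rng.permutation(
            permuted.data["treatment"].to_numpy()
        )
        res_b = RiskModel(permuted).fit()
        assert np.array_equal(res_a.params.to_numpy(), res_b.params.to_numpy())
        assert np.array_equal(res_a.linear_predictor, res_b.linear_predictor)
        assert "treatment" not in res_a.terms

    def test_coefficient_recovery_small(self):
        """Generative coefficients recovered within 3 SE at n = 20000 on a
        null trial (treatment-blind model correctly specified)."""
        cfg = small_config(n=20_000, seed=31, intercept=-0.5)
        res = RiskModel(generate_trial(cfg)).fit()
        truth = {"intercept": -0.5, "x": 0.8, "g=b": -0.5}
        for term, tv in truth.items():
            assert abs(res.params[term] - tv) < 3 * res.bse[term]

    def test_odds_ratio_table_shape(self, fitted):
        orr = fitted.odds_ratios()
        assert "intercept" not in orr.index
        assert np.all(orr["ci_low"] <= orr["odds_ratio"])
        assert np.all(orr["odds_ratio"] <= orr["ci_high"])
        assert np.allclose(orr["odds_ratio"], np.exp(fitted.params.drop("intercept")))

    def test_serialization_and_summary(self, fitted, tmp_path):
        fitted.to_json(tmp_path / "fit.json")
        import json

        blob = json.loads((tmp_path / "fit.json").read_text())
        assert blob["n_used"] == fitted.n_used
        assert "c_statistic" in blob["performance"]
        assert "odds_ratios" in blob
        assert "x" in fitted.summary()


def pair_count_c(predicted, outcome):
    """Exhaustive-pair oracle: concordant pairs + half ties."""
    pos = [p for p, y in zip(predicted, outcome) if y == 1]
    neg = [p for p, y in zip(predicted, outcome) if y == 0]
    total = conc = ties = 0
    for a, b in itertools.product(pos, neg):
        total += 1
        if a > b:
            conc += 1
        elif a == b:
            ties += 1
    return (conc + 0.5 * ties) / total


class TestCStatistic:
    def test_perfect_ordering(self):
        assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_predictions_half(self):
        assert c_statistic([0.4] * 6, [0, 1, 0, 1, 1, 0]) == 0.5

    def test_six_patient_toy_matches_enumeration(self):
        p = [0.2, 0.7, 0.4, 0.4, 0.9, 0.1]
        y = [0, 1, 0, 1, 0, 0]
        assert np.isclose(c_statistic(p, y), pair_count_c(p, y))

    @given(
        n=st.integers(2, 50),
        seed=st.integers(0, 10_000),
        tie_prone=st.booleans(),
    )
    def test_matches_pair_enumeration(self, n, seed, tie_prone):
        """Property: equals the exhaustive pair-count oracle for all n <= 50."""
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p = r.choice([0.1, 0.3, 0.5], size=n) if tie_prone else r.random(n)
        assert np.isclose(c_statistic(p, y), pair_count_c(p, y), atol=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            c_statistic([0.1, 0.9], [1, 1])


class TestBrierScore:
    def test_perfect_predictions(self):
        assert brier_score([0.0, 1.0, 1.0], [0, 1, 1]) == 0.0

    def test_all_half_is_quarter(self):
        assert brier_score([0.5] * 5, [0, 1, 1, 0, 1]) == 0.25

    def test_direct_arithmetic(self):
        assert np.isclose(brier_score([0.2, 0.9], [0, 1]), 0.025)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brier_score([1.2], [1])


class TestCalibration:
    @staticmethod
    def _simulate(n, shrink=1.0, seed=0):
        r = np.random.default_rng(seed)
        lp = r.normal(0, 1.5, size=n)
        y = (r.random(n) < expit(lp)).astype(float)
        return lp / shrink, y

    def test_self_calibration_limit(self):
        """Outcome regressed on its own generating linear predictor:
        slope -> 1, intercept -> 0."""
        lp, y = self._simulate(200_000, seed=4)
        intercept, slope = calibration(lp, y)
        assert abs(slope - 1.0) < 0.03
        assert abs(intercept) < 0.03

    def test_shrunk_logit_doubles_slope(self):
        """Predictions shrunk by factor 2 on the logit scale: slope -> 2."""
        lp_half, y = self._simulate(200_000, shrink=2.0, seed=8)
        _, slope = calibration(lp_half, y)
        assert abs(slope - 2.0) < 0.06

    def test_constant_lp_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            calibration(np.zeros(50), np.tile([0, 1], 25))
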