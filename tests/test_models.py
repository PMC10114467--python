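"""Model representation: linear predictors, probabilities, conditional risk, scores."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cpmval as cv
from cpmval.cohort import Cohort
from cpmval.models import (
    MultinomialCPM,
    ProbabilityMatrix,
    Term,
    model_from_dict,
    model_to_dict,
    softmax_probabilities,
)
from cpmval.schema import PredictorSchema, SchemaError, Variable

from conftest import data_path


def make_model(intercepts, coefs, terms, cats=("ref", "a", "b")):
    cats = list(cats)
    return MultinomialCPM(
        name="m",
        categories=cats,
        reference=cats[0],
        terms=terms,
        intercepts=dict(zip(cats[1:], intercepts)),
        coefficients={k: np.asarray(c, float) for k, c in zip(cats[1:], coefs)},
    )


class TestLinearPredictors:
    def test_intercept_only(self):
        m = make_model((-2.0, -3.0), ([0.0], [0.0]), [Term("x")])
        eta = cv.linear_predictors(m, pd.DataFrame({"x": [0.7, -1.3]}))
        assert np.allclose(eta, [[-2, -3], [-2, -3]])

    def test_single_term_arithmetic(self):
        m = make_model((1.0,), ([0.5],), [Term("temperature")], cats=("ref", "a"))
        eta = cv.linear_predictors(m, pd.DataFrame({"temperature": [38.0]}))
        assert eta[0, 0] == pytest.approx(1 + 0.5 * 38)  # = 20

    def test_three_term_hand_table(self):
        """Five records against a hand-computed linear-predictor table."""
        m = make_model(
            (1.0, -1.0),
            ([0.5, 1.0, 2.0], [0.1, -0.5, 1.0]),
            [Term("temperature"), Term("crp", "log"), Term("ill", "indicator", level=1)],
        )
        df = pd.DataFrame(
            {
                "temperature": [38.0, 37.0, 40.0, 36.5, 39.0],
                "crp": np.exp([1.0, 0.0, 2.0, 0.5, 3.0]),
                "ill": [1, 0, 1, 0, 1],
            }
        )
        expected = np.array(
            [  # alpha + 0.5*temp + 1.0*log(crp) + 2*ill ; alpha + 0.1*temp - 0.5*log(crp) + 1*ill
                [23.0, 3.3],
                [19.5, 2.7],
                [25.0, 3.0],
                [19.75, 2.4],
                [25.5, 2.4],
            ]
        )
        assert np.allclose(cv.linear_predictors(m, df), expected, atol=1e-9)

    def test_unresolvable_variable(self):
        m = make_model((0.0,), ([1.0],), [Term("missing_col")], cats=("ref", "a"))
        with pytest.raises(SchemaError, match="missing_col"):
            cv.linear_predictors(m, pd.DataFrame({"x": [1.0]}))

    def test_range_error_names_variable(self):
        schema = PredictorSchema([Variable("temperature", "continuous", "°C", allowed_range=(34, 43))])
        m = make_model((0.0,), ([1.0],), [Term("temperature")], cats=("ref", "a"))
        m.schema = schema
        with pytest.raises(cv.models.RangeError, match="temperature"):
            cv.linear_predictors(m, pd.DataFrame({"temperature": [50.0]}))


class TestPredictProbabilities:
    def test_symmetric_etas(self):
        P = softmax_probabilities(np.zeros((4, 2)), ["r", "a", "b"], "r")
        assert np.allclose(P.values, 1.0 / 3.0)

    def test_saturation_no_overflow(self):
        P = softmax_probabilities(np.array([[50.0, 0.0]]), ["r", "a", "b"], "r")
        assert P.column("a")[0] > 1 - 1e-15
        P = softmax_probabilities(np.array([[700.0, -700.0]]), ["r", "a", "b"], "r")
        assert np.all(np.isfinite(P.values))

    def test_closed_form(self):
        P = softmax_probabilities(np.log([[2.0, 3.0]]), ["r", "a", "b"], "r")
        assert np.allclose(P.values[0], [1 / 6, 2 / 6, 3 / 6])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=8))
    def test_rows_sum_to_one(self, etas):
        eta = np.array([etas])
        cats = ["r"] + [f"c{i}" for i in range(len(etas))]
        P = softmax_probabilities(eta, cats, "r")
        assert abs(P.values.sum() - 1.0) < 1e-9


class TestConditionalRisk:
    def test_arithmetic(self):
        P = ProbabilityMatrix(np.array([[0.7, 0.2, 0.1]]), ["no", "pneu", "other"], "no")
        assert cv.conditional_risk(P, "pneu")[0] == pytest.approx(0.2 / 0.9)

    def test_boundaries(self):
        P = ProbabilityMatrix(np.array([[0.5, 0.0, 0.5], [0.0, 0.6, 0.4]]), ["no", "a", "b"], "no")
        r = cv.conditional_risk(P, "a")
        assert r[0] == 0.0 and r[1] == 1.0

    def test_zero_zero_flagged_nan(self):
        P = ProbabilityMatrix(np.array([[0.0, 0.0, 1.0]]), ["no", "a", "b"], "no")
        assert np.isnan(cv.conditional_risk(P, "a")[0])

    def test_reference_is_an_error(self):
        P = ProbabilityMatrix(np.array([[0.5, 0.5]]), ["no", "a"], "no")
        with pytest.raises(ValueError):
            cv.conditional_risk(P, "no")

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(0.01, 5.0))
    def test_strictly_increasing_in_eta(self, eta_k, eta_other, delta):
        def risk(e):
            P = softmax_probabilities(np.array([[e, eta_other]]), ["r", "k", "o"], "r")
            return cv.conditional_risk(P, "k")[0]

        assert risk(eta_k + delta) > risk(eta_k)


class TestRiskScores:
    def test_non_deviant_defaults_score_zero(self, paws_like):
        df = pd.DataFrame(
            {
                "age": [2.0],
                "heart_rate": [110.0],
                "resp_rate": [25.0],
                "temperature": [37.0],
                "oxygen_sat_low": [0],
                "ill_appearance": [0],
                "conscious_level": ["alert"],
            }
        )
        assert cv.apply_risk_score(paws_like, df)[0] == 0

    def test_two_item_addition(self):
        score = cv.RiskScoreDef(
            name="two",
            items=[
                {
                    "variable": "heart_rate",
                    "bands": [
                        {"age": [0.0, 16.0], "intervals": [{"value": [150, 400], "points": 2}]}
                    ],
                },
                {"variable": "conscious", "points": {"alert": 0, "pain": 3}},
            ],
        )
        df = pd.DataFrame({"age": [3.0], "heart_rate": [160.0], "conscious": ["pain"]})
        assert cv.apply_risk_score(score, df)[0] == 5

    def test_hand_scored_table(self, paws_like):
        df = pd.DataFrame(
            {
                "age": [0.5, 0.5, 2, 2, 7, 7, 13, 13, 16, 1.0],
                "heart_rate": [120, 170, 150, 100, 60, 110, 105, 80, 59, 90],
                "resp_rate": [30, 55, 42, 30, 10, 25, 26, 20, 9, 50],
                "temperature": [37.0, 39.0, 38.5, 36.0, 35.0, 38.4, 37.5, 38.6, 36.5, 34.0],
                "oxygen_sat_low": [0, 0, 1, 0, 0, 0, 0, 0, 1, 0],
                "ill_appearance": [0, 0, 0, 0, 1, 0, 0, 0, 1, 0],
                "conscious_level": [
                    "alert", "alert", "voice", "alert", "pain",
                    "alert", "alert", "unresponsive", "alert", "alert",
                ],
            }
        )
        hand_scored = [0, 5, 8, 0, 9, 0, 4, 4, 8, 3]
        assert cv.apply_risk_score(paws_like, df).tolist() == hand_scored

    def test_age_outside_bands_raises(self, paws_like):
        df = pd.DataFrame(
            {
                "age": [17.0],
                "heart_rate": [100.0],
                "resp_rate": [20.0],
                "temperature": [37.0],
                "oxygen_sat_low": [0],
                "ill_appearance": [0],
                "conscious_level": ["alert"],
            }
        )
        with pytest.raises(cv.models.BandingError):
            cv.apply_risk_score(paws_like, df)

    def test_overlapping_age_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cv.RiskScoreDef(
                name="bad",
                items=[
                    {
                        "variable": "hr",
                        "bands": [
                            {"age": [0.0, 5.0], "intervals": [{"value": [0, 1], "points": 1}]},
                            {"age": [4.0, 16.0], "intervals": [{"value": [0, 1], "points": 1}]},
                        ],
                    }
                ],
            )


class TestSchema:
    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError):
            PredictorSchema([Variable("a"), Variable("a")])

    def test_ambiguous_alias_rejected(self):
        with pytest.raises(SchemaError):
            PredictorSchema([Variable("a", aliases=("x",)), Variable("b", aliases=("x",))])

    def test_default_outside_range_rejected(self):
        with pytest.raises(SchemaError):
            Variable("crp", "continuous", non_deviant_default=500.0, allowed_range=(0, 400))

    def test_alias_mapping_idempotent(self):
        s = PredictorSchema([Variable("crp", aliases=("poc_crp",)), Variable("temp")])
        cols = ["poc_crp", "temp", "other"]
        once = [s.alias_map().get(c, c) for c in cols]
        twice = [s.alias_map().get(c, c) for c in once]
        assert once == twice == ["crp", "temp", "other"]


class TestModelFiles:
    @pytest.mark.parametrize(
        "name",
        ["feverkids_like.json", "craig_like.json", "sbi_model_like.json", "paws_like.json", "sbi_score_like.json"],
    )
    def test_round_trip_lossless(self, name):
        with open(data_path(name), encoding="utf-8") as fh:
            raw = json.load(fh)
        assert model_to_dict(model_from_dict(raw)) == raw

    def test_binomial_requires_two_categories(self, feverkids_like):
        d = model_to_dict(feverkids_like)
        d["type"] = "binomial"
        with pytest.raises(ValueError):
            model_from_dict(d)

    def test_reference_carries_no_parameters(self, feverkids_like):
        assert feverkids_like.reference not in feverkids_like.coefficients
        d = model_to_dict(feverkids_like)
        d["coefficients"][d["reference"]] = {"intercept": 0.0, "betas": []}
        with pytest.raises(ValueError):
            model_from_dict(d)
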