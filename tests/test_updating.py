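"""Model updating: recalibration, revision, shrinkage, and the full pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist
from sklearn.linear_model import LogisticRegression

import cpmval as cv
from cpmval.cohort import Cohort
from cpmval.mnlogit import ConvergenceError, fit_multinomial, null_loglik
from cpmval.models import MultinomialCPM, Term, design_matrix

from conftest import simple_cohort, simple_truth


class TestRecalibrate:
    def test_self_recovery(self, truth3, cohort50k):
        """Recalibrating the generating model leaves it (nearly) unchanged."""
        cohort, _ = cohort50k
        recal = cv.recalibrate(truth3, cohort)
        for k in truth3.nonreference:
            s = recal.coefficients[k][0] / truth3.coefficients[k][0]
            assert s == pytest.approx(1.0, abs=0.05)
            a = recal.intercepts[k] - s * truth3.intercepts[k]
            assert a == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_known_distortion_recovers_inverse_slope(self, truth3, cohort50k, c):
        cohort, _ = cohort50k
        distorted = truth3.replace_parameters(
            {k: c * v for k, v in truth3.intercepts.items()},
            {k: c * v for k, v in truth3.coefficients.items()},
        )
        recal = cv.recalibrate(distorted, cohort)
        for k in truth3.nonreference:
            s = recal.coefficients[k][0] / distorted.coefficients[k][0]
            assert s == pytest.approx(1.0 / c, abs=0.05)

    def test_fixed_point_calibration(self, truth3, cohort20k):
        cohort, _ = cohort20k
        recal = cv.recalibrate(truth3, cohort)
        P = cv.predict_probabilities(recal, cohort)
        cal = cv.multinomial_calibration(P, cohort.df["outcome"].to_numpy())
        for fit in cal.values():
            assert abs(fit.intercept) < 1e-6 and abs(fit.slope - 1.0) < 1e-6


class TestRevise:
    def test_parameter_recovery(self, cohort20k):
        truth = simple_truth()
        cohort, _ = cohort20k
        revised, chi2, df = cv.revise(truth, cohort)
        for k in truth.nonreference:
            assert revised.intercepts[k] == pytest.approx(truth.intercepts[k], abs=0.15)
            assert np.allclose(revised.coefficients[k], truth.coefficients[k], atol=0.15)
        assert df == 4 and chi2 > 0

    def test_agrees_with_sklearn_multinomial(self, cohort20k):
        """Independent route: unpenalised scikit-learn multinomial fit."""
        truth = simple_truth()
        cohort, _ = cohort20k
        revised, _, _ = cv.revise(truth, cohort)
        X = design_matrix(truth, cohort)
        y = cohort.df["outcome"].to_numpy()
        sk = LogisticRegression(C=np.inf, tol=1e-10, max_iter=2000).fit(X, y)
        classes = list(sk.classes_)
        i_ref = classes.index("no_sbi")
        for k in truth.nonreference:
            i_k = classes.index(k)
            sk_beta = sk.coef_[i_k] - sk.coef_[i_ref]
            sk_alpha = sk.intercept_[i_k] - sk.intercept_[i_ref]
            assert revised.intercepts[k] == pytest.approx(sk_alpha, abs=1e-4)
            assert np.allclose(revised.coefficients[k], sk_beta, atol=1e-4)

    def test_null_truth_chi2_distribution(self):
        """Under an intercept-only truth, the LR chi2 behaves like chi2_df."""
        truth = simple_truth(coefs=((0.0, 0.0), (0.0, 0.0)))
        exceed = 0
        reps = 200
        for r in range(reps):
            cohort, _ = simple_cohort(truth, 400, seed=1000 + r)
            if cohort.df["outcome"].nunique() < 3:
                continue
            _, chi2, df = cv.revise(truth, cohort)
            if chi2 > chi2_dist.ppf(0.95, df):
                exceed += 1
        assert exceed / reps < 0.10

    def test_saturated_binary_predictor_closed_form(self):
        """One two-level predictor: coefficients equal the 2xK table log-odds-ratios."""
        rows = []
        counts = {(0, "no_sbi"): 400, (0, "pneumonia"): 40, (0, "other_sbi"): 20,
                  (1, "no_sbi"): 200, (1, "pneumonia"): 60, (1, "other_sbi"): 25}
        for (x, out), c in counts.items():
            rows += [{"x1": float(x), "outcome": out}] * c
        cohort = Cohort(pd.DataFrame(rows))
        model = MultinomialCPM(
            name="sat", categories=["no_sbi", "pneumonia", "other_sbi"], reference="no_sbi",
            terms=[Term("x1")], intercepts={"pneumonia": 0.0, "other_sbi": 0.0},
            coefficients={"pneumonia": np.zeros(1), "other_sbi": np.zeros(1)},
        )
        revised, _, _ = cv.revise(model, cohort)
        for k in ("pneumonia", "other_sbi"):
            lor = np.log(counts[(1, k)] / counts[(1, "no_sbi")]) - np.log(
                counts[(0, k)] / counts[(0, "no_sbi")]
            )
            intc = np.log(counts[(0, k)] / counts[(0, "no_sbi")])
            assert revised.coefficients[k][0] == pytest.approx(lor, abs=1e-5)
            assert revised.intercepts[k] == pytest.approx(intc, abs=1e-5)

    def test_rank_deficiency_names_terms(self, cohort20k):
        cohort, _ = cohort20k
        model = MultinomialCPM(
            name="collinear", categories=["no_sbi", "pneumonia", "other_sbi"], reference="no_sbi",
            terms=[Term("x1"), Term("x1")],
            intercepts={"pneumonia": 0.0, "other_sbi": 0.0},
            coefficients={"pneumonia": np.zeros(2), "other_sbi": np.zeros(2)},
        )
        with pytest.raises(np.linalg.LinAlgError, match="x1"):
            cv.revise(model, cohort)


class TestShrinkage:
    def test_arithmetic(self):
        assert cv.shrinkage_factor(100.0, 10) == pytest.approx(0.9)

    def test_clamped_at_zero(self):
        assert cv.shrinkage_factor(5.0, 10) == 0.0

    def test_limit_to_one(self):
        assert cv.shrinkage_factor(1e12, 10) == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_chi2_warns_zero(self):
        with pytest.warns(UserWarning):
            assert cv.shrinkage_factor(-1.0, 3) == 0.0

    def test_endpoints(self, truth3, cohort20k):
        cohort, _ = cohort20k
        recal = cv.recalibrate(truth3, cohort)
        revised, _, _ = cv.revise(truth3, cohort)
        at1 = cv.shrink_towards(revised, recal, 1.0, cohort)
        at0 = cv.shrink_towards(revised, recal, 0.0, cohort)
        for k in truth3.nonreference:
            assert np.allclose(at1.coefficients[k], revised.coefficients[k])
            assert np.allclose(at0.coefficients[k], recal.coefficients[k])

    @pytest.mark.parametrize("gamma", [0.0, 0.37, 1.0])
    def test_final_calibration_intercept_zero_for_any_gamma(self, truth3, cohort20k, gamma):
        cohort, _ = cohort20k
        recal = cv.recalibrate(truth3, cohort)
        revised, _, _ = cv.revise(truth3, cohort)
        final = cv.shrink_towards(revised, recal, gamma, cohort)
        P = cv.predict_probabilities(final, cohort)
        cal = cv.multinomial_calibration(P, cohort.df["outcome"].to_numpy())
        for fit in cal.values():
            assert round(fit.intercept, 2) == 0.0 and abs(fit.intercept) < 1e-6

    def test_convexity_of_final_coefficients(self, truth3, cohort20k):
        cohort, _ = cohort20k
        rep = cv.update_pipeline(truth3, cohort)
        for k in truth3.nonreference:
            lo = np.minimum(rep.revised.coefficients[k], rep.recalibrated.coefficients[k])
            hi = np.maximum(rep.revised.coefficients[k], rep.recalibrated.coefficients[k])
            assert np.all(rep.final.coefficients[k] >= lo - 1e-12)
            assert np.all(rep.final.coefficients[k] <= hi + 1e-12)


class TestUpdatePipeline:
    def test_post_c_not_worse(self, truth3, cohort20k):
        cohort, _ = cohort20k
        rep = cv.update_pipeline(truth3, cohort)
        for k in truth3.nonreference:
            assert rep.post_c[k].estimate >= rep.pre_c[k].estimate - 0.01

    def test_gross_miscalibration_repaired(self, truth3, cohort50k):
        cohort, _ = cohort50k
        bad = truth3.replace_parameters(
            {k: 3.0 * v + 1.0 for k, v in truth3.intercepts.items()},
            {k: 3.0 * v for k, v in truth3.coefficients.items()},
        )
        rep = cv.update_pipeline(bad, cohort)
        for fit in rep.post_cal.values():
            assert fit.slope == pytest.approx(1.0, abs=0.15)
            assert abs(fit.intercept) < 1e-6

    def test_self_update_recovers_truth(self, truth3, cohort50k):
        """Updating the generating model is (nearly) a no-op, with gamma >= 0.95."""
        cohort, _ = cohort50k
        rep = cv.update_pipeline(truth3, cohort)
        assert rep.gamma >= 0.95
        for k in truth3.nonreference:
            assert np.allclose(rep.final.coefficients[k], truth3.coefficients[k], atol=0.15)
            assert np.allclose(rep.final.coefficients[k], rep.revised.coefficients[k], atol=0.05)

    def test_binomial_pipeline(self):
        """The identical machinery runs with K = 2."""
        truth = MultinomialCPM(
            name="bin", categories=["no_sbi", "sbi"], reference="no_sbi",
            terms=[Term("x1"), Term("x2")], intercepts={"sbi": -2.0},
            coefficients={"sbi": np.array([0.8, -0.4])},
        )
        cohort, _ = simple_cohort(truth, 10_000, seed=21)
        rep = cv.update_pipeline(truth, cohort)
        assert 0.0 <= rep.gamma <= 1.0
        assert abs(rep.post_cal["sbi"].intercept) < 1e-6


class TestNewtonSolver:
    def test_matches_closed_form_binary(self):
        """K = 2 with intercept-only design reproduces the empirical log-odds."""
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_multinomial(y, [np.ones((100, 1))])
        assert fit.params[0][0] == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert fit.loglik == pytest.approx(null_loglik(y, 2), abs=1e-8)

    def test_offset_shifts_solution(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_multinomial(y, [np.ones((100, 1))], offsets=[np.full(100, 0.5)])
        assert fit.params[0][0] == pytest.approx(np.log(30 / 70) - 0.5, abs=1e-8)

    def test_separation_raises_convergence_error(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])])
        with pytest.raises(ConvergenceError):
            fit_multinomial(y, [X], max_iter=200)
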