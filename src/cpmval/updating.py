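"""Three-stage model updating: recalibration, revision, heuristic shrinkage.

Given an existing prediction model and a new validation cohort, the
update proceeds in three stages:

1. **Logistic recalibration** — per outcome category k, the original
   linear predictor eta_k is rescaled as eta'_k = a_k + s_k * eta_k.
   (a_k, s_k) are estimated by maximum likelihood on the conditional
   contrast "category-k cases versus reference controls", the same
   contrast on which multinomial calibration is assessed, so the
   recalibrated model is exactly calibrated (a = 0, b = 1) on the
   updating cohort.  Relative predictor weights are untouched.

2. **Revision** — a full joint multinomial ML refit of the same terms,
   re-estimating every coefficient.  The fit's likelihood-ratio
   chi-square (against the intercept-only model) and its degrees of
   freedom (number of non-intercept coefficients) are recorded.

3. **Heuristic shrinkage** — revised coefficients are pulled uniformly
   towards the recalibrated ones with the heuristic shrinkage factor
   gamma = (chi2 - df) / chi2 (clamped to [0, 1]), counteracting
   overfitting to the updating data; intercepts are then re-estimated
   with the shrunken coefficients held fixed as offsets, again on the
   conditional contrasts, so every post-update calibration intercept is
   0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .calibration import CategoryCalibration, multinomial_calibration, _fit_logistic
from .discrimination import CStatResult, conditional_c_statistic
from .mnlogit import fit_multinomial, null_loglik
from .models import (
    MultinomialCPM,
    design_matrix,
    linear_predictors,
    predict_probabilities,
)

__all__ = [
    "UpdateReport",
    "recalibrate",
    "revise",
    "shrinkage_factor",
    "shrink_towards",
    "update_pipeline",
]


def _y_codes(model: MultinomialCPM, outcomes: np.ndarray) -> np.ndarray:
    """Outcome labels -> integer codes (0 = reference, j+1 = j-th non-reference)."""
    lut = {model.reference: 0}
    for j, k in enumerate(model.nonreference):
        lut[k] = j + 1
    unknown = sorted({o for o in np.unique(outcomes) if o not in lut})
    if unknown:
        raise ValueError(f"outcomes not among model categories: {unknown}")
    return np.array([lut[o] for o in outcomes], dtype=int)


def recalibrate(model: MultinomialCPM, cohort) -> MultinomialCPM:
    """Logistic recalibration: eta'_k = a_k + s_k * eta_k per category.

    Each (a_k, s_k) is the ML estimate from a binary logistic fit of
    "outcome == k" on eta_k, restricted to category-k cases and
    reference-category controls.  The returned model carries
    beta'_k = s_k * beta_k and alpha'_k = a_k + s_k * alpha_k.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    outcomes = np.asarray(df["outcome"])
    _y_codes(model, outcomes)  # validates category coverage
    eta = linear_predictors(model, cohort)
    new_int, new_coef = {}, {}
    for j, k in enumerate(model.nonreference):
        mask = (outcomes == k) | (outcomes == model.reference)
        y = (outcomes[mask] == k).astype(float)
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError(f"category {k!r} or the reference is absent from the cohort")
        X = sm.add_constant(eta[mask, j])
        res = _fit_logistic(y, X)
        a_k, s_k = float(res.params[0]), float(res.params[1])
        new_int[k] = a_k + s_k * model.intercepts[k]
        new_coef[k] = s_k * model.coefficients[k]
    return model.replace_parameters(new_int, new_coef, suffix=" (recalibrated)")


def _collinear_terms(X: np.ndarray, labels: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [labels[i] for i in range(len(labels)) if diag[i] <= tol]


def revise(model: MultinomialCPM, cohort) -> tuple[MultinomialCPM, float, int]:
    """Full multinomial ML refit of the model's terms on the cohort.

    Returns ``(revised_model, fit_chi2, df)`` where ``fit_chi2`` is the
    likelihood-ratio chi-square against the intercept-only model and
    ``df`` the number of estimated non-intercept coefficients.
    """
    df_tbl = cohort.df if hasattr(cohort, "df") else cohort
    outcomes = np.asarray(df_tbl["outcome"])
    y = _y_codes(model, outcomes)
    X = design_matrix(model, cohort)
    Xc = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    labels = ["(intercept)"] + [t.label for t in model.terms]
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient; collinear terms: {_collinear_terms(Xc, labels)}"
        )
    m = len(model.nonreference)
    fit = fit_multinomial(y, [Xc] * m)
    ll0 = null_loglik(y, len(model.categories))
    fit_chi2 = 2.0 * (fit.loglik - ll0)
    dof = m * X.shape[1]
    new_int = {k: float(fit.params[j][0]) for j, k in enumerate(model.nonreference)}
    new_coef = {k: fit.params[j][1:].copy() for j, k in enumerate(model.nonreference)}
    return model.replace_parameters(new_int, new_coef, suffix=" (revised)"), float(fit_chi2), int(dof)


def shrinkage_factor(fit_chi2: float, df: int) -> float:
    """Heuristic shrinkage factor gamma = (chi2 - df) / chi2, clamped to [0, 1]."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if fit_chi2 <= 0:
        warnings.warn("non-positive model chi-square; shrinkage factor set to 0", stacklevel=2)
        return 0.0
    return float(np.clip((fit_chi2 - df) / fit_chi2, 0.0, 1.0))


def shrink_towards(
    revised: MultinomialCPM, recalibrated: MultinomialCPM, gamma: float, cohort
) -> MultinomialCPM:
    """Convex combination of coefficient sets, then intercept re-estimation.

    Non-intercept coefficients become
    ``beta* = gamma * beta_revised + (1 - gamma) * beta_recalibrated``;
    each intercept is then re-estimated by maximum likelihood on the
    category-k-versus-reference contrast with ``x . beta*`` as a fixed
    offset, which makes every calibration intercept of the final model
    exactly 0 on the updating cohort.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if [t.label for t in revised.terms] != [t.label for t in recalibrated.terms] or list(
        revised.categories
    ) != list(recalibrated.categories):
        raise ValueError("revised and recalibrated models must share terms and categories")
    df_tbl = cohort.df if hasattr(cohort, "df") else cohort
    outcomes = np.asarray(df_tbl["outcome"])
    X = design_matrix(revised, cohort)
    new_int, new_coef = {}, {}
    for k in revised.nonreference:
        beta = gamma * revised.coefficients[k] + (1.0 - gamma) * recalibrated.coefficients[k]
        new_coef[k] = beta
        mask = (outcomes == k) | (outcomes == revised.reference)
        y = (outcomes[mask] == k).astype(float)
        offset = X[mask] @ beta
        res = _fit_logistic(y, np.ones((int(mask.sum()), 1)), offset=offset)
        new_int[k] = float(res.params[0])
    final = revised.replace_parameters(new_int, new_coef)
    final.name = revised.name.removesuffix(" (revised)") + " (updated)"
    return final


@dataclass
class UpdateReport:
    """All artefacts of one model update, plus before/after performance."""

    original: MultinomialCPM
    recalibrated: MultinomialCPM
    revised: MultinomialCPM
    final: MultinomialCPM
    gamma: float
    fit_chi2: float
    df: int
    pre_c: dict[str, CStatResult] = field(default_factory=dict)
    post_c: dict[str, CStatResult] = field(default_factory=dict)
    pre_cal: dict[str, CategoryCalibration] = field(default_factory=dict)
    post_cal: dict[str, CategoryCalibration] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from .models import model_to_dict

        def cstat(d):
            return {
                k: {
                    "estimate": v.estimate,
                    "ci_low": v.ci_low,
                    "ci_high": v.ci_high,
                    "n_cases": v.n_cases,
                    "n_controls": v.n_controls,
                }
                for k, v in d.items()
            }

        def cal(d):
            return {
                k: {
                    "intercept": v.intercept,
                    "intercept_ci": list(v.intercept_ci),
                    "slope": v.slope,
                    "slope_ci": list(v.slope_ci),
                    "n_used": v.n_used,
                    "degenerate": v.degenerate,
                }
                for k, v in d.items()
            }

        return {
            "gamma": self.gamma,
            "fit_chi2": self.fit_chi2,
            "df": self.df,
            "recalibrated": model_to_dict(self.recalibrated),
            "revised": model_to_dict(self.revised),
            "final": model_to_dict(self.final),
            "pre_c": cstat(self.pre_c),
            "post_c": cstat(self.post_c),
            "pre_calibration": cal(self.pre_cal),
            "post_calibration": cal(self.post_cal),
            "metadata": self.metadata,
        }


def update_pipeline(model: MultinomialCPM, cohort) -> UpdateReport:
    """Run recalibration, revision, shrinkage, and before/after assessment."""
    df_tbl = cohort.df if hasattr(cohort, "df") else cohort
    outcomes = np.asarray(df_tbl["outcome"])
    P_pre = predict_probabilities(model, cohort)
    pre_c = {k: conditional_c_statistic(P_pre, outcomes, k) for k in model.nonreference}
    pre_cal = multinomial_calibration(P_pre, outcomes)

    recal = recalibrate(model, cohort)
    revised, fit_chi2, dof = revise(model, cohort)
    gamma = shrinkage_factor(fit_chi2, dof)
    final = shrink_towards(revised, recal, gamma, cohort)

    P_post = predict_probabilities(final, cohort)
    post_c = {k: conditional_c_statistic(P_post, outcomes, k) for k in model.nonreference}
    post_cal = multinomial_calibration(P_post, outcomes)
    return UpdateReport(
        original=model,
        recalibrated=recal,
        revised=revised,
        final=final,
        gamma=gamma,
        fit_chi2=fit_chi2,
        df=dof,
        pre_c=pre_c,
        post_c=post_c,
        pre_cal=pre_cal,
        post_cal=post_cal,
        metadata={
            "calibration_variant": "conditional (category vs reference)",
            "intercept_reestimation": "sequential, per conditional contrast",
            "shrinkage": "uniform gamma from the revised fit's (chi2, df)",
        },
    )
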