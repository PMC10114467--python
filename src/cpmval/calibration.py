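"""Calibration intercepts, slopes, and flexible calibration curves.

For a predicted risk p and binary outcome y, the *calibration slope* b is
the coefficient of logit(p) in a logistic regression of y on logit(p);
the *calibration intercept* a is the intercept of a second logistic fit
in which logit(p) enters as a fixed offset (slope constrained to 1).
Perfect calibration gives a = 0, b = 1; a < 0 means risks are
overestimated overall, b < 1 means they are too extreme.

For a multinomial model, calibration is assessed per outcome category k
on the *conditional* contrast "category-k cases versus reference
controls" using the conditional risks P_k / (P_k + P_ref): each contrast
yields exactly one intercept and one slope, which is how validation
reports tabulate multinomial calibration.

The flexible calibration curve is a logistic fit of the outcome on a
restricted-cubic-spline basis of logit(p), evaluated on a risk grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .models import ProbabilityMatrix, conditional_risk

__all__ = [
    "CategoryCalibration",
    "CalibrationConvergenceError",
    "RISK_CLIP",
    "binary_calibration",
    "multinomial_calibration",
    "flexible_calibration_curve",
    "rcs_basis",
]

#: Risks are clipped to [RISK_CLIP, 1 - RISK_CLIP] before the logit to
#: guard saturated predictions.
RISK_CLIP = 1e-10

DEFAULT_KNOT_QUANTILES = (0.05, 0.275, 0.5, 0.725, 0.95)


class CalibrationConvergenceError(RuntimeError):
    """Logistic calibration fit failed (e.g. complete separation)."""


@dataclass(frozen=True)
class CategoryCalibration:
    """Calibration intercept/slope (with Wald 95% CIs) for one contrast."""

    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    n_used: int
    category: str = ""
    degenerate: bool = False
    curve: pd.DataFrame | None = field(default=None, compare=False)


def _logit_risks(risks: np.ndarray) -> np.ndarray:
    risks = np.asarray(risks, dtype=float)
    return logit(np.clip(risks, RISK_CLIP, 1.0 - RISK_CLIP))


def _fit_logistic(y: np.ndarray, X: np.ndarray, offset: np.ndarray | None = None):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit()
    except Exception as e:  # separation / non-convergence
        raise CalibrationConvergenceError(
            f"logistic calibration fit failed (n={len(y)}, events={int(y.sum())}): {e}"
        ) from e
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 1e3):
        raise CalibrationConvergenceError(
            f"calibration fit diverged: params={res.params}, events={int(y.sum())}"
        )
    return res


def binary_calibration(risks, outcomes, category: str = "", include_curve: bool = False) -> CategoryCalibration:
    """Calibration intercept and slope of predicted ``risks`` for binary ``outcomes``.

    The slope comes from the ML logistic fit ``y ~ logit(p)``; the
    intercept from a second fit with logit(p) as a fixed offset.  Both
    carry Wald 95% CIs.
    """
    y = np.asarray(outcomes).astype(float)
    L = _logit_risks(risks)
    if y.shape != L.shape:
        raise ValueError("risks and outcomes must have equal length")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if np.ptp(L) == 0.0:
        # constant predictions: the slope is unidentifiable, only
        # calibration-in-the-large remains meaningful
        b, b_ci = float("nan"), (float("nan"), float("nan"))
    else:
        slope_res = _fit_logistic(y, sm.add_constant(L))
        b = float(slope_res.params[1])
        b_ci = tuple(float(v) for v in slope_res.conf_int()[1])
    int_res = _fit_logistic(y, np.ones((len(y), 1)), offset=L)
    a = float(int_res.params[0])
    a_ci = tuple(float(v) for v in int_res.conf_int()[0])
    curve = None
    if include_curve and len(y) >= 50:
        try:
            curve = flexible_calibration_curve(np.asarray(risks, dtype=float), y)
        except CalibrationConvergenceError as e:
            warnings.warn(f"calibration curve omitted for {category or 'model'}: {e}", stacklevel=2)
    return CategoryCalibration(
        intercept=a,
        intercept_ci=a_ci,
        slope=b,
        slope_ci=b_ci,
        n_used=int(len(y)),
        category=category,
        curve=curve,
    )


def multinomial_calibration(
    P: ProbabilityMatrix, outcomes, include_curve: bool = False
) -> dict[str, CategoryCalibration]:
    """Per-category conditional calibration of a multinomial model.

    For every non-reference category k the cohort is restricted to
    category-k cases and reference-category controls and
    :func:`binary_calibration` is applied to the conditional risks.  An
    absent category yields a degenerate placeholder; the remaining
    categories are still computed.
    """
    outcomes = np.asarray(outcomes)
    out: dict[str, CategoryCalibration] = {}
    for k in P.categories:
        if k == P.reference:
            continue
        mask = (outcomes == k) | (outcomes == P.reference)
        y = (outcomes[mask] == k).astype(float)
        if y.sum() == 0 or y.sum() == y.size:
            out[k] = CategoryCalibration(
                intercept=float("nan"),
                intercept_ci=(float("nan"), float("nan")),
                slope=float("nan"),
                slope_ci=(float("nan"), float("nan")),
                n_used=int(mask.sum()),
                category=k,
                degenerate=True,
            )
            continue
        r = conditional_risk(P, k)[mask]
        defined = ~np.isnan(r)
        if (~defined).any():
            warnings.warn(
                f"category {k!r}: dropped {int((~defined).sum())} undefined conditional risks",
                stacklevel=2,
            )
        out[k] = binary_calibration(r[defined], y[defined], category=k, include_curve=include_curve)
    return out


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term + k-2 nonlinear terms.

    Truncated-power construction, linear beyond the boundary knots,
    normalised by the squared knot span.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(x - tj)
            - cube(x - tk1) * (tk - tj) / (tk - tk1)
            + cube(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def flexible_calibration_curve(risks, outcomes, grid=None, n_grid: int = 100) -> pd.DataFrame:
    """Smooth observed-rate estimate as a function of predicted risk.

    Fits a logistic model of the outcome on a restricted-cubic-spline
    basis (5 knots at the 5/27.5/50/72.5/95th percentiles) of logit(risk)
    and evaluates it on ``grid`` (default: 100 equally spaced points from
    the 1st to the 99th percentile of the predicted risks).  Returns a
    frame with columns predicted, observed, lower, upper, extrapolated;
    grid points outside the observed risk range are flagged.
    """
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes).astype(float)
    if len(risks) < 50:
        raise ValueError("flexible calibration curve needs n >= 50")
    L = _logit_risks(risks)
    # events limit the supportable flexibility: 5 knots need ~50 events
    m = int(min(y.sum(), len(y) - y.sum()))
    if m >= 50:
        quantiles = DEFAULT_KNOT_QUANTILES
    elif m >= 20:
        quantiles = (0.1, 0.5, 0.9)
    else:
        quantiles = ()  # linear (logistic-recalibration) curve only
    knots = np.unique(np.quantile(L, quantiles)) if quantiles else np.array([])
    if grid is None:
        grid = np.linspace(np.quantile(risks, 0.01), np.quantile(risks, 0.99), n_grid)
    grid = np.asarray(grid, dtype=float)
    Lg = _logit_risks(grid)
    if np.ptp(L) == 0.0:
        # constant predictions: flat curve at the observed event rate
        B, Bg = np.ones((len(y), 1)), np.ones((len(grid), 1))
    elif len(knots) < 3:
        B = sm.add_constant(L)
        Bg = np.column_stack([np.ones(len(grid)), Lg])
    else:
        B = sm.add_constant(rcs_basis(L, knots))
        Bg = np.column_stack([np.ones(len(grid)), rcs_basis(Lg, knots)])
    res = _fit_logistic(y, B)
    eta = Bg @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Bg, res.cov_params(), Bg))
    extrapolated = (grid < risks.min()) | (grid > risks.max())
    return pd.DataFrame(
        {
            "predicted": grid,
            "observed": expit(eta),
            "lower": expit(eta - 1.959963984540054 * se),
            "upper": expit(eta + 1.959963984540054 * se),
            "extrapolated": extrapolated,
        }
    )
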