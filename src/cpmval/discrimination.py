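"""Concordance statistics (AUC) with DeLong confidence intervals.

The C-statistic is the Mann-Whitney concordance probability: the chance
that a randomly chosen case receives a higher score than a randomly
chosen control, ties counting one half.  For a K-category model the
*conditional pairwise* C-statistic of category k restricts the cohort to
category-k cases and reference-category controls and scores records by
the conditional risk P_k / (P_k + P_ref).

Confidence intervals use DeLong's placement-value variance, computed on
the logit scale and back-transformed so the bounds stay inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .models import ProbabilityMatrix, conditional_risk

__all__ = ["CStatResult", "DegenerateInputError", "c_statistic", "conditional_c_statistic"]


class DegenerateInputError(ValueError):
    """Scores/labels cannot support a concordance estimate (single class)."""


@dataclass(frozen=True)
class CStatResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    method: str = "delong-logit"
    n_dropped: int = 0

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("CI does not contain the estimate")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong placement values (midrank algorithm)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    n1, n0 = len(cases), len(controls)
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:n1] - case_ranks) / n0  # P(case_i beats a control)
    v01 = 1.0 - (all_ranks[n1:] - control_ranks) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def c_statistic(scores, labels) -> CStatResult:
    """Concordance probability of ``scores`` for binary ``labels``.

    Equals the area under the ROC curve; ties contribute 1/2.  Requires
    at least one case and one control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN; drop undefined records first")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError(f"need both classes: {n1} cases, {n0} controls")
    auc, v10, v01 = _delong_placements(scores, labels)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.975)
    if se == 0.0 or auc <= 0.0 or auc >= 1.0:
        # degenerate variance (e.g. perfect separation): collapse the CI
        lo = hi = auc if se == 0.0 else None
        if lo is None:
            lo, hi = max(auc - z * se, 0.0), min(auc + z * se, 1.0)
    else:
        se_logit = se / (auc * (1.0 - auc))
        lo = float(expit(logit(auc) - z * se_logit))
        hi = float(expit(logit(auc) + z * se_logit))
    return CStatResult(
        estimate=auc,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        n_cases=n1,
        n_controls=n0,
    )


def conditional_c_statistic(P: ProbabilityMatrix, outcomes, category: str) -> CStatResult:
    """C-statistic of category ``category`` versus the reference outcome.

    Cases are records whose outcome equals ``category``; controls are
    records with the reference outcome; all other records are ignored.
    Scores are the conditional risks; records with an undefined (0/0)
    conditional risk are dropped with a warning and counted in
    ``n_dropped``.
    """
    outcomes = np.asarray(outcomes)
    mask = (outcomes == category) | (outcomes == P.reference)
    n_case = int((outcomes == category).sum())
    n_ctrl = int((outcomes == P.reference).sum())
    if n_case == 0 or n_ctrl == 0:
        raise DegenerateInputError(
            f"category {category!r}: {n_case} cases, {n_ctrl} reference controls"
        )
    r = conditional_risk(P, category)[mask]
    y = (outcomes[mask] == category).astype(int)
    defined = ~np.isnan(r)
    n_dropped = int((~defined).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} records with undefined (0/0) conditional risk", stacklevel=2
        )
    res = c_statistic(r[defined], y[defined])
    return CStatResult(
        estimate=res.estimate,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        n_cases=res.n_cases,
        n_controls=res.n_controls,
        method=res.method,
        n_dropped=n_dropped,
    )
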