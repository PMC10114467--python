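"""Threshold-based diagnostic accuracy: 2x2 tables, sens/spec, likelihood ratios.

Dichotomising a predicted risk or a point score at a clinical cut-off
yields a 2x2 table against the outcome.  Sensitivity and specificity get
Wilson score 95% intervals (well-behaved at the 0 and 1 boundaries that
degenerate tables produce); likelihood ratios get log-transform
intervals, with a 0.5 continuity correction only when a cell is zero but
the ratio is still defined.  Undefined ratios (zero denominators) are
flagged rather than raised and print as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ContingencyTable", "AccuracyStats", "contingency", "diagnostic_stats"]

_Z = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of test result (rows) against outcome (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float | int = float("nan")
    direction: str = ">="

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyStats:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_pos: float | None  # None encodes the undefined ("NA") case
    lr_pos_ci: tuple[float, float] | None
    lr_neg: float | None
    lr_neg_ci: tuple[float, float] | None


_OPS = {
    ">=": np.greater_equal,
    ">": np.greater,
    "<=": np.less_equal,
    "<": np.less,
}


def contingency(values, labels, threshold, direction: str = ">=") -> ContingencyTable:
    """Cross-classify test positivity (``value <direction> threshold``) by outcome."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if values.size == 0:
        raise ValueError("empty input")
    if np.isnan(values).any():
        raise ValueError("values contain missing entries")
    if direction not in _OPS:
        raise ValueError(f"direction must be one of {sorted(_OPS)}")
    pos = _OPS[direction](values, threshold)
    return ContingencyTable(
        tp=int((pos & (labels == 1)).sum()),
        fp=int((pos & (labels == 0)).sum()),
        fn=int((~pos & (labels == 1)).sum()),
        tn=int((~pos & (labels == 0)).sum()),
        threshold=threshold,
        direction=direction,
    )


def _lr_ci(num_events: int, num_total: int, den_events: int, den_total: int, lr: float):
    """Log-method CI for a ratio of two proportions; 0.5 correction on zero cells."""
    a, b = num_events, num_total - num_events
    c, d = den_events, den_total - den_events
    if lr == 0.0 or any(x == 0 for x in (a, c)):
        # continuity correction keeps the interval defined when one cell is 0
        a_, c_ = a + 0.5, c + 0.5
        m_, n_ = num_total + 0.5, den_total + 0.5
        lr_c = (a_ / m_) / (c_ / n_)
        se = math.sqrt(1.0 / a_ - 1.0 / m_ + 1.0 / c_ - 1.0 / n_)
        lo, hi = lr_c * math.exp(-_Z * se), lr_c * math.exp(_Z * se)
        if lr == 0.0:
            lo = 0.0
        return (lo, hi)
    se = math.sqrt(1.0 / a - 1.0 / num_total + 1.0 / c - 1.0 / den_total)
    return (lr * math.exp(-_Z * se), lr * math.exp(_Z * se))


def diagnostic_stats(t: ContingencyTable) -> AccuracyStats:
    """Sensitivity, specificity (Wilson 95% CIs) and likelihood ratios.

    ``LR+ = sens / (1 - spec)`` and ``LR- = (1 - sens) / spec``; a zero
    denominator yields ``None`` (reported as "NA").  Degenerate tables are
    flagged, never raised.
    """
    n_dis = t.tp + t.fn
    n_ctl = t.tn + t.fp
    sens = t.tp / n_dis if n_dis else float("nan")
    spec = t.tn / n_ctl if n_ctl else float("nan")
    sens_ci = (
        tuple(float(v) for v in proportion_confint(t.tp, n_dis, alpha=0.05, method="wilson"))
        if n_dis
        else (float("nan"), float("nan"))
    )
    spec_ci = (
        tuple(float(v) for v in proportion_confint(t.tn, n_ctl, alpha=0.05, method="wilson"))
        if n_ctl
        else (float("nan"), float("nan"))
    )
    lr_pos = lr_pos_ci = lr_neg = lr_neg_ci = None
    if n_dis and n_ctl:
        if spec < 1.0:
            lr_pos = sens / (1.0 - spec)
            lr_pos_ci = _lr_ci(t.tp, n_dis, t.fp, n_ctl, lr_pos)
        if spec > 0.0:
            lr_neg = (1.0 - sens) / spec
            lr_neg_ci = _lr_ci(t.fn, n_dis, t.tn, n_ctl, lr_neg)
    return AccuracyStats(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        lr_pos=lr_pos,
        lr_pos_ci=lr_pos_ci,
        lr_neg=lr_neg,
        lr_neg_ci=lr_neg_ci,
    )
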