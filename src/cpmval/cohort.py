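"""Cohort ingestion, eligibility filtering, imputation and subsets.

A cohort is a rectangular table of acutely ill children (one row per
child) with predictor columns, an ``outcome`` label, ``age`` in years,
``sex`` and a care ``setting``.  The analysis flow mirrors a prospective
ambulatory-care validation study:

1. load the raw CSV, resolving alias column names against the schema;
2. exclude records missing an *essential* field (outcome, age, sex,
   temperature) and records outside the study age range, with full flow
   accounting;
3. single imputation of remaining missing findings with their
   "non-deviant" (normal) value — the assumption being that a normal
   finding is less likely to be written down for a well-appearing child;
4. analysis subsets: serious-bacterial-infection analyses exclude
   gastro-enteritis records because viral and bacterial gastro-enteritis
   cannot be told apart at adjudication.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .schema import PredictorSchema

__all__ = [
    "Cohort",
    "FlowCounts",
    "ESSENTIAL_FIELDS",
    "SBI_CATEGORIES",
    "SI_CATEGORIES",
    "REFERENCE_CATEGORY",
    "GASTRO_CATEGORY",
    "load_cohort",
    "eligibility_filter",
    "impute_non_deviant",
    "sbi_analysis_subset",
    "prevalence",
    "subgroup",
]

ESSENTIAL_FIELDS = ("outcome", "age", "sex", "temperature")
REFERENCE_CATEGORY = "no_si"
GASTRO_CATEGORY = "gastroenteritis_dehydration"

#: Serious bacterial infections (hospital admission > 24 h).
SBI_CATEGORIES = (
    "abscess_cellulitis",
    "appendicitis",
    "cuti",
    "meningitis",
    "osteomyelitis",
    "pneumonia",
    "sepsis_bacteraemia",
)

#: Serious infections: SBI plus the two serious non-bacterial conditions.
SI_CATEGORIES = SBI_CATEGORIES + (GASTRO_CATEGORY, "viral_rti_hypoxia")

MISSING_TOKENS = ("", "NA")


@dataclass
class Cohort:
    """A patient table plus its predictor schema."""

    df: pd.DataFrame
    schema: PredictorSchema | None = None

    def __len__(self):
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "Cohort":
        return replace(self, df=df)


@dataclass(frozen=True)
class FlowCounts:
    """Participant-flow accounting; conservation is asserted on construction."""

    enrolled: int
    excluded_missing_essential: int
    excluded_age: int
    analyzed: int

    def __post_init__(self):
        if self.analyzed != self.enrolled - self.excluded_missing_essential - self.excluded_age:
            raise ValueError(
                "flow not conserved: "
                f"{self.enrolled} != {self.analyzed} + {self.excluded_missing_essential} + {self.excluded_age}"
            )


def load_cohort(path, schema: PredictorSchema | None = None) -> Cohort:
    """Read a cohort CSV (UTF-8, header row; '' and 'NA' are missing).

    Columns are alias-resolved against the schema; columns neither in the
    schema nor structural (outcome/age/sex/setting/temperature) are kept
    but flagged with a warning.  Numeric schema columns are coerced; a
    malformed cell raises with the row and column named.
    """
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False, encoding="utf-8")
    if schema is not None:
        df = df.rename(columns=schema.resolve_aliases(list(df.columns)))
        structural = set(ESSENTIAL_FIELDS) | {"setting"}
        unknown = [c for c in df.columns if c not in schema.names and c not in structural]
        if unknown:
            import warnings

            warnings.warn(f"columns not in schema (kept as-is): {unknown}", stacklevel=2)
        for var in schema:
            if var.name in df.columns and var.kind in ("binary", "continuous"):
                coerced = pd.to_numeric(df[var.name], errors="coerce")
                bad = coerced.isna() & df[var.name].notna()
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValueError(
                        f"malformed numeric value {df[var.name].iloc[i]!r} in column "
                        f"{var.name!r}, row {i}"
                    )
                df[var.name] = coerced
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "temperature" in df.columns:
        df["temperature"] = pd.to_numeric(df["temperature"], errors="coerce")
    return Cohort(df=df.reset_index(drop=True), schema=schema)


def eligibility_filter(
    cohort: Cohort, age_range: tuple[float, float] = (1.0 / 12.0, 16.0)
) -> tuple[Cohort, FlowCounts]:
    """Apply the study's eligibility rules with flow accounting.

    A record missing any essential field (outcome, age, sex, temperature)
    is excluded first; among the remainder, records outside ``age_range``
    (inclusive at both ends) are excluded.  A record failing both rules is
    counted once, under the first rule.
    """
    df = cohort.df
    enrolled = len(df)
    present = [c for c in ESSENTIAL_FIELDS if c in df.columns]
    missing_essential = df[present].isna().any(axis=1) if present else pd.Series(False, index=df.index)
    lo, hi = age_range
    age = pd.to_numeric(df["age"], errors="coerce") if "age" in df.columns else pd.Series(np.nan, index=df.index)
    age_out = (~missing_essential) & ((age < lo) | (age > hi))
    keep = ~missing_essential & ~age_out
    flow = FlowCounts(
        enrolled=enrolled,
        excluded_missing_essential=int(missing_essential.sum()),
        excluded_age=int(age_out.sum()),
        analyzed=int(keep.sum()),
    )
    return cohort.with_df(df.loc[keep].reset_index(drop=True)), flow


def impute_non_deviant(cohort: Cohort, schema: PredictorSchema | None = None) -> Cohort:
    """Replace missing non-essential findings by their non-deviant default.

    Essential fields are untouched (eligibility guarantees them present).
    A schema variable with missing values but no declared default is an
    error listing all such variables.
    """
    schema = schema if schema is not None else cohort.schema
    if schema is None:
        raise ValueError("impute_non_deviant needs a predictor schema")
    df = cohort.df.copy()
    undefaulted = []
    for var in schema:
        if var.name not in df.columns or var.name in ESSENTIAL_FIELDS:
            continue
        n_missing = int(df[var.name].isna().sum())
        if n_missing == 0:
            continue
        if var.non_deviant_default is None:
            undefaulted.append(var.name)
            continue
        df[var.name] = df[var.name].fillna(var.non_deviant_default)
    if undefaulted:
        raise ValueError(f"missing values with no non-deviant default: {undefaulted}")
    return cohort.with_df(df)


def sbi_analysis_subset(cohort: Cohort, gastro_category: str = GASTRO_CATEGORY) -> Cohort:
    """Drop gastro-enteritis records (viral vs bacterial not adjudicable)."""
    df = cohort.df
    keep = df["outcome"] != gastro_category
    out = cohort.with_df(df.loc[keep].reset_index(drop=True))
    if len(out) == 0:
        import warnings

        warnings.warn("SBI analysis subset is empty", stacklevel=2)
    return out


def prevalence(cohort: Cohort, outcome_set: Iterable[str]) -> dict:
    """Proportion of the cohort whose outcome is in ``outcome_set``.

    Returns count, n, the proportion, a Wilson-score 95% CI, and the
    percentage rounded to one decimal for reporting.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("prevalence of an empty cohort is undefined")
    outcome_set = set(outcome_set)
    count = int(cohort.df["outcome"].isin(outcome_set).sum())
    p = count / n
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    return {
        "count": count,
        "n": n,
        "proportion": p,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "percent": round(100.0 * p, 1),
    }


def subgroup(
    cohort: Cohort,
    setting: str | None = None,
    age_min: float | None = None,
    age_max: float | None = None,
) -> Cohort:
    """Pure row filter by care setting and/or age (bounds inclusive)."""
    df = cohort.df
    keep = pd.Series(True, index=df.index)
    if setting is not None:
        keep &= df["setting"] == setting
    if age_min is not None:
        keep &= df["age"] >= age_min
    if age_max is not None:
        keep &= df["age"] <= age_max
    out = cohort.with_df(df.loc[keep].reset_index(drop=True))
    if len(out) == 0:
        import warnings

        warnings.warn("subgroup filter matched no records", stacklevel=2)
    return out
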