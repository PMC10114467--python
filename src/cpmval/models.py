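"""Clinical prediction model representations.

Two families of models are represented generically:

* :class:`MultinomialCPM` — a K-category multinomial logistic model
  (K = 2 gives the binomial special case).  Per non-reference category k
  the model stores an intercept ``alpha_k`` and a coefficient vector
  ``beta_k`` over a shared list of model *terms*; the reference category
  ("absence of serious bacterial infection") has linear predictor
  identically zero.  Category probabilities follow from the softmax link,
  and the *conditional risk* of category k is
  ``P_k / (P_k + P_ref)`` — the pairwise risk of disease k versus the
  reference outcome.

* :class:`RiskScoreDef` — an additive point score whose items are either
  per-level point tables or age-banded lookups on vital signs, with named
  decision cut-offs.

Terms support four declarative transformations: ``identity``, natural
``log`` (for right-skewed predictors such as CRP), ``indicator`` (one
categorical level) and ``banded`` (age-dependent interval lookup on a
vital sign).  Anything else must be precomputed into the cohort, keeping
model-definition files declarative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import PredictorSchema, SchemaError

__all__ = [
    "Term",
    "MultinomialCPM",
    "RiskScoreDef",
    "ProbabilityMatrix",
    "RangeError",
    "BandingError",
    "linear_predictors",
    "predict_probabilities",
    "conditional_risk",
    "apply_risk_score",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
]

TRANSFORMS = ("identity", "log", "indicator", "banded")


class RangeError(ValueError):
    """A predictor value lies outside its schema-declared allowed range."""


class BandingError(ValueError):
    """A record's age falls outside every declared age band."""


@dataclass(frozen=True)
class Term:
    """One model term: a variable plus a declarative transformation.

    ``level`` applies to ``indicator`` terms; ``bands`` applies to
    ``banded`` terms and is a tuple of dicts
    ``{"age": [lo, hi], "value": [lo, hi], "output": x}`` — the term
    evaluates to ``output`` for the first rule whose age band (half-open,
    last band closed) and value interval match, else 0.
    """

    variable: str
    transform: str = "identity"
    level: object = None
    bands: tuple = ()

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "indicator" and self.level is None:
            raise ValueError(f"indicator term on {self.variable!r} needs a level")
        if self.transform == "banded" and not self.bands:
            raise ValueError(f"banded term on {self.variable!r} needs bands")
        if self.bands:
            object.__setattr__(
                self, "bands", tuple(dict(b) if not isinstance(b, dict) else b for b in self.bands)
            )

    @property
    def label(self) -> str:
        if self.transform == "identity":
            return self.variable
        if self.transform == "log":
            return f"log({self.variable})"
        if self.transform == "indicator":
            return f"{self.variable}=={self.level}"
        return f"banded({self.variable})"


def _in_band(age: np.ndarray, lo: float, hi: float, is_last: bool) -> np.ndarray:
    # half-open [lo, hi); the last band also accepts age == hi
    return (age >= lo) & ((age <= hi) if is_last else (age < hi))


def _eval_banded(bands: tuple, age: np.ndarray, values: np.ndarray, variable: str) -> np.ndarray:
    out = np.zeros(len(age))
    matched_age = np.zeros(len(age), dtype=bool)
    done = np.zeros(len(age), dtype=bool)
    hi_all = max(b["age"][1] for b in bands)
    for b in bands:
        lo, hi = b["age"]
        in_age = _in_band(age, lo, hi, is_last=(hi == hi_all))
        matched_age |= in_age
        vlo, vhi = b.get("value", (-math.inf, math.inf))
        hit = in_age & ~done & (values >= vlo) & (values < vhi)
        out[hit] = b.get("output", 1.0)
        done |= hit
    if not matched_age.all():
        i = int(np.flatnonzero(~matched_age)[0])
        raise BandingError(
            f"record {i}: age {age[i]:g} outside all declared bands of banded({variable})"
        )
    return out


@dataclass
class MultinomialCPM:
    """A K-category logistic prediction model with a fixed reference category.

    ``coefficients[k]`` is the beta vector of non-reference category k over
    ``terms`` (same order); ``intercepts[k]`` its alpha.  The reference
    category carries no parameters.
    """

    name: str
    categories: list[str]
    reference: str
    terms: list[Term]
    intercepts: dict[str, float]
    coefficients: dict[str, np.ndarray]
    provenance: str = ""
    schema: PredictorSchema | None = None

    def __post_init__(self):
        if self.reference not in self.categories:
            raise ValueError(f"reference {self.reference!r} not among categories")
        if len(self.categories) < 2:
            raise ValueError("a prediction model needs K >= 2 outcome categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate outcome categories")
        for k in self.nonreference:
            if k not in self.intercepts:
                raise ValueError(f"missing intercept for category {k!r}")
            beta = np.asarray(self.coefficients.get(k, np.zeros(len(self.terms))), dtype=float)
            if beta.shape != (len(self.terms),):
                raise ValueError(
                    f"category {k!r}: {beta.size} coefficients for {len(self.terms)} terms"
                )
            self.coefficients[k] = beta
        if self.reference in self.intercepts or self.reference in self.coefficients:
            raise ValueError("reference category must not carry parameters")
        if self.schema is not None:
            for t in self.terms:
                if t.variable not in self.schema:
                    raise SchemaError(f"term variable {t.variable!r} not in schema")

    @property
    def nonreference(self) -> list[str]:
        return [c for c in self.categories if c != self.reference]

    @property
    def is_binomial(self) -> bool:
        return len(self.categories) == 2

    def replace_parameters(
        self, intercepts: dict[str, float], coefficients: dict[str, np.ndarray], suffix: str = ""
    ) -> "MultinomialCPM":
        return MultinomialCPM(
            name=self.name + suffix,
            categories=list(self.categories),
            reference=self.reference,
            terms=list(self.terms),
            intercepts={k: float(v) for k, v in intercepts.items()},
            coefficients={k: np.asarray(v, dtype=float).copy() for k, v in coefficients.items()},
            provenance=self.provenance,
            schema=self.schema,
        )


class ProbabilityMatrix:
    """n x K matrix of category probabilities; rows sum to 1 within 1e-9."""

    def __init__(self, values: np.ndarray, categories: list[str], reference: str):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(categories):
            raise ValueError("probability matrix shape does not match categories")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite probabilities")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        rowsum = values.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("probability rows do not sum to 1 within 1e-9")
        self.values = values
        self.categories = list(categories)
        self.reference = reference

    def __len__(self):
        return self.values.shape[0]

    def column(self, category: str) -> np.ndarray:
        return self.values[:, self.categories.index(category)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.categories)


def _df_of(cohort) -> pd.DataFrame:
    return cohort.df if hasattr(cohort, "df") else cohort


def design_matrix(model: MultinomialCPM, cohort) -> np.ndarray:
    """n x p matrix of transformed term values (no intercept column)."""
    df = _df_of(cohort)
    schema = model.schema
    amap = schema.alias_map() if schema is not None else {}
    cols = []
    for t in model.terms:
        col = t.variable
        if col not in df.columns:
            for alias, canon in amap.items():
                if canon == t.variable and alias in df.columns:
                    col = alias
                    break
        if col not in df.columns:
            raise SchemaError(f"variable {t.variable!r} not resolvable in cohort columns")
        raw = df[col]
        if raw.isna().any():
            raise ValueError(
                f"column {t.variable!r} has {int(raw.isna().sum())} missing values; impute first"
            )
        if schema is not None and t.variable in schema:
            var = schema[t.variable]
            if var.allowed_range is not None and var.kind != "categorical":
                vals = pd.to_numeric(raw, errors="coerce")
                lo, hi = var.allowed_range
                bad = (vals < lo) | (vals > hi) | vals.isna()
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise RangeError(
                        f"{t.variable!r} value {raw.iloc[i]!r} (row {i}) outside allowed range [{lo}, {hi}]"
                    )
        if t.transform == "identity":
            cols.append(raw.to_numpy(dtype=float))
        elif t.transform == "log":
            vals = raw.to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise RangeError(f"log transform of {t.variable!r}: non-positive values present")
            cols.append(np.log(vals))
        elif t.transform == "indicator":
            cols.append((raw == t.level).to_numpy(dtype=float))
        else:  # banded
            if "age" not in df.columns:
                raise SchemaError(f"banded term on {t.variable!r} requires an 'age' column")
            cols.append(
                _eval_banded(
                    t.bands,
                    df["age"].to_numpy(dtype=float),
                    raw.to_numpy(dtype=float),
                    t.variable,
                )
            )
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def linear_predictors(model: MultinomialCPM, cohort) -> np.ndarray:
    """n x (K-1) matrix of linear predictors eta_k = alpha_k + beta_k . x.

    Columns follow ``model.nonreference`` order; the reference category's
    (implicit) linear predictor is identically 0.
    """
    X = design_matrix(model, cohort)
    eta = np.empty((X.shape[0], len(model.nonreference)))
    for j, k in enumerate(model.nonreference):
        eta[:, j] = model.intercepts[k] + X @ model.coefficients[k]
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return eta


def softmax_probabilities(eta: np.ndarray, categories: list[str], reference: str) -> ProbabilityMatrix:
    """Softmax with the reference category's eta fixed at 0; stable for |eta| up to ~700."""
    nonref = [c for c in categories if c != reference]
    if eta.shape[1] != len(nonref):
        raise ValueError("eta width does not match non-reference categories")
    full = np.zeros((eta.shape[0], len(categories)))
    for j, k in enumerate(nonref):
        full[:, categories.index(k)] = eta[:, j]
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    P = ex / ex.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(P, categories, reference)


def predict_probabilities(model: MultinomialCPM, cohort) -> ProbabilityMatrix:
    """Category probabilities P_ik = exp(eta_ik) / sum_j exp(eta_ij), eta_ref = 0."""
    eta = linear_predictors(model, cohort)
    return softmax_probabilities(eta, model.categories, model.reference)


def conditional_risk(P: ProbabilityMatrix, category: str) -> np.ndarray:
    """Pairwise risk of ``category`` versus the reference: P_k / (P_k + P_ref).

    Records where both probabilities are exactly 0 get NaN (undefined) and
    are expected to be dropped, with a count, by downstream statistics.
    """
    if category == P.reference:
        raise ValueError("conditional risk of the reference category is undefined by construction")
    pk = P.column(category)
    pref = P.column(P.reference)
    denom = pk + pref
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, pk / np.where(denom > 0, denom, 1.0), np.nan)
    return r


# ---------------------------------------------------------------------------
# Additive risk scores


def _check_intervals(intervals, where: str):
    ivs = sorted((float(iv["value"][0]), float(iv["value"][1])) for iv in intervals)
    for (alo, ahi), (blo, bhi) in zip(ivs, ivs[1:]):
        if blo < ahi:
            raise ValueError(f"{where}: overlapping value intervals [{alo},{ahi}) and [{blo},{bhi})")


@dataclass
class RiskScoreDef:
    """An additive point score with optional age-banded items.

    ``items`` entries are dicts of one of two shapes::

        {"variable": v, "points": {"level": pts, ...}}          # per-level
        {"variable": v, "bands": [{"age": [lo, hi],
                                   "intervals": [{"value": [lo, hi],
                                                  "points": p}, ...]}, ...]}

    Age bands are half-open ``[lo, hi)`` (the last band is closed), must be
    disjoint, and must cover ``age_range``.  Value intervals within a band
    are half-open and disjoint; an unmatched value scores 0 points.
    ``cutoffs`` are dicts ``{"name", "op", "value"}`` with op in
    {"<=", "<", ">=", ">"}.
    """

    name: str
    items: list[dict]
    cutoffs: list[dict] = field(default_factory=list)
    age_range: tuple = (1.0 / 12.0, 16.0)
    age_band_unit: str = "years"
    provenance: str = ""
    schema: PredictorSchema | None = None

    def __post_init__(self):
        if self.age_band_unit not in ("years", "months"):
            raise ValueError("age_band_unit must be 'years' or 'months'")
        lo_r, hi_r = (float(a) for a in self.age_range)
        for item in self.items:
            v = item["variable"]
            if "points" in item:
                for lev, p in item["points"].items():
                    if int(p) != p or p < 0:
                        raise ValueError(f"item {v!r}: points must be non-negative integers")
            elif "bands" in item:
                bands = sorted(item["bands"], key=lambda b: b["age"][0])
                for (a, b) in zip(bands, bands[1:]):
                    if b["age"][0] < a["age"][1]:
                        raise ValueError(f"item {v!r}: overlapping age bands")
                    if b["age"][0] > a["age"][1]:
                        raise ValueError(f"item {v!r}: gap in age bands at {a['age'][1]}")
                if bands[0]["age"][0] > lo_r or bands[-1]["age"][1] < hi_r:
                    raise ValueError(f"item {v!r}: age bands do not cover declared age range")
                for b in bands:
                    _check_intervals(b["intervals"], f"item {v!r} band {b['age']}")
                    for iv in b["intervals"]:
                        p = iv["points"]
                        if int(p) != p or p < 0:
                            raise ValueError(f"item {v!r}: points must be non-negative integers")
            else:
                raise ValueError(f"item {v!r}: needs 'points' or 'bands'")
        ops = {"<=", "<", ">=", ">"}
        for c in self.cutoffs:
            if c.get("op") not in ops:
                raise ValueError(f"cutoff {c.get('name')!r}: op must be one of {sorted(ops)}")

    def cutoff(self, name: str) -> dict:
        for c in self.cutoffs:
            if c["name"] == name:
                return c
        raise KeyError(name)


def apply_risk_score(score: RiskScoreDef, cohort) -> np.ndarray:
    """Total points per record (integer vector).

    Imputed (non-deviant) values simply score whatever their band/level
    awards — typically 0 points by construction of a normal value.
    """
    df = _df_of(cohort)
    n = len(df)
    total = np.zeros(n, dtype=int)
    age = None
    if any("bands" in item for item in score.items):
        if "age" not in df.columns:
            raise SchemaError("age-banded score requires an 'age' column")
        age = df["age"].to_numpy(dtype=float)
        if score.age_band_unit == "months":
            age = age * 12.0
    for item in score.items:
        v = item["variable"]
        if v not in df.columns:
            raise SchemaError(f"score variable {v!r} not in cohort")
        col = df[v]
        if col.isna().any():
            raise ValueError(f"score variable {v!r} has missing values; impute first")
        if "points" in item:
            tbl = item["points"]

            def lookup(x, tbl=tbl):
                # JSON object keys are strings; accept 1, 1.0 and "1" alike
                if x in tbl:
                    return tbl[x]
                if str(x) in tbl:
                    return tbl[str(x)]
                try:
                    xi = int(float(x))
                    if float(x) == xi and str(xi) in tbl:
                        return tbl[str(xi)]
                except (TypeError, ValueError):
                    pass
                return 0

            total += col.map(lookup).to_numpy(dtype=int)
        else:
            vals = col.to_numpy(dtype=float)
            bands = sorted(item["bands"], key=lambda b: b["age"][0])
            hi_all = bands[-1]["age"][1]
            matched = np.zeros(n, dtype=bool)
            pts = np.zeros(n, dtype=int)
            for b in bands:
                lo, hi = b["age"]
                in_age = _in_band(age, lo, hi, is_last=(hi == hi_all))
                matched |= in_age
                for iv in b["intervals"]:
                    vlo, vhi = iv["value"]
                    pts[in_age & (vals >= vlo) & (vals < vhi)] = int(iv["points"])
            if not matched.all():
                i = int(np.flatnonzero(~matched)[0])
                raise BandingError(f"record {i}: age outside declared bands of item {v!r}")
            total += pts
    return total


# ---------------------------------------------------------------------------
# Model-definition files (JSON).  Round-trip read/write is lossless.


def model_to_dict(model) -> dict:
    if isinstance(model, RiskScoreDef):
        return {
            "name": model.name,
            "type": "risk_score",
            "provenance": model.provenance,
            "age_range": list(model.age_range),
            "age_band_unit": model.age_band_unit,
            "items": model.items,
            "cutoffs": model.cutoffs,
            "schema_ref": model.schema.to_dict() if model.schema is not None else None,
        }
    d = {
        "name": model.name,
        "type": "binomial" if model.is_binomial else "multinomial",
        "provenance": model.provenance,
        "categories": list(model.categories),
        "reference": model.reference,
        "terms": [
            {
                "variable": t.variable,
                "transform": t.transform,
                **({"level": t.level} if t.level is not None else {}),
                **({"bands": [dict(b) for b in t.bands]} if t.bands else {}),
            }
            for t in model.terms
        ],
        "coefficients": {
            k: {"intercept": float(model.intercepts[k]), "betas": [float(b) for b in model.coefficients[k]]}
            for k in model.nonreference
        },
        "schema_ref": model.schema.to_dict() if model.schema is not None else None,
    }
    return d


def model_from_dict(d: dict):
    schema = PredictorSchema.from_dict(d["schema_ref"]) if d.get("schema_ref") else None
    if d["type"] == "risk_score":
        return RiskScoreDef(
            name=d["name"],
            items=d["items"],
            cutoffs=d.get("cutoffs", []),
            age_range=tuple(d.get("age_range", (1.0 / 12.0, 16.0))),
            age_band_unit=d.get("age_band_unit", "years"),
            provenance=d.get("provenance", ""),
            schema=schema,
        )
    if d["type"] not in ("multinomial", "binomial"):
        raise ValueError(f"unknown model type {d['type']!r}")
    terms = [
        Term(
            variable=t["variable"],
            transform=t.get("transform", "identity"),
            level=t.get("level"),
            bands=tuple(t.get("bands", ())),
        )
        for t in d["terms"]
    ]
    model = MultinomialCPM(
        name=d["name"],
        categories=list(d["categories"]),
        reference=d["reference"],
        terms=terms,
        intercepts={k: float(c["intercept"]) for k, c in d["coefficients"].items()},
        coefficients={k: np.asarray(c["betas"], dtype=float) for k, c in d["coefficients"].items()},
        provenance=d.get("provenance", ""),
        schema=schema,
    )
    if d["type"] == "binomial" and not model.is_binomial:
        raise ValueError("binomial model must have exactly 2 categories")
    return model


def load_model(path):
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def save_model(model, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")
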