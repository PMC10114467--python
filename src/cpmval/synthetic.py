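"""Synthetic patient cohorts with a known true outcome model.

The generator draws mixed binary/continuous predictors (symptoms,
temperature in °C, CRP in mg/L, vital signs), computes category
probabilities from a known true multinomial model, and draws one outcome
label per child — so every downstream statistic can be checked against
the generating truth.  Marginal structure mirrors an ambulatory-care
study of acutely ill children aged 1 month to 16 years: a reference
category "no serious infection", nine serious-infection categories with
a combined prevalence near 6%, ~54% boys, and a GP / outpatient
paediatric / emergency-department setting mix.

Prevalence targets are hit by calibrating the truth model's intercepts
against a fixed Monte-Carlo predictor sample; missingness is masked
MCAR (missing completely at random) per variable, which matches the
single-imputation assumption the analysis makes but is *not* a model of
real-world informative missingness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .cohort import (
    ESSENTIAL_FIELDS,
    GASTRO_CATEGORY,
    REFERENCE_CATEGORY,
    SI_CATEGORIES,
    Cohort,
)
from .models import MultinomialCPM, ProbabilityMatrix, Term, predict_probabilities
from .schema import PredictorSchema, Variable

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "calibrate_intercepts",
    "inject_missingness",
    "ernie2_preset",
    "make_flow_fixture",
    "save_generated",
    "EMULATED_SI_COUNTS",
]

#: Outcome counts of the emulated validation cohort (n analyzed = 8211);
#: the generator preset converts these to target prevalences.
EMULATED_SI_COUNTS = {
    "abscess_cellulitis": 10,
    "appendicitis": 15,
    "cuti": 57,
    GASTRO_CATEGORY: 162,
    "meningitis": 16,
    "osteomyelitis": 0,
    "pneumonia": 171,
    "sepsis_bacteraemia": 7,
    "viral_rti_hypoxia": 60,
}
_ANALYZED = 8211
_SI_MALE = 268  # of 498 serious infections
_NOSI_MALE = 4133  # of 7713 without serious infection
_SETTING_COUNTS = {  # (serious infection, no serious infection) per setting
    "GP": (23, 2879),
    "paediatric outpatient": (109, 2610),
    "ED": (366, 2224),
}


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic cohort.

    ``predictors`` maps a variable name to a marginal distribution spec:
    ``{"dist": "bernoulli", "p"}``, ``{"dist": "normal", "mu", "sigma"}``
    or ``{"dist": "lognormal", "mu", "sigma"}`` (log-scale parameters),
    the continuous ones truncated to ``"range"`` when given.
    ``correlation`` optionally imposes a Gaussian copula over the listed
    predictor order (default: independent).
    """

    n: int
    seed: int
    predictors: dict[str, dict]
    truth: MultinomialCPM
    target_prevalences: dict[str, float] | None = None
    missingness: dict[str, float] = field(default_factory=dict)
    essential_missing_rate: float = 0.0
    age_out_rate: float = 0.0
    correlation: np.ndarray | None = None
    sex_male_p: float = 0.54
    setting_probs: dict[str, float] = field(
        default_factory=lambda: {"GP": 0.3534, "paediatric outpatient": 0.3311, "ED": 0.3155}
    )
    schema: PredictorSchema | None = None

    def __post_init__(self):
        if self.target_prevalences is not None:
            vals = list(self.target_prevalences.values())
            if any(not 0.0 < v < 1.0 for v in vals) or sum(vals) >= 1.0:
                raise ValueError("target prevalences must lie in (0,1) and sum below 1")
        for v, r in self.missingness.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missingness rate for {v!r} must be in [0, 1)")

    def to_dict(self) -> dict:
        from .models import model_to_dict

        return {
            "n": self.n,
            "seed": self.seed,
            "predictors": self.predictors,
            "truth": model_to_dict(self.truth),
            "target_prevalences": self.target_prevalences,
            "missingness": self.missingness,
            "essential_missing_rate": self.essential_missing_rate,
            "age_out_rate": self.age_out_rate,
            "correlation": None if self.correlation is None else np.asarray(self.correlation).tolist(),
            "sex_male_p": self.sex_male_p,
            "setting_probs": self.setting_probs,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _marginal_ppf(spec: dict, u: np.ndarray) -> np.ndarray:
    dist = spec["dist"]
    if dist == "bernoulli":
        return (u > 1.0 - spec["p"]).astype(float)
    if dist == "categorical":
        cum = np.cumsum(spec["p"])
        return np.asarray(spec["levels"], dtype=object)[np.searchsorted(cum, u)]
    lo, hi = spec.get("range", (-np.inf, np.inf))
    if dist == "normal":
        mu, sg = spec["mu"], spec["sigma"]
        a, b = (lo - mu) / sg, (hi - mu) / sg
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sg)
    if dist == "lognormal":
        mu, sg = spec["mu"], spec["sigma"]
        llo = np.log(lo) if lo > 0 else -np.inf
        lhi = np.log(hi) if np.isfinite(hi) else np.inf
        a, b = (llo - mu) / sg, (lhi - mu) / sg
        return np.exp(stats.truncnorm.ppf(u, a, b, loc=mu, scale=sg))
    raise ValueError(f"unknown distribution {dist!r}")


def _draw_predictors(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    names = list(config.predictors)
    z = rng.standard_normal((n, len(names)))
    if config.correlation is not None:
        L = np.linalg.cholesky(np.asarray(config.correlation, dtype=float))
        z = z @ L.T
    u = ndtr(z)
    return pd.DataFrame({v: _marginal_ppf(config.predictors[v], u[:, j]) for j, v in enumerate(names)})


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, ProbabilityMatrix]:
    """Draw a complete cohort plus the true probability matrix.

    All randomness flows through one generator seeded with
    ``config.seed``, so identical configs give identical tables.  If
    ``target_prevalences`` is set, intercepts are calibrated first.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    if config.target_prevalences is not None:
        truth = calibrate_intercepts(truth, config.target_prevalences, config.predictors)
    df = _draw_predictors(config, config.n, rng)
    df["sex"] = np.where(rng.random(config.n) < config.sex_male_p, "male", "female")
    settings = list(config.setting_probs)
    df["setting"] = rng.choice(settings, size=config.n, p=list(config.setting_probs.values()))
    if config.age_out_rate > 0 and "age" in df.columns:
        out = rng.random(config.n) < config.age_out_rate
        df.loc[out, "age"] = np.where(rng.random(int(out.sum())) < 0.5, 17.5, 0.04)
    P = predict_probabilities(truth, Cohort(df, config.schema))
    u = rng.random(config.n)
    cum = np.cumsum(P.values, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    df["outcome"] = [P.categories[i] for i in idx]
    return Cohort(df.reset_index(drop=True), config.schema), P


_CALIBRATION_MEMO: dict[str, MultinomialCPM] = {}


def calibrate_intercepts(
    truth: MultinomialCPM,
    target_prevalences: dict[str, float],
    predictor_specs: dict[str, dict],
    n_mc: int = 100_000,
    mc_seed: int = 202304,
    tol: float = 1e-4,
    max_sweeps: int = 200,
) -> MultinomialCPM:
    """Adjust intercepts so expected category probabilities match targets.

    Expectations are taken over a fixed Monte-Carlo predictor sample
    (``n_mc`` draws, internal seed), and each intercept is solved by
    damped Newton sweeps, iterated to joint convergence within ``tol``.
    The solve is deterministic, so repeated identical calls are memoised.
    """
    from .models import model_to_dict

    key = hashlib.sha256(
        json.dumps(
            [model_to_dict(truth), target_prevalences, predictor_specs, n_mc, mc_seed, tol],
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    if key in _CALIBRATION_MEMO:
        return _CALIBRATION_MEMO[key]
    cfg = GeneratorConfig(
        n=n_mc, seed=mc_seed, predictors=predictor_specs, truth=truth, schema=truth.schema
    )
    rng = np.random.default_rng(mc_seed)
    df = _draw_predictors(cfg, n_mc, rng)
    from .models import design_matrix

    X = design_matrix(truth, Cohort(df, truth.schema))
    nonref = truth.nonreference
    for k in target_prevalences:
        if k not in nonref:
            raise ValueError(f"target category {k!r} not in the truth model")
    alphas = {k: float(truth.intercepts[k]) for k in nonref}
    etas = np.column_stack([alphas[k] + X @ truth.coefficients[k] for k in nonref])

    def mean_probs(e):
        full = np.concatenate([np.zeros((n_mc, 1)), e], axis=1)
        full = full - full.max(axis=1, keepdims=True)
        ex = np.exp(full)
        return (ex / ex.sum(axis=1, keepdims=True)).mean(axis=0)[1:]

    def probs(e):
        full = np.concatenate([np.zeros((n_mc, 1)), e], axis=1)
        full = full - full.max(axis=1, keepdims=True)
        ex = np.exp(full)
        return ex / ex.sum(axis=1, keepdims=True)

    for _ in range(max_sweeps):
        for j, k in enumerate(nonref):
            if k not in target_prevalences:
                continue
            target = target_prevalences[k]
            for _ in range(50):  # 1-D Newton in alpha_k, others held fixed
                Pm = probs(etas)
                mu = Pm[:, j + 1].mean()
                if abs(mu - target) < tol / 10:
                    break
                deriv = (Pm[:, j + 1] * (1.0 - Pm[:, j + 1])).mean()
                step = np.clip((target - mu) / max(deriv, 1e-12), -5.0, 5.0)
                alphas[k] += step
                etas[:, j] += step
        # joint convergence is judged after the whole sweep: each 1-D solve
        # perturbs every other category through the shared normalisation
        mean_after = probs(etas).mean(axis=0)
        worst = max(
            abs(mean_after[nonref.index(k) + 1] - t) for k, t in target_prevalences.items()
        )
        if worst < tol:
            break
    else:
        raise RuntimeError(
            f"intercept calibration did not converge within {max_sweeps} sweeps (worst error {worst:g})"
        )
    result = truth.replace_parameters(
        alphas, {k: truth.coefficients[k] for k in nonref}, suffix=""
    )
    _CALIBRATION_MEMO[key] = result
    return result


def inject_missingness(cohort: Cohort, config: GeneratorConfig, rng=None) -> Cohort:
    """Mask cells MCAR at the configured per-variable rates.

    Essential fields are only masked through ``essential_missing_rate``
    (one essential field per selected record, round-robin).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    df = cohort.df.copy()
    for v, rate in config.missingness.items():
        if rate <= 0 or v not in df.columns or v in ESSENTIAL_FIELDS:
            continue
        df.loc[rng.random(len(df)) < rate, v] = np.nan
    if config.essential_missing_rate > 0:
        hit = np.flatnonzero(rng.random(len(df)) < config.essential_missing_rate)
        fields = [f for f in ESSENTIAL_FIELDS if f in df.columns]
        for i, row in enumerate(hit):
            df.loc[row, fields[i % len(fields)]] = np.nan
    return cohort.with_df(df)


# ---------------------------------------------------------------------------
# Presets and fixtures


def default_schema() -> PredictorSchema:
    return PredictorSchema(
        [
            Variable("age", "continuous", "years", allowed_range=(0.0, 18.0)),
            Variable("temperature", "continuous", "°C", non_deviant_default=37.0, allowed_range=(34.0, 43.0)),
            Variable("crp", "continuous", "mg/L", non_deviant_default=5.0, allowed_range=(0.1, 400.0), aliases=("poc_crp",)),
            Variable("ill_appearance", "binary", "", non_deviant_default=0, aliases=("ill_appearing",)),
            Variable("tachypnoea", "binary", "", non_deviant_default=0),
            Variable("oxygen_sat_low", "binary", "", non_deviant_default=0, aliases=("hypoxia",)),
            Variable("vomiting", "binary", "", non_deviant_default=0),
            Variable("heart_rate", "continuous", "/min", non_deviant_default=110.0, allowed_range=(40.0, 250.0)),
            Variable("resp_rate", "continuous", "/min", non_deviant_default=25.0, allowed_range=(5.0, 120.0)),
            Variable(
                "conscious_level",
                "categorical",
                "",
                non_deviant_default="alert",
                allowed_range=("alert", "voice", "pain", "unresponsive"),
            ),
        ]
    )


def _preset_truth(schema: PredictorSchema) -> MultinomialCPM:
    categories = [REFERENCE_CATEGORY] + list(SI_CATEGORIES)
    terms = [
        Term("temperature"),
        Term("crp", "log"),
        Term("ill_appearance"),
        Term("tachypnoea"),
        Term("oxygen_sat_low"),
        Term("vomiting"),
        Term("age", "log"),
    ]
    # rows: temperature, log CRP, ill appearance, tachypnoea, low SpO2, vomiting, log age
    B = {
        "abscess_cellulitis": [0.1, 0.5, 0.8, 0.0, 0.0, 0.0, 0.2],
        "appendicitis": [0.2, 0.6, 0.9, 0.0, 0.0, 0.8, 0.6],
        "cuti": [0.5, 0.8, 0.6, 0.0, 0.0, 0.3, -0.4],
        GASTRO_CATEGORY: [0.2, 0.3, 0.9, 0.0, 0.0, 1.6, -0.3],
        "meningitis": [0.5, 0.7, 1.5, 0.2, 0.0, 0.5, -0.5],
        "osteomyelitis": [0.2, 0.6, 0.5, 0.0, 0.0, 0.0, 0.3],
        "pneumonia": [0.5, 0.9, 0.7, 1.3, 1.1, 0.2, -0.2],
        "sepsis_bacteraemia": [0.6, 0.9, 1.8, 0.3, 0.4, 0.3, -0.4],
        "viral_rti_hypoxia": [0.3, 0.2, 0.6, 1.2, 2.0, 0.1, -0.7],
    }
    return MultinomialCPM(
        name="synthetic truth (ambulatory SI cohort)",
        categories=categories,
        reference=REFERENCE_CATEGORY,
        terms=terms,
        intercepts={k: -8.0 for k in B},
        coefficients={k: np.asarray(v, dtype=float) for k, v in B.items()},
        provenance="synthetic generating model; coefficients are illustrative, not published values",
        schema=schema,
    )


def ernie2_preset(n: int = _ANALYZED, seed: int = 20130215) -> GeneratorConfig:
    """Generator configuration emulating the validation cohort's structure.

    Nine serious-infection categories plus the reference, category
    prevalences matching the emulated cohort's outcome table (the one
    empty category is given a small positive rate of 1/1000 so it can be
    exercised), age 1 month-16 years, ~54% male, three care settings.
    """
    schema = default_schema()
    targets = {
        k: (c if c > 0 else 8) / _ANALYZED for k, c in EMULATED_SI_COUNTS.items()
    }
    predictors = {
        "age": {"dist": "lognormal", "mu": float(np.log(2.0)), "sigma": 1.05, "range": (1.0 / 12.0, 16.0)},
        "temperature": {"dist": "normal", "mu": 38.0, "sigma": 1.0, "range": (34.5, 42.0)},
        "crp": {"dist": "lognormal", "mu": float(np.log(10.0)), "sigma": 1.1, "range": (0.5, 300.0)},
        "ill_appearance": {"dist": "bernoulli", "p": 0.12},
        "tachypnoea": {"dist": "bernoulli", "p": 0.15},
        "oxygen_sat_low": {"dist": "bernoulli", "p": 0.05},
        "vomiting": {"dist": "bernoulli", "p": 0.25},
        "heart_rate": {"dist": "normal", "mu": 120.0, "sigma": 25.0, "range": (50.0, 230.0)},
        "resp_rate": {"dist": "normal", "mu": 30.0, "sigma": 10.0, "range": (10.0, 90.0)},
        "conscious_level": {
            "dist": "categorical",
            "levels": ["alert", "voice", "pain", "unresponsive"],
            "p": [0.96, 0.025, 0.01, 0.005],
        },
    }
    missingness = {
        "crp": 0.25,
        "heart_rate": 0.15,
        "resp_rate": 0.15,
        "oxygen_sat_low": 0.20,
        "ill_appearance": 0.05,
        "tachypnoea": 0.05,
        "vomiting": 0.05,
    }
    return GeneratorConfig(
        n=n,
        seed=seed,
        predictors=predictors,
        truth=_preset_truth(schema),
        target_prevalences=targets,
        missingness=missingness,
        schema=schema,
    )


def make_flow_fixture(seed: int = 0) -> Cohort:
    """Deterministic participant-flow fixture.

    Exactly 8962 enrolled records: 8211 complete and in age range with
    the emulated outcome counts (268 of the 498 serious infections male),
    730 with at least one missing essential field, and 21 complete
    records outside the 1 month-16 years age range.  Row order is
    shuffled by ``seed``; all counts are exact by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def base_row(outcome):
        return {
            "age": float(np.round(rng.uniform(0.1, 15.9), 2)),
            "sex": "female",
            "temperature": float(np.round(rng.uniform(36.5, 40.5), 1)),
            "setting": "GP",
            "outcome": outcome,
        }

    si_rows, nosi_rows = [], []
    for cat, count in EMULATED_SI_COUNTS.items():
        for _ in range(count):
            si_rows.append(base_row(cat))
    for _ in range(_ANALYZED - len(si_rows)):
        nosi_rows.append(base_row(REFERENCE_CATEGORY))
    for r in si_rows[:_SI_MALE]:
        r["sex"] = "male"
    for r in nosi_rows[:_NOSI_MALE]:
        r["sex"] = "male"
    # assign settings with exact per-setting counts
    si_set, nosi_set = [], []
    for s, (n_si, n_nosi) in _SETTING_COUNTS.items():
        si_set += [s] * n_si
        nosi_set += [s] * n_nosi
    rng.shuffle(si_set)
    rng.shuffle(nosi_set)
    for r, s in zip(si_rows, si_set):
        r["setting"] = s
    for r, s in zip(nosi_rows, nosi_set):
        r["setting"] = s
    rows = si_rows + nosi_rows

    essentials = ("outcome", "age", "sex", "temperature")
    for i in range(730):
        r = base_row(REFERENCE_CATEGORY)
        r[essentials[i % 4]] = np.nan
        rows.append(r)
    for i in range(21):
        r = base_row(REFERENCE_CATEGORY)
        r["age"] = 17.0 + i * 0.1 if i % 2 == 0 else 0.03
        rows.append(r)

    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    return Cohort(df.iloc[order].reset_index(drop=True), default_schema())


def save_generated(outdir, cohort: Cohort, truth: MultinomialCPM, config: GeneratorConfig):
    """Write cohort CSV + truth-model JSON + a provenance sidecar."""
    from .models import save_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.df.to_csv(outdir / "cohort.csv", index=False)
    save_model(truth, outdir / "truth_model.json")
    sidecar = {"seed": config.seed, "n": config.n, "config_sha256_16": config.digest()}
    (outdir / "provenance.json").write_text(json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")
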