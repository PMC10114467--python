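"""End-to-end runs and report tables.

``run`` executes the full validation flow on one cohort and any number of
models — load, eligibility filter, non-deviant imputation, analysis
subsets, discrimination and calibration (for regression models),
updating, and threshold accuracy — and writes report CSVs laid out like
a validation paper's performance tables: one C-statistic table, one
calibration intercept/slope table, one diagnostic-accuracy table, plus
calibration-curve points, flow counts, and a JSON manifest with
full-precision values.

Reported numbers are rounded to two decimals (prevalences to one decimal
percent); undefined likelihood ratios print as "NA".
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import contingency, diagnostic_stats
from .calibration import multinomial_calibration
from .cohort import (
    SBI_CATEGORIES,
    SI_CATEGORIES,
    Cohort,
    eligibility_filter,
    impute_non_deviant,
    load_cohort,
    prevalence,
    sbi_analysis_subset,
    subgroup,
)
from .discrimination import conditional_c_statistic
from .models import (
    MultinomialCPM,
    RiskScoreDef,
    apply_risk_score,
    load_model,
    predict_probabilities,
)
from .updating import update_pipeline

log = logging.getLogger("cpmval")

__all__ = ["RunConfig", "run", "relabel_outcomes", "default_outcome_map"]

DEFAULT_RISK_CUTOFFS = (0.025, 0.10, 0.30)


#: Model-category synonyms for the fine-grained cohort outcome labels.
_CATEGORY_SYNONYMS = {
    "bacteraemia": ["sepsis_bacteraemia"],
    "sbi": list(SBI_CATEGORIES),
}


def default_outcome_map(model: MultinomialCPM) -> dict[str, list[str]]:
    """Map fine-grained cohort outcomes onto a model's categories.

    Categories named after a cohort outcome (or a known synonym) map to
    themselves; a category named ``other_sbi`` absorbs the remaining
    bacterial categories; the model's reference absorbs everything left.
    """
    m: dict[str, list[str]] = {}
    used: set[str] = set()
    for k in model.nonreference:
        if k == "other_sbi":
            continue
        m[k] = _CATEGORY_SYNONYMS.get(k, [k])
        used.update(m[k])
    if "other_sbi" in model.nonreference:
        m["other_sbi"] = [c for c in SBI_CATEGORIES if c not in used]
        used.update(m["other_sbi"])
    m[model.reference] = ["__rest__"]
    return m


def relabel_outcomes(outcomes, outcome_map: dict[str, list[str]], reference: str) -> np.ndarray:
    outcomes = np.asarray(outcomes)
    out = np.full(outcomes.shape, "", dtype=object)
    assigned = np.zeros(outcomes.shape, dtype=bool)
    for target, sources in outcome_map.items():
        if sources == ["__rest__"]:
            continue
        mask = np.isin(outcomes, sources)
        out[mask] = target
        assigned |= mask
    rest_target = next((t for t, s in outcome_map.items() if s == ["__rest__"]), reference)
    out[~assigned] = rest_target
    return out


@dataclass
class RunConfig:
    """One reproducible validation/update/accuracy run."""

    models: list  # paths or model objects
    cohort: str | Cohort | None = None
    preset: str | None = None  # "ernie2"
    n: int | None = None
    analysis: str = "all"  # validate | update | accuracy | all
    outcome_maps: dict = field(default_factory=dict)  # model name -> outcome map
    risk_cutoffs: tuple = DEFAULT_RISK_CUTOFFS
    subgroup_filter: dict = field(default_factory=dict)  # setting / age_min / age_max
    outdir: str = "results"
    seed: int = 0
    quiet: bool = False

    def __post_init__(self):
        if not self.models and self.analysis != "simulate":
            raise ValueError("at least one model is required")
        if self.cohort is None and self.preset is None:
            raise ValueError("either a cohort or a generator preset is required")
        if self.analysis not in ("validate", "update", "accuracy", "all"):
            raise ValueError(f"unknown analysis set {self.analysis!r}")
        for c in self.risk_cutoffs:
            if not 0.0 < c < 1.0:
                raise ValueError("risk cut-offs must lie in (0, 1)")


def _r2(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), 2)


def _fmt_lr(x):
    return "NA" if x is None else f"{x:.2f}"


def _resolve_models(config: RunConfig):
    out = []
    for m in config.models:
        out.append(load_model(m) if isinstance(m, (str, Path)) else m)
    return out


def _prepare_cohort(config: RunConfig):
    from .synthetic import ernie2_preset, generate_cohort, inject_missingness

    if config.preset is not None:
        if config.preset != "ernie2":
            raise ValueError(f"unknown preset {config.preset!r}")
        gen = ernie2_preset(seed=config.seed, **({"n": config.n} if config.n else {}))
        cohort, _ = generate_cohort(gen)
        cohort = inject_missingness(cohort, gen)
    elif isinstance(config.cohort, Cohort):
        cohort = config.cohort
    else:
        cohort = load_cohort(config.cohort)
    return cohort


def _validate_model(model, cohort, outcome_map, tables, curves):
    P = predict_probabilities(model, cohort)
    y = relabel_outcomes(cohort.df["outcome"], outcome_map, model.reference)
    cal = multinomial_calibration(P, y, include_curve=True)
    for k in model.nonreference:
        c = conditional_c_statistic(P, y, k)
        tables["cstat"].append(
            {
                "model": model.name,
                "category": k,
                "c_statistic": _r2(c.estimate),
                "ci_low": _r2(c.ci_low),
                "ci_high": _r2(c.ci_high),
                "n_cases": c.n_cases,
                "n_controls": c.n_controls,
            }
        )
        f = cal[k]
        tables["calibration"].append(
            {
                "model": model.name,
                "contrast": f"{k} vs. {model.reference}",
                "intercept": _r2(f.intercept),
                "intercept_ci_low": _r2(f.intercept_ci[0]),
                "intercept_ci_high": _r2(f.intercept_ci[1]),
                "slope": _r2(f.slope),
                "slope_ci_low": _r2(f.slope_ci[0]),
                "slope_ci_high": _r2(f.slope_ci[1]),
                "n_used": f.n_used,
            }
        )
        if f.curve is not None:
            cv = f.curve.copy()
            cv.insert(0, "category", k)
            cv.insert(0, "model", model.name)
            curves.append(cv)
    return P, y, cal


def _accuracy_rows(model, values, y_binary, cutoffs, tables, category=""):
    for cut in cutoffs:
        name, op, thr = cut if isinstance(cut, tuple) else (f">= {cut:g}", ">=", cut)
        t = contingency(values, y_binary, thr, op)
        s = diagnostic_stats(t)
        tables["accuracy"].append(
            {
                "model": model.name,
                "category": category,
                "cutoff": name,
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
                "sensitivity": _r2(s.sensitivity),
                "sens_ci_low": _r2(s.sensitivity_ci[0]),
                "sens_ci_high": _r2(s.sensitivity_ci[1]),
                "specificity": _r2(s.specificity),
                "spec_ci_low": _r2(s.specificity_ci[0]),
                "spec_ci_high": _r2(s.specificity_ci[1]),
                "lr_pos": _fmt_lr(s.lr_pos),
                "lr_neg": _fmt_lr(s.lr_neg),
            }
        )


def run(config: RunConfig) -> dict:
    """Execute the configured analyses; returns the manifest dictionary."""
    level = logging.WARNING if config.quiet else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level, format="%(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    stage = "prepare"
    try:
        cohort = _prepare_cohort(config)
        stage = "eligibility"
        cohort, flow = eligibility_filter(cohort)
        log.info("eligibility: %s analyzed of %s enrolled", flow.analyzed, flow.enrolled)
        stage = "imputation"
        cohort = impute_non_deviant(cohort)
        if config.subgroup_filter:
            cohort = subgroup(cohort, **config.subgroup_filter)
        prev_si = prevalence(cohort, SI_CATEGORIES)
        prev_sbi = prevalence(cohort, SBI_CATEGORIES)
        models = _resolve_models(config)
        tables = {"cstat": [], "calibration": [], "accuracy": []}
        curves: list[pd.DataFrame] = []
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "analysis": config.analysis,
            "flow": vars(flow) | {},
            "prevalence": {"SI": prev_si, "SBI": prev_sbi},
            "decisions": {
                "calibration_variant": "conditional (category vs reference)",
                "ci_methods": {"auc": "DeLong (logit scale)", "proportions": "Wilson"},
            },
            "models": {},
        }
        for model in models:
            t_m = time.time()
            stage = f"model {model.name}"
            if isinstance(model, RiskScoreDef):
                if config.analysis in ("accuracy", "all"):
                    pts = apply_risk_score(model, cohort)
                    y = cohort.df["outcome"].isin(SI_CATEGORIES).astype(int).to_numpy()
                    # a "<="/"<" cut-off names the low-risk zone; test-positive
                    # means exceeding it
                    flip = {"<=": ">", "<": ">="}
                    cuts = [
                        (f"{c['op']} {c['value']}", flip.get(c["op"], c["op"]), c["value"])
                        for c in model.cutoffs
                    ]
                    _accuracy_rows(model, pts, y, cuts, tables, category="SI")
                manifest["models"][model.name] = {"type": "risk_score"}
            else:
                predicts_sbi = any(c in ("other_sbi", "sbi") for c in model.categories)
                analysis_cohort = sbi_analysis_subset(cohort) if predicts_sbi else cohort
                omap = config.outcome_maps.get(model.name) or default_outcome_map(model)
                info = {"type": "binomial" if model.is_binomial else "multinomial", "n": len(analysis_cohort)}
                if config.analysis in ("validate", "all", "accuracy", "update"):
                    P, y, _ = _validate_model(model, analysis_cohort, omap, tables, curves)
                final_model = model
                if config.analysis in ("update", "all"):
                    rep = update_pipeline(
                        model, Cohort(analysis_cohort.df.assign(outcome=y), analysis_cohort.schema)
                    )
                    final_model = rep.final
                    info["gamma"] = rep.gamma
                    info["fit_chi2"] = rep.fit_chi2
                    info["df"] = rep.df
                    info["update"] = rep.to_dict()
                    upd = final_model.replace_parameters(
                        final_model.intercepts, final_model.coefficients
                    )
                    _validate_model(upd, analysis_cohort, omap, tables, curves)
                if config.analysis in ("accuracy", "all"):
                    Pf = predict_probabilities(final_model, analysis_cohort)
                    for k in final_model.nonreference:
                        r = Pf.column(k)
                        yk = (y == k).astype(int)
                        _accuracy_rows(final_model, r, yk, list(config.risk_cutoffs), tables, category=k)
                manifest["models"][model.name] = info
            log.info("%s: %.1f s", model.name, time.time() - t_m)

        stage = "writing"
        for name, rows in tables.items():
            if rows:
                p = outdir / f"{name}.csv"
                pd.DataFrame(rows).to_csv(p, index=False)
                written.append(p)
        if curves:
            p = outdir / "calibration_curves.csv"
            pd.concat(curves, ignore_index=True).to_csv(p, index=False)
            written.append(p)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=1, default=float) + "\n", encoding="utf-8")
        written.append(p)
        log.info("run finished in %.1f s", time.time() - t0)
        return manifest
    except Exception as e:
        for p in written:  # leave no partial report behind
            p.unlink(missing_ok=True)
        raise RuntimeError(f"run failed at stage {stage!r}: {e}") from e
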