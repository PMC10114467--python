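import importlib.resources as ir

import numpy as np
import pandas as pd
import pytest

import cpmval as cv
from cpmval.cohort import Cohort
from cpmval.models import MultinomialCPM, Term
from cpmval.reporting import default_outcome_map, relabel_outcomes


def data_path(name: str) -> str:
    return str(ir.files("cpmval") / "data" / name)


@pytest.fixture(scope="session")
def feverkids_like():
    return cv.load_model(data_path("feverkids_like.json"))


@pytest.fixture(scope="session")
def paws_like():
    return cv.load_model(data_path("paws_like.json"))


@pytest.fixture(scope="session")
def sbi_score_like():
    return cv.load_model(data_path("sbi_score_like.json"))


def simple_truth(coefs=((0.8, -0.5), (0.3, 0.9)), intercepts=(-2.0, -2.5)):
    """Tiny 3-category truth model over two continuous predictors."""
    cats = ["no_sbi", "pneumonia", "other_sbi"]
    return MultinomialCPM(
        name="simple truth",
        categories=cats,
        reference="no_sbi",
        terms=[Term("x1"), Term("x2")],
        intercepts={"pneumonia": intercepts[0], "other_sbi": intercepts[1]},
        coefficients={"pneumonia": np.array(coefs[0]), "other_sbi": np.array(coefs[1])},
    )


def simple_cohort(truth, n, seed):
    """Standard-normal predictors, outcomes drawn from the truth model."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
    P = cv.predict_probabilities(truth, Cohort(df))
    u = rng.random(n)
    idx = (u[:, None] > np.cumsum(P.values, axis=1)).sum(axis=1)
    df["outcome"] = [P.categories[i] for i in idx]
    return Cohort(df), P


@pytest.fixture(scope="session")
def truth3():
    return simple_truth()


@pytest.fixture(scope="session")
def cohort20k(truth3):
    return simple_cohort(truth3, 20_000, seed=11)


@pytest.fixture(scope="session")
def cohort50k(truth3):
    return simple_cohort(truth3, 50_000, seed=12)


@pytest.fixture(scope="session")
def flow_cohort():
    return cv.make_flow_fixture(seed=0)


@pytest.fixture(scope="session")
def preset_cohort():
    """One ambulatory-care preset cohort at the shipped seed, reused widely."""
    gen = cv.ernie2_preset()
    cohort, P = cv.generate_cohort(gen)
    return gen, cohort, P


@pytest.fixture(scope="session")
def mapped_cohort20k(feverkids_like):
    """Preset-style cohort mapped onto the 3-category fixture model's outcomes."""
    gen = cv.ernie2_preset(n=20_000, seed=7)
    cohort, _ = cv.generate_cohort(gen)
    sub = cv.sbi_analysis_subset(cohort)
    y = relabel_outcomes(sub.df["outcome"], default_outcome_map(feverkids_like), feverkids_like.reference)
    return Cohort(sub.df.assign(outcome=y), sub.schema)
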