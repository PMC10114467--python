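"""Cohort ingestion, eligibility flow, imputation, subsets, prevalence."""

import numpy as np
import pandas as pd
import pytest

import cpmval as cv
from cpmval.cohort import Cohort, FlowCounts, GASTRO_CATEGORY
from cpmval.schema import PredictorSchema, Variable


@pytest.fixture
def schema():
    return PredictorSchema(
        [
            Variable("crp", "continuous", "mg/L", non_deviant_default=5.0, allowed_range=(0, 400), aliases=("poc_crp",)),
            Variable("vomiting", "binary", non_deviant_default=0),
        ]
    )


class TestLoadCohort:
    def test_alias_headers_renamed(self, tmp_path, schema):
        p = tmp_path / "c.csv"
        p.write_text("poc_crp,vomiting,outcome\n12,1,no_si\n", encoding="utf-8")
        c = cv.load_cohort(p, schema)
        assert "crp" in c.df.columns and "poc_crp" not in c.df.columns

    def test_empty_and_na_are_missing(self, tmp_path, schema):
        p = tmp_path / "c.csv"
        p.write_text("crp,vomiting,outcome\n,1,no_si\nNA,0,no_si\n7,,no_si\n", encoding="utf-8")
        c = cv.load_cohort(p, schema)
        assert c.df["crp"].isna().tolist() == [True, True, False]
        assert c.df["vomiting"].isna().tolist() == [False, False, True]

    def test_malformed_numeric_names_row_and_column(self, tmp_path, schema):
        p = tmp_path / "c.csv"
        p.write_text("crp,vomiting,outcome\nok?,1,no_si\n", encoding="utf-8")
        with pytest.raises(ValueError, match="crp.*row 0"):
            cv.load_cohort(p, schema)

    def test_unknown_column_warns_but_keeps(self, tmp_path, schema):
        p = tmp_path / "c.csv"
        p.write_text("crp,mystery,outcome\n3,9,no_si\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="mystery"):
            c = cv.load_cohort(p, schema)
        assert "mystery" in c.df.columns


class TestEligibilityFlow:
    def test_engineered_flow_fixture(self, flow_cohort):
        filtered, flow = cv.eligibility_filter(flow_cohort)
        assert flow == FlowCounts(8962, 730, 21, 8211)
        assert len(filtered) == 8211
        essentials = filtered.df[["outcome", "age", "sex", "temperature"]]
        assert not essentials.isna().any().any()

    def test_no_exclusions_is_identity(self):
        df = pd.DataFrame(
            {"outcome": ["no_si"] * 3, "age": [1.0, 2.0, 3.0], "sex": ["male"] * 3, "temperature": [38.0] * 3}
        )
        _, flow = cv.eligibility_filter(Cohort(df))
        assert flow.analyzed == flow.enrolled == 3

    def test_double_failure_counted_once_under_first_rule(self):
        df = pd.DataFrame(
            {"outcome": [np.nan], "age": [25.0], "sex": ["male"], "temperature": [38.0]}
        )
        _, flow = cv.eligibility_filter(Cohort(df))
        assert flow.excluded_missing_essential == 1 and flow.excluded_age == 0

    def test_age_bounds_inclusive(self):
        df = pd.DataFrame(
            {
                "outcome": ["no_si"] * 3,
                "age": [1.0 / 12.0, 16.0, 16.01],
                "sex": ["male"] * 3,
                "temperature": [38.0] * 3,
            }
        )
        kept, flow = cv.eligibility_filter(Cohort(df))
        assert flow.excluded_age == 1 and len(kept) == 2

    def test_flow_conservation_enforced(self):
        with pytest.raises(ValueError):
            FlowCounts(enrolled=10, excluded_missing_essential=1, excluded_age=1, analyzed=9)


class TestImputation:
    def test_schema_driven_defaults(self, schema):
        df = pd.DataFrame({"crp": [np.nan, 12.0], "vomiting": [np.nan, 1.0], "outcome": ["no_si"] * 2})
        out = cv.impute_non_deviant(Cohort(df), schema)
        assert out.df["crp"].tolist() == [5.0, 12.0]
        assert out.df["vomiting"].tolist() == [0.0, 1.0]

    def test_idempotent_and_identity_when_complete(self, schema):
        df = pd.DataFrame({"crp": [3.0], "vomiting": [1.0], "outcome": ["no_si"]})
        once = cv.impute_non_deviant(Cohort(df), schema)
        pd.testing.assert_frame_equal(once.df, df)
        df2 = pd.DataFrame({"crp": [np.nan], "vomiting": [1.0], "outcome": ["no_si"]})
        once = cv.impute_non_deviant(Cohort(df2), schema)
        twice = cv.impute_non_deviant(once, schema)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_missing_without_default_raises(self):
        schema = PredictorSchema([Variable("mystery", "continuous")])
        df = pd.DataFrame({"mystery": [np.nan], "outcome": ["no_si"]})
        with pytest.raises(ValueError, match="mystery"):
            cv.impute_non_deviant(Cohort(df), schema)


class TestSbiSubsetAndPrevalence:
    def test_gastro_exclusion_on_flow_fixture(self, flow_cohort):
        filtered, _ = cv.eligibility_filter(flow_cohort)
        sub = cv.sbi_analysis_subset(filtered)
        assert len(sub) == 8049
        assert not (sub.df["outcome"] == GASTRO_CATEGORY).any()

    def test_no_gastro_is_identity(self):
        df = pd.DataFrame({"outcome": ["no_si", "pneumonia"]})
        assert len(cv.sbi_analysis_subset(Cohort(df))) == 2

    def test_all_gastro_warns_empty(self):
        df = pd.DataFrame({"outcome": [GASTRO_CATEGORY] * 2})
        with pytest.warns(UserWarning):
            assert len(cv.sbi_analysis_subset(Cohort(df))) == 0

    def test_si_and_sbi_percentages(self, flow_cohort):
        filtered, _ = cv.eligibility_filter(flow_cohort)
        si = cv.prevalence(filtered, cv.SI_CATEGORIES)
        sbi = cv.prevalence(filtered, cv.SBI_CATEGORIES)
        assert (si["count"], si["percent"]) == (498, 6.1)
        assert (sbi["count"], sbi["percent"]) == (276, 3.4)
        assert round(100 * si["ci_low"], 1) == 5.6 and round(100 * si["ci_high"], 1) == 6.6

    def test_zero_events(self):
        df = pd.DataFrame({"outcome": ["no_si"] * 10})
        p = cv.prevalence(Cohort(df), ["pneumonia"])
        assert p["percent"] == 0.0 and p["ci_low"] == 0.0

    def test_partition_sums_to_one(self, flow_cohort):
        filtered, _ = cv.eligibility_filter(flow_cohort)
        cats = list(cv.SI_CATEGORIES) + ["no_si"]
        total = sum(cv.prevalence(filtered, [c])["proportion"] for c in cats)
        assert total == pytest.approx(1.0)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cv.prevalence(Cohort(pd.DataFrame({"outcome": []})), ["x"])


class TestSubgroup:
    def test_setting_filter(self, flow_cohort):
        filtered, _ = cv.eligibility_filter(flow_cohort)
        ed = cv.subgroup(filtered, setting="ED")
        assert set(ed.df["setting"]) == {"ED"}
        assert len(ed) == 2590

    def test_age_boundary_inclusive(self):
        df = pd.DataFrame({"outcome": ["no_si"] * 2, "age": [5.0, 5.01], "setting": ["GP"] * 2})
        assert cv.subgroup(Cohort(df), age_max=5.0).df["age"].tolist() == [5.0]

    def test_filters_commute(self, flow_cohort):
        filtered, _ = cv.eligibility_filter(flow_cohort)
        a = cv.subgroup(cv.subgroup(filtered, setting="GP"), age_max=5.0)
        b = cv.subgroup(cv.subgroup(filtered, age_max=5.0), setting="GP")
        pd.testing.assert_frame_equal(a.df, b.df)
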