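"""Case/non-case flagging and the descriptive cohort summaries."""

import datetime as dt
import random

import pandas as pd
import pytest

from pvsignal.cohort import (AnalysisDataset, co_reported_fraction,
                             demographic_summary, flag_cases, outcome_summary,
                             select_primary_outcome, summarize_counts,
                             tto_summary)
from pvsignal.vocabulary import DrugSynonymSet
from tests.conftest import make_report


def pct(df, category, level):
    row = df[(df["category"] == category) & (df["level"] == level)]
    assert len(row) == 1, f"missing {category}/{level}"
    return float(row["percentage"].iloc[0])


class TestFlagCases:
    def test_primary_suspect_synonym_is_case(self, target_synonyms):
        ds = flag_cases([make_report(drugs=[("Temodar", "PS", 1)])],
                        target_synonyms)
        assert ds.reports["is_case"].all()

    def test_concomitant_role_is_non_case(self, target_synonyms):
        ds = flag_cases([make_report(drugs=[("temozolomide", "C", 1)])],
                        target_synonyms)
        assert not ds.reports["is_case"].any()

    def test_units_are_distinct_report_pt_pairs(self, target_synonyms):
        r = make_report(events=["nausea", "rash", "Nausea", "vomiting"])
        ds = flag_cases([r], target_synonyms)
        assert len(ds.units) == 3  # duplicate PT collapses

    def test_report_order_invariance(self, target_synonyms):
        reports = [make_report(report_id=i,
                               drugs=[("temodar" if i % 2 else "other", "PS", 1)],
                               events=[f"pt_{i % 5}"]) for i in range(20)]
        shuffled = reports[:]
        random.Random(3).shuffle(shuffled)
        a = flag_cases(reports, target_synonyms)
        b = flag_cases(shuffled, target_synonyms)
        assert (set(a.reports[a.reports["is_case"]]["report_id"])
                == set(b.reports[b.reports["is_case"]]["report_id"]))


class TestSummaryArithmetic:
    """The published characteristic-table percentages re-derive exactly."""

    def test_sex_percentages(self):
        df = summarize_counts("sex", {"female": 6306, "male": 7302})
        assert pct(df, "sex", "male") == 53.66
        assert pct(df, "sex", "female") == 46.34

    def test_age_band_percentage(self):
        counts = {"<18": 716, "18-45": 2058, "45-65": 4742, "65-75": 2327,
                  ">=75": 910, "unknown": 2855}
        df = summarize_counts("age", counts)
        assert sum(counts.values()) == 13608
        assert pct(df, "age", "45-65") == 34.85

    def test_outcome_percentages_use_reports_with_outcomes(self):
        counts = {"hospitalization": 4843, "other serious": 4637,
                  "death": 3087, "life threatening": 709, "disability": 219,
                  "required intervention": 37, "congenital anomaly": 12}
        assert sum(counts.values()) == 13544
        df = summarize_counts("outcome", counts)
        assert pct(df, "outcome", "hospitalization") == 35.76

    def test_tto_percentages_include_unknown_level(self):
        counts = {"<7": 694, "7-28": 1204, "28-60": 1248, ">=60": 1668,
                  "unknown": 4128}
        assert sum(counts.values()) == 8942
        df = summarize_counts("tto", counts)
        assert pct(df, "tto", "<7") == 7.76

    def test_zero_denominator(self):
        df = summarize_counts("sex", {"female": 0})
        assert df["percentage"].iloc[0] == 0.0


class TestDemographicSummary:
    def test_levels_sum_to_case_count_per_category(self, target_synonyms):
        reports = [
            make_report(1, sex="male", age_value=50, occupation="MD", country="US"),
            make_report(2, sex="female", age_value=70, occupation="PH", country="JP"),
            make_report(3, sex="unknown", age_value=None, age_unit="unknown",
                        occupation="unknown", country="unknown"),
            make_report(4, drugs=[("other", "PS", 1)]),  # non-case: excluded
        ]
        ds = flag_cases(reports, target_synonyms)
        df = demographic_summary(ds)
        for cat in ("sex", "age", "reporter", "country"):
            assert df[df["category"] == cat]["count"].sum() == 3

    def test_age_units_converted_and_binned(self, target_synonyms):
        reports = [make_report(1, age_value=540, age_unit="month"),   # 45 years
                   make_report(2, age_value=6, age_unit="decade"),    # 60 years
                   make_report(3, age_value=17.9, age_unit="year")]
        ds = flag_cases(reports, target_synonyms)
        df = demographic_summary(ds)
        age = df[df["category"] == "age"].set_index("level")["count"]
        assert age["45-65"] == 2 and age["<18"] == 1

    def test_all_unknown_sex_is_100_percent(self, target_synonyms):
        ds = flag_cases([make_report(1, sex="unknown")], target_synonyms)
        assert pct(demographic_summary(ds), "sex", "unknown") == 100.00


class TestOutcomeSummary:
    def test_priority_selects_single_most_serious(self):
        assert select_primary_outcome(["HO", "DE"]) == "DE"
        assert select_primary_outcome(["OT", "RI", "CA"]) == "CA"
        assert select_primary_outcome([]) is None

    def test_denominator_excludes_reports_without_outcomes(self, target_synonyms):
        reports = [make_report(1, outcomes=["HO", "DE"]),
                   make_report(2, outcomes=["HO"]),
                   make_report(3, outcomes=[])]
        ds = flag_cases(reports, target_synonyms)
        df = outcome_summary(ds)
        assert df["count"].sum() == 2
        assert pct(df, "outcome", "death") == 50.0

    def test_no_outcomes_yields_empty_summary(self, target_synonyms):
        ds = flag_cases([make_report(1, outcomes=[])], target_synonyms)
        assert outcome_summary(ds).empty


class TestTtoSummary:
    @pytest.mark.parametrize("start,event,expected_level", [
        (dt.date(2023, 1, 1), dt.date(2023, 1, 7), "<7"),     # 6 days
        (dt.date(2023, 1, 1), dt.date(2023, 1, 8), "7-28"),   # 7: left-closed
        (dt.date(2023, 1, 1), dt.date(2023, 1, 29), "28-60"), # 28 days
        (dt.date(2023, 1, 1), dt.date(2023, 3, 15), ">=60"),
        (dt.date(2023, 3, 1), dt.date(2023, 1, 1), "unknown"),  # negative
        (None, dt.date(2023, 1, 1), "unknown"),
    ])
    def test_binning(self, target_synonyms, start, event, expected_level):
        ds = flag_cases([make_report(1, start_date=start, event_date=event)],
                        target_synonyms)
        df = tto_summary(ds)
        assert pct(df, "tto", expected_level) == 100.00

    def test_unknown_in_denominator(self, target_synonyms):
        reports = [make_report(1, start_date=dt.date(2023, 1, 1),
                               event_date=dt.date(2023, 1, 3)),
                   make_report(2)]
        df = tto_summary(flag_cases(reports, target_synonyms))
        assert pct(df, "tto", "<7") == 50.0


class TestCoReportedFraction:
    def _dataset(self, n_with_pt, n_with_co, pt="pjp", co="dexamethasone"):
        reports, units, drugs = [], [], []
        for i in range(n_with_pt):
            rid = f"r{i}"
            reports.append({"report_id": rid, "is_case": True})
            units.append({"report_id": rid, "pt": pt, "is_case": True})
            drugs.append({"report_id": rid, "drugname": "temozolomide",
                          "role": "PS"})
            if i < n_with_co:
                drugs.append({"report_id": rid, "drugname": co.upper(),
                              "role": "C"})
        return AnalysisDataset(reports=pd.DataFrame(reports),
                               units=pd.DataFrame(units),
                               drugs=pd.DataFrame(drugs))

    def test_fraction_arithmetic(self):
        dexa = DrugSynonymSet.from_names("dexamethasone")
        ds = self._dataset(39, 17)
        assert co_reported_fraction(ds, "PJP", dexa) == (39, 17, 43.6)

    def test_absent_pt(self):
        dexa = DrugSynonymSet.from_names("dexamethasone")
        ds = self._dataset(5, 2)
        assert co_reported_fraction(ds, "nope", dexa) == (0, 0, None)

    def test_co_drug_never_present(self):
        other = DrugSynonymSet.from_names("mannitol")
        ds = self._dataset(10, 0)
        assert co_reported_fraction(ds, "pjp", other) == (10, 0, 0.0)
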