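"""Case/non-case construction and descriptive cohort summaries.

A *case* is a deduplicated report carrying the target drug in the primary
suspect (PS) role; every other report is a *non-case*.  The analysis unit for
disproportionality is the distinct (report, PT) pair.  This module flags
cases, enumerates units, and produces the standard reporting-characteristics
tables (sex, age, reporter, country, outcome, time-to-onset) plus named-drug
co-reporting fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import ReportCase
from .vocabulary import DrugSynonymSet, is_target_drug

__all__ = [
    "AnalysisDataset",
    "flag_cases",
    "summarize_counts",
    "demographic_summary",
    "outcome_summary",
    "tto_summary",
    "co_reported_fraction",
    "OUTCOME_PRIORITY",
    "OUTCOME_LABELS",
    "AGE_BINS",
    "TTO_BINS",
]

#: Seriousness priority used to pick ONE outcome per report.
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention to prevent permanent impairment/damage",
    "OT": "other serious",
}

#: Age bins in years, half-open on the right: [low, high).
AGE_BINS = ((0, 18, "<18"), (18, 45, "18-45"), (45, 65, "45-65"),
            (65, 75, "65-75"), (75, float("inf"), ">=75"))

#: Time-to-onset bins in whole days, half-open on the right.
TTO_BINS = ((0, 7, "<7"), (7, 28, "7-28"), (28, 60, "28-60"),
            (60, float("inf"), ">=60"))

_OCCUPATION_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "CN": "Consumer",
    "RN": "Registered Nurse",
    "LW": "Lawyer",
}


@dataclass
class AnalysisDataset:
    """Flagged reports plus their (report, PT) analysis units.

    ``reports`` has one row per deduplicated report (columns: report_id,
    is_case, sex, age_years, occupation, country, outcomes, tto_days);
    ``units`` one row per distinct (report_id, pt) with the report's case
    flag repeated; ``drugs`` one row per (report_id, drugname, role).
    """

    reports: pd.DataFrame
    units: pd.DataFrame
    drugs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["report_id", "drugname", "role"]))

    @property
    def n_case_reports(self) -> int:
        return int(self.reports["is_case"].sum())

    @property
    def n_noncase_reports(self) -> int:
        return int((~self.reports["is_case"]).sum())

    def case_reports(self) -> pd.DataFrame:
        return self.reports[self.reports["is_case"]]


def _tto_days(report: ReportCase) -> float:
    if report.event_date is None or report.therapy_start_date is None:
        return float("nan")
    days = (report.event_date - report.therapy_start_date).days
    return float(days) if days >= 0 else float("nan")


def flag_cases(reports: Sequence[ReportCase],
               synonyms: DrugSynonymSet) -> AnalysisDataset:
    """Label each report case/non-case and enumerate its analysis units.

    A report is a case iff at least one of its drugs has role ``PS`` and a
    name in the synonym set.  Duplicate PTs within a report contribute a
    single unit; report order does not affect the result.
    """
    rep_rows, unit_rows, drug_rows = [], [], []
    for r in reports:
        is_case = any(role == "PS" and is_target_drug(name, synonyms)
                      for name, role, _seq in r.drugs)
        rep_rows.append({
            "report_id": r.report_id,
            "is_case": is_case,
            "sex": r.sex,
            "age_years": r.age_years if r.age_years is not None else float("nan"),
            "occupation": r.reporter_occupation,
            "country": r.reporter_country,
            "outcomes": tuple(r.outcomes),
            "tto_days": _tto_days(r),
        })
        seen = set()
        for pt in r.events:
            key = pt.strip().casefold()
            if not key or key in seen:
                continue
            seen.add(key)
            unit_rows.append({"report_id": r.report_id, "pt": pt.strip(),
                              "is_case": is_case})
        for name, role, _seq in r.drugs:
            drug_rows.append({"report_id": r.report_id, "drugname": name,
                              "role": role})
    return AnalysisDataset(
        reports=pd.DataFrame(rep_rows, columns=[
            "report_id", "is_case", "sex", "age_years", "occupation",
            "country", "outcomes", "tto_days"]),
        units=pd.DataFrame(unit_rows, columns=["report_id", "pt", "is_case"]),
        drugs=pd.DataFrame(drug_rows, columns=["report_id", "drugname", "role"]),
    )


def summarize_counts(category: str,
                     counts: Mapping[str, int]) -> pd.DataFrame:
    """Turn level counts into a (category, level, count, percentage) table.

    The denominator is the sum of the supplied counts and percentages are
    rounded to two decimals, matching the convention of published FAERS
    characteristic tables.  A zero denominator yields zero percentages.
    """
    total = sum(counts.values())
    rows = [{
        "category": category,
        "level": level,
        "count": int(n),
        "percentage": round(100.0 * n / total, 2) if total else 0.0,
    } for level, n in counts.items()]
    return pd.DataFrame(rows, columns=["category", "level", "count", "percentage"])


def _bin_label(value: float, bins) -> str:
    if np.isnan(value) or value < 0:
        return "unknown"
    for low, high, label in bins:
        if low <= value < high:
            return label
    return "unknown"


def demographic_summary(dataset: AnalysisDataset) -> pd.DataFrame:
    """Sex, age-band, reporter-occupation and country breakdown of the cases.

    Denominator: all case reports; missing values appear as an ``unknown``
    level rather than being excluded.
    """
    cases = dataset.case_reports()
    frames = []

    sex_counts = {level: int((cases["sex"] == level).sum())
                  for level in ("female", "male", "unknown")}
    frames.append(summarize_counts("sex", sex_counts))

    age_labels = [b[2] for b in AGE_BINS] + ["unknown"]
    binned = cases["age_years"].map(lambda v: _bin_label(v, AGE_BINS))
    frames.append(summarize_counts(
        "age", {lab: int((binned == lab).sum()) for lab in age_labels}))

    occ = cases["occupation"].map(
        lambda c: _OCCUPATION_LABELS.get(str(c).upper(), "unknown" if str(c) in
                                         ("unknown", "nan", "") else str(c)))
    occ_counts = occ.value_counts()
    frames.append(summarize_counts("reporter", occ_counts.to_dict()))

    country_counts = cases["country"].fillna("unknown").value_counts()
    frames.append(summarize_counts("country", country_counts.to_dict()))

    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["category", "level", "count", "percentage"])
    return pd.concat(frames, ignore_index=True)


def select_primary_outcome(codes: Iterable[str]) -> str | None:
    """Pick the single most serious outcome code, or None when there is none."""
    present = set(codes)
    for code in OUTCOME_PRIORITY:
        if code in present:
            return code
    return None


def outcome_summary(dataset: AnalysisDataset) -> pd.DataFrame:
    """Outcome distribution of the cases, one outcome per report.

    Each report contributes its single most serious outcome (priority
    DE > LT > HO > DS > CA > RI > OT); reports without any outcome code are
    excluded from the denominator.
    """
    cases = dataset.case_reports()
    primary = cases["outcomes"].map(select_primary_outcome).dropna()
    if primary.empty:
        return pd.DataFrame(columns=["category", "level", "count", "percentage"])
    counts = primary.value_counts()
    ordered = {OUTCOME_LABELS[c]: int(counts.get(c, 0))
               for c in OUTCOME_PRIORITY if counts.get(c, 0) > 0}
    return summarize_counts("outcome", ordered)


def tto_summary(dataset: AnalysisDataset) -> pd.DataFrame:
    """Time-to-onset distribution (event date minus therapy start, days).

    Negative or missing intervals fall in the ``unknown`` level, which is
    part of the denominator alongside the four day bins.
    """
    cases = dataset.case_reports()
    labels = [b[2] for b in TTO_BINS] + ["unknown"]
    binned = cases["tto_days"].map(lambda v: _bin_label(v, TTO_BINS))
    return summarize_counts(
        "tto", {lab: int((binned == lab).sum()) for lab in labels})


def co_reported_fraction(dataset: AnalysisDataset, pt: str,
                         co_drug: DrugSynonymSet) -> tuple[int, int, float | None]:
    """Among case reports with a PT, the share also listing a named co-drug.

    The co-drug may appear in any role.  Returns (number of case reports with
    the PT, number of those also listing the co-drug, percentage rounded to
    one decimal — or ``None`` when the PT does not occur among cases).
    """
    key = pt.strip().casefold()
    units = dataset.units
    with_pt = units[units["is_case"] & (units["pt"].str.strip().str.casefold() == key)]
    pt_report_ids = set(with_pt["report_id"])
    n_cases = len(pt_report_ids)
    if n_cases == 0:
        return 0, 0, None
    drugs = dataset.drugs
    drugs = drugs[drugs["report_id"].isin(pt_report_ids)]
    co_ids = {rid for rid, name in zip(drugs["report_id"], drugs["drugname"])
              if is_target_drug(name, co_drug)}
    n_co = len(co_ids)
    return n_cases, n_co, round(100.0 * n_co / n_cases, 1)
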