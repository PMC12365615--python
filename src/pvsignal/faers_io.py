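"""Reading, writing and deduplicating FAERS-style quarterly ASCII bundles.

The public FAERS quarterly extracts are distributed as a set of ``$``-delimited
text tables (DEMO, DRUG, REAC, OUTC, THER, INDI), one header line per file,
keyed by a report identifier (``primaryid``) and a case identifier (``caseid``).
A safety report may be revised: several report versions then share one case id,
and the FDA recommendation is to keep only the most recent version of each
case.  This module parses the dialect, applies that deduplication rule, and
joins the tables into :class:`ReportCase` records ready for case/non-case
analysis.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FaersFormatError",
    "QuarterBundle",
    "ReportCase",
    "TABLE_NAMES",
    "parse_quarter",
    "read_table",
    "write_quarter",
    "deduplicate",
    "assemble_cases",
    "parse_faers_date",
]

DELIMITER = "$"

#: The six tables of a quarterly bundle, in canonical order.
TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther", "indi")

#: Canonical column names per table.  The report-id column is mandatory
#: everywhere; everything else is optional and passed through.
CANONICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
        "occp_cod", "reporter_country",
    ),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: Header aliases absorbing historical drift in the public files
#: (e.g. the pre-2012 "ISR"/"CASE" keys, "gndr_cod" for sex).
DEFAULT_ALIASES: dict[str, dict[str, str]] = {
    "demo": {"isr": "primaryid", "case": "caseid", "gndr_cod": "sex"},
    "drug": {"isr": "primaryid"},
    "reac": {"isr": "primaryid"},
    "outc": {"isr": "primaryid"},
    "ther": {"isr": "primaryid", "drug_seq": "dsg_drug_seq"},
    "indi": {"isr": "primaryid", "drug_seq": "indi_drug_seq"},
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class FaersFormatError(ValueError):
    """A quarterly file violates the expected dialect."""


@dataclass
class QuarterBundle:
    """One quarter's worth of raw tables, as parsed (all values are strings)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    quarter_label: str = ""

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class ReportCase:
    """One deduplicated safety report, joined across the quarterly tables."""

    report_id: str
    case_id: str
    receipt_date: _dt.date | None
    sex: str  # "female" | "male" | "unknown"
    age_value: float | None
    age_unit: str  # year|month|week|day|decade|hour|unknown
    reporter_occupation: str
    reporter_country: str
    drugs: list[tuple[str, str, int]]  # (name, role, sequence)
    events: list[str]
    outcomes: list[str]
    event_date: _dt.date | None = None
    therapy_start_date: _dt.date | None = None

    @property
    def age_years(self) -> float | None:
        """Age converted to years; ``None`` when value or unit is unknown."""
        if self.age_value is None:
            return None
        factor = {
            "year": 1.0, "month": 1 / 12, "week": 1 / 52,
            "day": 1 / 365.25, "decade": 10.0, "hour": 1 / 8766,
        }.get(self.age_unit)
        return None if factor is None else self.age_value * factor


def parse_faers_date(raw: str | None) -> _dt.date | None:
    """Parse a FAERS date field (YYYYMMDD, YYYYMM or YYYY).

    Partial dates resolve to the first day of the stated period, which keeps
    time-to-onset computable while erring on the long side.  Anything that is
    not a valid calendar date returns ``None``.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 1)
        if len(s) == 4:
            return _dt.date(int(s), 1, 1)
    except ValueError:
        return None
    return None


def _resolve_columns(columns: Sequence[str], table: str,
                     aliases: Mapping[str, str] | None = None) -> list[str]:
    table_aliases = dict(DEFAULT_ALIASES.get(table, {}))
    if aliases:
        table_aliases.update({k.lower(): v for k, v in aliases.items()})
    out = []
    for col in columns:
        key = col.strip().lower()
        out.append(table_aliases.get(key, key))
    return out


def read_table(path: str | Path, table: str,
               aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one ``$``-delimited table; empty fields become missing values."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=DELIMITER, dtype=str, engine="c",
            keep_default_na=False, na_values=[""],
            quoting=3,  # QUOTE_NONE: the public files are unquoted
        )
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise FaersFormatError(f"{path.name}: unreadable line ({exc})") from exc
    df.columns = _resolve_columns(df.columns, table, aliases)
    if "primaryid" not in df.columns:
        raise FaersFormatError(
            f"{path.name}: mandatory report-id column 'primaryid' missing "
            f"(found columns: {list(df.columns)})"
        )
    return df


def parse_quarter(file_paths: Mapping[str, str | Path],
                  quarter_label: str = "",
                  aliases: Mapping[str, Mapping[str, str]] | None = None) -> QuarterBundle:
    """Parse one quarterly bundle from a table-name → path mapping.

    Tables absent from ``file_paths`` come back empty.  ``aliases`` maps
    table name → {observed header: canonical header} for dialect drift.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        if name in file_paths:
            tables[name] = read_table(
                file_paths[name], name,
                aliases.get(name) if aliases else None,
            )
        else:
            tables[name] = pd.DataFrame(columns=list(CANONICAL_COLUMNS[name]))
    return QuarterBundle(quarter_label=quarter_label, **tables)


def write_quarter(bundle: QuarterBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle in the ``$``-delimited dialect; byte-stable per bundle.

    Files are named ``<table>.txt``.  Missing values are written as empty
    fields; rows keep their frame order, so a deterministic bundle yields
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        df = bundle.table(name)
        path = directory / f"{name}.txt"
        df.to_csv(path, sep=DELIMITER, index=False, na_rep="",
                  lineterminator="\n")
        paths[name] = path
    return paths


def _id_sort_key(series: pd.Series) -> pd.Series:
    """Numeric ordering for ids when possible, lexicographic otherwise."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric
    return series.astype(str)


def deduplicate(demo: pd.DataFrame) -> tuple[set[str], int]:
    """Keep one report per case: latest receipt date, ties to largest id.

    Returns the retained ``primaryid`` set and the count of records dropped
    for lacking a ``caseid``.  Deterministic, idempotent and independent of
    input row order.
    """
    if demo.empty:
        return set(), 0
    df = demo.copy()
    has_case = df["caseid"].notna() if "caseid" in df.columns else pd.Series(False, index=df.index)
    n_missing_case = int((~has_case).sum())
    df = df[has_case]
    if df.empty:
        return set(), n_missing_case
    df = df.assign(
        _dt=df["fda_dt"].fillna("") if "fda_dt" in df.columns else "",
        _idkey=_id_sort_key(df["primaryid"]),
    )
    df = df.sort_values(["caseid", "_dt", "_idkey"], kind="mergesort")
    retained = df.groupby("caseid", sort=False).tail(1)["primaryid"]
    return set(retained), n_missing_case


_SEX_MAP = {"F": "female", "M": "male"}
_AGE_UNIT_MAP = {"YR": "year", "MON": "month", "WK": "week", "DY": "day",
                 "DEC": "decade", "HR": "hour"}


def _clean_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    s = str(value).strip()
    return s or None


def assemble_cases(bundles: Iterable[QuarterBundle]) -> tuple[list[ReportCase], Counter]:
    """Join the tables of one or more quarters into deduplicated reports.

    Deduplication runs jointly across all supplied quarters (a case revised in
    a later quarter supersedes earlier versions).  Cleaning drops empty or
    whitespace-only event terms, removes any event that exactly matches an
    indication recorded for the same report (case-insensitively), and finally
    drops reports left with no events.  Demographic blanks are retained as
    "unknown" levels rather than dropped.  Every removal is tallied.
    """
    bundles = list(bundles)
    tally: Counter = Counter()

    def _concat(name: str) -> pd.DataFrame:
        frames = [b.table(name) for b in bundles if not b.table(name).empty]
        if not frames:
            return pd.DataFrame(columns=list(CANONICAL_COLUMNS[name]))
        return pd.concat(frames, ignore_index=True)

    demo = _concat("demo")
    retained, n_missing_case = deduplicate(demo)
    tally["demo_records"] = len(demo)
    tally["missing_case_id"] = n_missing_case
    tally["duplicate_versions_removed"] = len(demo) - n_missing_case - len(retained)
    if not retained:
        return [], tally

    demo_kept = demo[demo["primaryid"].isin(retained)]
    # last occurrence wins if a primaryid is repeated verbatim across quarters
    demo_kept = demo_kept.drop_duplicates(subset="primaryid", keep="last")

    def _grouped(name: str, columns: Sequence[str]) -> dict[str, pd.DataFrame]:
        df = _concat(name)
        if df.empty:
            return {}
        known = df["primaryid"].isin(retained)
        tally[f"orphan_{name}_records"] += int((~known).sum())
        df = df[known]
        return {pid: g for pid, g in df.groupby("primaryid", sort=False)}

    drug_by_id = _grouped("drug", CANONICAL_COLUMNS["drug"])
    reac_by_id = _grouped("reac", CANONICAL_COLUMNS["reac"])
    outc_by_id = _grouped("outc", CANONICAL_COLUMNS["outc"])
    ther_by_id = _grouped("ther", CANONICAL_COLUMNS["ther"])
    indi_by_id = _grouped("indi", CANONICAL_COLUMNS["indi"])

    cases: list[ReportCase] = []
    for row in demo_kept.itertuples(index=False):
        rec = row._asdict()
        pid = rec["primaryid"]

        events: list[str] = []
        seen = set()
        for raw in (reac_by_id.get(pid, pd.DataFrame()).get("pt", pd.Series(dtype=str))):
            term = _clean_str(raw)
            if term is None:
                tally["blank_event_terms"] += 1
                continue
            if term.lower() in seen:
                continue
            seen.add(term.lower())
            events.append(term)

        indications = set()
        ind = indi_by_id.get(pid)
        if ind is not None and "indi_pt" in ind.columns:
            for raw in ind["indi_pt"]:
                term = _clean_str(raw)
                if term is not None:
                    indications.add(term.lower())
        if indications:
            kept_events = [e for e in events if e.lower() not in indications]
            tally["indication_filtered_events"] += len(events) - len(kept_events)
            events = kept_events

        if not events:
            tally["zero_event_reports"] += 1
            continue

        drugs: list[tuple[str, str, int]] = []
        dr = drug_by_id.get(pid)
        if dr is not None:
            for i, drow in enumerate(dr.itertuples(index=False)):
                d = drow._asdict()
                name = _clean_str(d.get("drugname"))
                if name is None:
                    tally["blank_drug_names"] += 1
                    continue
                role = _clean_str(d.get("role_cod")) or ""
                role = role.upper() if role.upper() in ROLE_CODES else "C"
                try:
                    seq = int(str(d.get("drug_seq")))
                except (TypeError, ValueError):
                    seq = i + 1
                drugs.append((name, role, seq))

        outcomes: list[str] = []
        oc = outc_by_id.get(pid)
        if oc is not None and "outc_cod" in oc.columns:
            for raw in oc["outc_cod"]:
                code = (_clean_str(raw) or "").upper()
                if code in OUTCOME_CODES:
                    if code not in outcomes:
                        outcomes.append(code)
                elif code:
                    tally["unknown_outcome_codes"] += 1

        start_date = None
        th = ther_by_id.get(pid)
        if th is not None and "start_dt" in th.columns:
            starts = [parse_faers_date(v) for v in th["start_dt"]]
            starts = [s for s in starts if s is not None]
            if starts:
                start_date = min(starts)

        age_raw = _clean_str(rec.get("age"))
        try:
            age_value = float(age_raw) if age_raw is not None else None
        except ValueError:
            age_value = None
        age_unit = _AGE_UNIT_MAP.get((_clean_str(rec.get("age_cod")) or "").upper(),
                                     "unknown")
        if age_value is None:
            age_unit = "unknown"

        cases.append(ReportCase(
            report_id=str(pid),
            case_id=str(rec.get("caseid")),
            receipt_date=parse_faers_date(rec.get("fda_dt")),
            sex=_SEX_MAP.get((_clean_str(rec.get("sex")) or "").upper(), "unknown"),
            age_value=age_value,
            age_unit=age_unit,
            reporter_occupation=_clean_str(rec.get("occp_cod")) or "unknown",
            reporter_country=_clean_str(rec.get("reporter_country")) or "unknown",
            drugs=drugs,
            events=events,
            outcomes=outcomes,
            event_date=parse_faers_date(rec.get("event_dt")),
            therapy_start_date=start_date,
        ))

    tally["retained_reports"] = len(cases)
    return cases, tally
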