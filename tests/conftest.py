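import datetime as dt

import pandas as pd
import pytest

from pvsignal.faers_io import QuarterBundle, ReportCase
from pvsignal.vocabulary import DrugSynonymSet, PtSocMap


def write_delim(path, header, rows):
    """Write one $-delimited table file."""
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def target_synonyms():
    return DrugSynonymSet.from_names("temozolomide", "temodar", "temodal")


@pytest.fixture
def tiny_soc_map():
    return PtSocMap({"pt_0007": "soc_blood", "nausea": "soc_gastro",
                     "petechiae": "soc_blood"}, version_label="test")


def make_report(report_id="1", drugs=(("temozolomide", "PS", 1),),
                events=("nausea",), outcomes=(), sex="male",
                age_value=55.0, age_unit="year", occupation="MD",
                country="US", event_date=None, start_date=None,
                case_id=None, receipt=dt.date(2023, 1, 1)):
    return ReportCase(
        report_id=str(report_id),
        case_id=str(case_id if case_id is not None else report_id),
        receipt_date=receipt,
        sex=sex, age_value=age_value, age_unit=age_unit,
        reporter_occupation=occupation, reporter_country=country,
        drugs=list(drugs), events=list(events), outcomes=list(outcomes),
        event_date=event_date, therapy_start_date=start_date,
    )


@pytest.fixture
def make_bundle():
    """Factory for in-memory QuarterBundles from simple row dicts."""
    def _make(demo_rows, drug_rows=(), reac_rows=(), outc_rows=(),
              ther_rows=(), indi_rows=(), label="2023Q1"):
        def frame(rows, cols):
            return pd.DataFrame(list(rows), columns=cols, dtype=str)
        return QuarterBundle(
            demo=frame(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt",
                                   "sex", "age", "age_cod", "occp_cod",
                                   "reporter_country"]),
            drug=frame(drug_rows, ["primaryid", "drug_seq", "role_cod", "drugname"]),
            reac=frame(reac_rows, ["primaryid", "pt"]),
            outc=frame(outc_rows, ["primaryid", "outc_cod"]),
            ther=frame(ther_rows, ["primaryid", "dsg_drug_seq", "start_dt"]),
            indi=frame(indi_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
            quarter_label=label,
        )
    return _make
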