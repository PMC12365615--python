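"""Synthetic FAERS-like report generator with planted ground truth.

The generator emulates the structural features of the public quarterly
extracts that the pipeline must survive — multi-table reports keyed by
case/report ids, revised case versions (duplicates), a primary-suspect role
code, several PT events per report, outcome codes, therapy and event dates,
field-level missingness — while keeping a known ground truth: selected
(drug, PT) pairs are planted with a *reporting-odds multiplier*.

Event generation uses two channels:

* every report draws ``1 + Poisson(events_per_report − 1)`` background events
  from a Zipf-like categorical over the non-planted PTs (identical for cases
  and non-cases, so every background pair has true odds ratio exactly 1);
* each planted PT is included independently per report with baseline odds
  ``q/(1−q)`` multiplied by the pair's multiplier when the report's primary
  suspect drug matches.  The planted multiplier is therefore *exactly* the
  report-level odds ratio that the ROR estimates, which makes null
  calibration and parameter recovery well-defined.

Planted PTs are excluded from the background channel so the two channels
cannot dilute each other.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisDataset
from .faers_io import QuarterBundle, write_quarter
from .vocabulary import DrugSynonymSet, PtSocMap

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "simulate_dataset",
    "write_bundles",
    "write_truth",
    "default_synonyms",
    "default_pt_soc_map",
    "write_vocabulary_files",
]

_OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT", "none")


def _default_outcome_dist() -> dict[str, float]:
    # roughly the outcome mix of large oncology cohorts in FAERS, plus a
    # slice of reports that carry no outcome code at all
    return {"HO": 0.32, "OT": 0.31, "DE": 0.20, "LT": 0.05, "DS": 0.015,
            "RI": 0.003, "CA": 0.001, "none": 0.101}


def _default_missingness() -> dict[str, float]:
    return {"sex": 0.05, "age": 0.15, "occupation": 0.12, "country": 0.02,
            "event_date": 0.35, "therapy_start_date": 0.35}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic reporting stream.

    ``rate_multipliers`` maps ``(drug_name, pt_name)`` to the planted
    reporting-odds multiplier (1 = null).  ``seed`` fully determines the
    output.
    """

    n_reports: int = 50_000
    n_drugs: int = 20
    n_pts: int = 100
    target_drug_share: float = 0.10
    events_per_report: float = 2.0
    rate_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    signal_base_rate: float = 0.01
    duplicate_rate: float = 0.0
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    outcome_dist: dict[str, float] = field(default_factory=_default_outcome_dist)
    tto_log_mean: float = 3.4   # median ≈ 30 days
    tto_log_sigma: float = 1.0
    zipf_exponent: float = 1.0
    concomitant_mean: float = 1.0
    indication_term: str = "indication_primary"
    indication_as_event_rate: float = 0.01
    p_male: float = 0.54
    year: int = 2023
    n_quarters: int = 4
    target_drug_name: str = "drug_target"
    seed: int = 0

    def __post_init__(self):
        for name, p in [("target_drug_share", self.target_drug_share),
                        ("signal_base_rate", self.signal_base_rate),
                        ("duplicate_rate", self.duplicate_rate),
                        ("indication_as_event_rate", self.indication_as_event_rate),
                        ("p_male", self.p_male),
                        *self.missingness.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.events_per_report < 1.0:
            raise ValueError("events_per_report must be ≥ 1 (reports need an event)")
        if abs(sum(self.outcome_dist.values()) - 1.0) > 1e-9:
            raise ValueError("outcome_dist must sum to 1")
        if set(self.outcome_dist) - set(_OUTCOME_CODES):
            raise ValueError(f"unknown outcome codes: {set(self.outcome_dist) - set(_OUTCOME_CODES)}")
        pts = set(self.pt_names())
        drugs = set(self.drug_names()) | {self.target_drug_name}
        for (drug, pt), m in self.rate_multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for ({drug}, {pt}) must be > 0")
            if pt not in pts:
                raise ValueError(f"multiplier names unknown PT {pt!r}")
            if drug not in drugs:
                raise ValueError(f"multiplier names unknown drug {drug!r}")
        planted = {pt for _, pt in self.rate_multipliers}
        if len(planted) >= self.n_pts:
            raise ValueError("at least one PT must remain for the background channel")
        if not 1 <= self.n_quarters <= 4:
            raise ValueError("n_quarters must be in 1..4")

    def drug_names(self) -> list[str]:
        return [f"drug_{i:04d}" for i in range(1, self.n_drugs + 1)]

    def pt_names(self) -> list[str]:
        return [f"pt_{i:04d}" for i in range(1, self.n_pts + 1)]


@dataclass
class GroundTruth:
    """What was planted: multipliers and exact pre-duplication counts."""

    n_reports: int
    n_case_reports: int
    n_noncase_reports: int
    multipliers: dict[tuple[str, str], float]
    #: implied per-report inclusion probability of each planted PT,
    #: (baseline, under-multiplier)
    planted_probs: dict[tuple[str, str], tuple[float, float]]

    def true_odds_ratio(self, drug: str, pt: str) -> float:
        return self.multipliers.get((drug, pt), 1.0)


# ---------------------------------------------------------------------------
# core simulation


def _simulate_core(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    n = cfg.n_reports
    drug_names = np.array([cfg.target_drug_name] + cfg.drug_names())
    pt_names = np.array(cfg.pt_names())
    n_all_drugs = len(drug_names)

    is_case = rng.random(n) < cfg.target_drug_share
    ps_drug = np.where(is_case, 0,
                       rng.integers(1, n_all_drugs, size=n))

    planted_pts = sorted({pt for _, pt in cfg.rate_multipliers})
    planted_idx = {pt: i for i, pt in
                   enumerate(pt for pt in pt_names if pt in set(planted_pts))}
    pt_index = {pt: i for i, pt in enumerate(pt_names)}
    bg_idx = np.array([i for i, pt in enumerate(pt_names)
                       if pt not in planted_idx], dtype=np.int64)
    ranks = np.arange(1, len(bg_idx) + 1, dtype=float)
    w = 1.0 / ranks ** cfg.zipf_exponent
    w /= w.sum()

    # background events: shifted-Poisson count per report, Zipf categorical
    k = 1 + rng.poisson(cfg.events_per_report - 1.0, size=n)
    total = int(k.sum())
    bg_draws = rng.choice(bg_idx, size=total, p=w)
    bg_report = np.repeat(np.arange(n), k)

    # planted events: independent Bernoulli with odds multiplied per PS drug
    sig_report_parts, sig_pt_parts = [], []
    q = cfg.signal_base_rate
    planted_probs: dict[tuple[str, str], tuple[float, float]] = {}
    for pt in planted_pts:
        j = pt_index[pt]
        prob = np.full(n, q)
        for (drug, ppt), m in cfg.rate_multipliers.items():
            if ppt != pt or m == 1.0:
                continue
            didx = int(np.where(drug_names == drug)[0][0])
            qm = m * q / (1.0 + (m - 1.0) * q)
            prob[ps_drug == didx] = qm
            planted_probs[(drug, pt)] = (q, qm)
        hit = rng.random(n) < prob
        sig_report_parts.append(np.where(hit)[0])
        sig_pt_parts.append(np.full(int(hit.sum()), j, dtype=np.int64))

    ev_report = np.concatenate([bg_report] + sig_report_parts)
    ev_pt = np.concatenate([bg_draws] + sig_pt_parts)
    # distinct (report, pt) units
    key = ev_report * len(pt_names) + ev_pt
    key = np.unique(key)
    unit_report = key // len(pt_names)
    unit_pt = key % len(pt_names)

    # concomitant drugs (role C), any drug including the target
    n_con = rng.poisson(cfg.concomitant_mean, size=n)
    con_report = np.repeat(np.arange(n), n_con)
    con_drug = rng.integers(0, n_all_drugs, size=int(n_con.sum()))

    # demographics
    miss = cfg.missingness
    sex = np.where(rng.random(n) < cfg.p_male, "M", "F")
    sex = np.where(rng.random(n) < miss.get("sex", 0.0), "", sex)
    age = np.clip(np.round(rng.normal(56.0, 18.0, size=n)), 0, 95)
    age_known = rng.random(n) >= miss.get("age", 0.0)
    occ_codes = np.array(["MD", "PH", "OT", "CN", "RN"])
    occ = occ_codes[rng.choice(len(occ_codes), size=n,
                               p=[0.36, 0.32, 0.16, 0.145, 0.015])]
    occ = np.where(rng.random(n) < miss.get("occupation", 0.0), "", occ)
    countries = np.array(["US", "JP", "CA", "FR", "DE", "GB", "IT", "CN", "XX"])
    country = countries[rng.choice(len(countries), size=n,
                                   p=[0.52, 0.05, 0.04, 0.04, 0.03, 0.03,
                                      0.02, 0.02, 0.25])]
    country = np.where(rng.random(n) < miss.get("country", 0.0), "", country)

    # outcomes: one primary code per report (possibly none)
    codes = list(cfg.outcome_dist)
    probs = np.array([cfg.outcome_dist[c] for c in codes])
    outcome = np.array(codes)[rng.choice(len(codes), size=n, p=probs)]

    # dates: receipt uniform over the configured quarters of one year
    q_starts = [1, 4, 7, 10][: cfg.n_quarters]
    month = np.array(q_starts)[rng.integers(0, cfg.n_quarters, size=n)]
    month = month + rng.integers(0, 3, size=n)
    day = rng.integers(1, 29, size=n)
    receipt = np.array([_dt.date(cfg.year, int(m), int(d)).toordinal()
                        for m, d in zip(month, day)], dtype=np.int64)
    tto = np.round(rng.lognormal(cfg.tto_log_mean, cfg.tto_log_sigma, size=n))
    tto = np.clip(tto, 0, 2000).astype(np.int64)
    start = receipt - tto - rng.integers(5, 40, size=n)
    event = start + tto
    event_known = rng.random(n) >= miss.get("event_date", 0.0)
    start_known = rng.random(n) >= miss.get("therapy_start_date", 0.0)

    indication_event = rng.random(n) < cfg.indication_as_event_rate

    n_case = int(is_case.sum())
    truth = GroundTruth(
        n_reports=n, n_case_reports=n_case, n_noncase_reports=n - n_case,
        multipliers=dict(cfg.rate_multipliers), planted_probs=planted_probs,
    )
    return {
        "drug_names": drug_names, "pt_names": pt_names,
        "is_case": is_case, "ps_drug": ps_drug,
        "unit_report": unit_report, "unit_pt": unit_pt,
        "con_report": con_report, "con_drug": con_drug,
        "sex": sex, "age": age, "age_known": age_known,
        "occ": occ, "country": country, "outcome": outcome,
        "receipt": receipt, "start": start, "event": event, "tto": tto,
        "event_known": event_known, "start_known": start_known,
        "indication_event": indication_event,
        "truth": truth,
    }


def simulate_dataset(cfg: GeneratorConfig,
                     demographics: bool = True,
                     ) -> tuple[AnalysisDataset, GroundTruth]:
    """Simulate straight to a flagged :class:`AnalysisDataset`.

    Bypasses the ASCII round trip (no duplicate versions, no missingness in
    the id/date join keys) and is the fast path for simulation studies; the
    event-generation core is shared with :func:`generate`.
    """
    rng = np.random.default_rng(cfg.seed)
    core = _simulate_core(cfg, rng)
    n = cfg.n_reports
    report_ids = np.arange(n, dtype=np.int64)

    units = pd.DataFrame({
        "report_id": core["unit_report"],
        "pt": core["pt_names"][core["unit_pt"]],
        "is_case": core["is_case"][core["unit_report"]],
    })
    if demographics:
        tto_days = np.where(core["event_known"] & core["start_known"],
                            core["tto"].astype(float), np.nan)
        outcomes = [(o,) if o != "none" else () for o in core["outcome"]]
        reports = pd.DataFrame({
            "report_id": report_ids,
            "is_case": core["is_case"],
            "sex": np.where(core["sex"] == "M", "male",
                            np.where(core["sex"] == "F", "female", "unknown")),
            "age_years": np.where(core["age_known"], core["age"], np.nan),
            "occupation": np.where(core["occ"] == "", "unknown", core["occ"]),
            "country": np.where(core["country"] == "", "unknown", core["country"]),
            "outcomes": outcomes,
            "tto_days": tto_days,
        })
    else:
        reports = pd.DataFrame({
            "report_id": report_ids,
            "is_case": core["is_case"],
        })

    ps = pd.DataFrame({
        "report_id": report_ids,
        "drugname": core["drug_names"][core["ps_drug"]],
        "role": "PS",
    })
    con = pd.DataFrame({
        "report_id": core["con_report"],
        "drugname": core["drug_names"][core["con_drug"]],
        "role": "C",
    })
    drugs = pd.concat([ps, con], ignore_index=True)
    return AnalysisDataset(reports=reports, units=units, drugs=drugs), core["truth"]


def _date_str(ordinals: np.ndarray) -> list[str]:
    return [_dt.date.fromordinal(int(o)).strftime("%Y%m%d") for o in ordinals]


def generate(cfg: GeneratorConfig) -> tuple[list[QuarterBundle], GroundTruth]:
    """Generate quarterly ASCII-style bundles plus the ground-truth record.

    Case ids are ``100000 + i``; report (primary) ids are ``caseid*10 +
    version`` so a revised case's latest version has both the larger id and
    the later receipt date.  With ``duplicate_rate > 0``, extra earlier
    versions of some cases are emitted (possibly in an earlier quarter), and
    FDA-rule deduplication recovers exactly the pre-duplication reports.
    """
    rng = np.random.default_rng(cfg.seed)
    core = _simulate_core(cfg, rng)
    n = cfg.n_reports
    caseid = 100_000 + np.arange(n, dtype=np.int64)
    primaryid = caseid * 10 + 1

    # duplicate (superseded) versions with earlier dates and smaller ids
    dup_mask = rng.random(n) < cfg.duplicate_rate
    dup_idx = np.where(dup_mask)[0]
    dup_primaryid = caseid[dup_idx] * 10
    dup_receipt = core["receipt"][dup_idx] - rng.integers(20, 120, size=dup_idx.size)
    jan1 = _dt.date(cfg.year, 1, 1).toordinal()
    dup_receipt = np.maximum(dup_receipt, jan1)

    def col(values, known=None):
        out = np.asarray(values, dtype=object)
        if known is not None:
            out = np.where(known, out, "")
        return out

    demo = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid.astype(str),
        "fda_dt": _date_str(core["receipt"]),
        "event_dt": col(_date_str(core["event"]), core["event_known"]),
        "sex": core["sex"],
        "age": col(np.char.mod("%d", core["age"].astype(int)), core["age_known"]),
        "age_cod": col(np.full(n, "YR"), core["age_known"]),
        "occp_cod": core["occ"],
        "reporter_country": core["country"],
    })
    if dup_idx.size:
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["primaryid"] = dup_primaryid.astype(str)
        dup_demo["fda_dt"] = _date_str(dup_receipt)
        demo = pd.concat([demo, dup_demo], ignore_index=True)

    target_spellings = np.array(
        [cfg.target_drug_name, cfg.target_drug_name.upper(),
         cfg.target_drug_name.title() + " "])
    all_names = core["drug_names"]

    def drug_display(idx: np.ndarray, r: np.ndarray) -> np.ndarray:
        names = all_names[idx].astype(object)
        is_target = idx == 0
        spell = target_spellings[rng.integers(0, len(target_spellings),
                                              size=len(idx))]
        return np.where(is_target, spell, names)

    ps_names = drug_display(core["ps_drug"], rng)
    drug_frames = [pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "drug_seq": "1",
        "role_cod": "PS",
        "drugname": ps_names,
    })]
    if core["con_report"].size:
        con_names = drug_display(core["con_drug"], rng)
        drug_frames.append(pd.DataFrame({
            "primaryid": primaryid[core["con_report"]].astype(str),
            "drug_seq": "2",
            "role_cod": "C",
            "drugname": con_names,
        }))
    drug = pd.concat(drug_frames, ignore_index=True)

    reac = pd.DataFrame({
        "primaryid": primaryid[core["unit_report"]].astype(str),
        "pt": core["pt_names"][core["unit_pt"]],
    })
    ind_ev = np.where(core["indication_event"])[0]
    if ind_ev.size:
        reac = pd.concat([reac, pd.DataFrame({
            "primaryid": primaryid[ind_ev].astype(str),
            "pt": cfg.indication_term,
        })], ignore_index=True)

    has_outcome = core["outcome"] != "none"
    outc = pd.DataFrame({
        "primaryid": primaryid[has_outcome].astype(str),
        "outc_cod": core["outcome"][has_outcome],
    })
    ther = pd.DataFrame({
        "primaryid": primaryid[core["start_known"]].astype(str),
        "dsg_drug_seq": "1",
        "start_dt": _date_str(core["start"][core["start_known"]]),
    })
    indi = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "indi_drug_seq": "1",
        "indi_pt": cfg.indication_term,
    })
    if dup_idx.size:
        dup_ids = set(dup_primaryid.astype(str))
        orig_ids = primaryid[dup_idx].astype(str)
        remap = dict(zip(orig_ids, dup_primaryid.astype(str)))

        def duplicate_rows(df: pd.DataFrame) -> pd.DataFrame:
            part = df[df["primaryid"].isin(remap)].copy()
            part["primaryid"] = part["primaryid"].map(remap)
            return part

        drug = pd.concat([drug, duplicate_rows(drug)], ignore_index=True)
        reac = pd.concat([reac, duplicate_rows(reac)], ignore_index=True)
        outc = pd.concat([outc, duplicate_rows(outc)], ignore_index=True)
        ther = pd.concat([ther, duplicate_rows(ther)], ignore_index=True)
        indi = pd.concat([indi, duplicate_rows(indi)], ignore_index=True)

    # split into quarters by receipt date
    def quarter_of(fda_dt: pd.Series) -> pd.Series:
        months = fda_dt.str.slice(4, 6).astype(int)
        return (months - 1) // 3 + 1

    demo = demo.assign(_q=quarter_of(demo["fda_dt"]))
    id_to_q = dict(zip(demo["primaryid"], demo["_q"]))
    bundles = []
    for qn in range(1, cfg.n_quarters + 1):
        label = f"{cfg.year}Q{qn}"
        d = demo[demo["_q"] == qn].drop(columns="_q").sort_values(
            "primaryid", kind="mergesort").reset_index(drop=True)
        ids = set(d["primaryid"])

        def pick(df: pd.DataFrame) -> pd.DataFrame:
            return (df[df["primaryid"].isin(ids)]
                    .sort_values("primaryid", kind="mergesort")
                    .reset_index(drop=True))

        bundles.append(QuarterBundle(
            demo=d, drug=pick(drug), reac=pick(reac), outc=pick(outc),
            ther=pick(ther), indi=pick(indi), quarter_label=label,
        ))
    return bundles, core["truth"]


def write_bundles(bundles: Sequence[QuarterBundle],
                  directory: str | Path) -> list[Path]:
    """Write each bundle into ``directory/<quarter_label>/``."""
    directory = Path(directory)
    out = []
    for b in bundles:
        sub = directory / (b.quarter_label or "quarter")
        write_quarter(b, sub)
        out.append(sub)
    return out


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Sidecar TSV with the planted multipliers and exact counts."""
    path = Path(path)
    rows = [{"drug": d, "pt": p, "multiplier": m,
             "true_odds_ratio": truth.true_odds_ratio(d, p)}
            for (d, p), m in sorted(truth.multipliers.items())]
    header = pd.DataFrame(rows, columns=["drug", "pt", "multiplier",
                                         "true_odds_ratio"])
    with open(path, "w") as fh:
        fh.write(f"# n_reports={truth.n_reports}\t"
                 f"n_case_reports={truth.n_case_reports}\t"
                 f"n_noncase_reports={truth.n_noncase_reports}\n")
        header.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def default_synonyms(cfg: GeneratorConfig) -> DrugSynonymSet:
    """Synonym set matching every spelling the generator emits for the target."""
    base = cfg.target_drug_name
    return DrugSynonymSet.from_names(base, base.upper(), base.title())


def default_pt_soc_map(cfg: GeneratorConfig, n_socs: int = 10) -> PtSocMap:
    """Round-robin PT → SOC assignment over ``n_socs`` synthetic classes."""
    entries = {pt: f"soc_{(i % n_socs) + 1:02d}"
               for i, pt in enumerate(cfg.pt_names())}
    return PtSocMap(entries, version_label="synthetic")


def write_vocabulary_files(cfg: GeneratorConfig,
                           directory: str | Path) -> tuple[Path, Path]:
    """Write the synonym list and PT→SOC TSV the pipeline config points at."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    syn_path = directory / "target_synonyms.txt"
    syn_path.write_text("\n".join([cfg.target_drug_name,
                                   cfg.target_drug_name.upper(),
                                   cfg.target_drug_name.title()]) + "\n")
    soc_path = directory / "pt_soc_map.tsv"
    m = default_pt_soc_map(cfg)
    pd.DataFrame(sorted(m.entries.items()), columns=["pt", "soc"]).to_csv(
        soc_path, sep="\t", index=False, lineterminator="\n")
    return syn_path, soc_path
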