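"""End-to-end orchestration: parse → dedup → assemble → flag → score → export.

A run is described by one declarative YAML config::

    input_dir: path with one subdirectory per quarter (demo.txt, drug.txt, ...)
    synonym_file: one drug name per line, canonical first
    pt_soc_file: 2-column TSV (pt, soc)
    output_dir: where the TSV outputs and run log are written
    thresholds: {min_a: 3, min_ror: 2, min_ror_ci_low: 1, min_chisq: 4,
                 min_ic_2sd: 0}           # optional, defaults shown
    zero_correction: false                # Haldane–Anscombe +0.5 on zero cells
    denominator: reports                  # or "units"
    fit_mgps_prior: true

Outputs: ``descriptive_summary.tsv``, ``soc_signals.tsv``, ``pt_signals.tsv``,
``volcano.tsv`` and ``run_log.txt`` (dropped-record tallies and every active
setting).  Given fixed inputs and config the outputs are byte-stable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, disproportionality as dp, signal_report
from .faers_io import TABLE_NAMES, assemble_cases, parse_quarter
from .vocabulary import DrugSynonymSet, PtSocMap

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    input_dir: Path
    synonym_file: Path
    pt_soc_file: Path
    output_dir: Path
    thresholds: dp.SignalThresholds = field(default_factory=dp.SignalThresholds)
    zero_correction: bool = False
    denominator: str = "reports"
    fit_mgps_prior: bool = True

    def validate(self) -> None:
        for name in ("input_dir", "synonym_file", "pt_soc_file"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"config: {name} does not exist: {p}")
        if self.denominator not in ("reports", "units"):
            raise PipelineError("config: denominator must be 'reports' or 'units'")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PipelineError(f"config: {path} is not a mapping")
    thresholds = dp.SignalThresholds(**raw.pop("thresholds", {}) or {})
    try:
        return RunConfig(
            input_dir=Path(raw.pop("input_dir")),
            synonym_file=Path(raw.pop("synonym_file")),
            pt_soc_file=Path(raw.pop("pt_soc_file")),
            output_dir=Path(raw.pop("output_dir")),
            thresholds=thresholds,
            **raw,
        )
    except KeyError as exc:
        raise PipelineError(f"config: missing required key {exc}") from exc


def _discover_quarters(input_dir: Path) -> list[dict[str, Path]]:
    quarters = []
    for sub in sorted(p for p in Path(input_dir).iterdir() if p.is_dir()):
        paths = {name: sub / f"{name}.txt" for name in TABLE_NAMES
                 if (sub / f"{name}.txt").exists()}
        if "demo" in paths:
            quarters.append({"label": sub.name, **paths})
    if not quarters:
        raise PipelineError(f"parse: no quarter subdirectories with demo.txt under {input_dir}")
    return quarters


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns the paths of every written output."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log("settings:")
    log(f"  thresholds: {dataclasses.asdict(config.thresholds)}")
    log(f"  zero_correction: {config.zero_correction}")
    log(f"  denominator: {config.denominator}")
    log(f"  fit_mgps_prior: {config.fit_mgps_prior}")
    log("  dedup rule: one report per case id, latest receipt date, "
        "ties to largest report id")
    log("  indication filter: event PTs equal to a same-report indication "
        "PT are removed")

    try:
        synonyms = DrugSynonymSet.from_file(config.synonym_file)
        soc_map = PtSocMap.from_tsv(config.pt_soc_file)
    except Exception as exc:
        raise PipelineError(f"vocabulary: {exc}") from exc

    try:
        quarter_paths = _discover_quarters(config.input_dir)
        bundles = [parse_quarter({k: v for k, v in q.items() if k != "label"},
                                 quarter_label=q["label"])
                   for q in quarter_paths]
        log(f"parsed quarters: {[q['label'] for q in quarter_paths]}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"parse: {exc}") from exc

    try:
        reports, tally = assemble_cases(bundles)
        for key in sorted(tally):
            log(f"tally {key}: {tally[key]}")
    except Exception as exc:
        raise PipelineError(f"assemble: {exc}") from exc

    try:
        dataset = cohort.flag_cases(reports, synonyms)
        log(f"case reports: {dataset.n_case_reports}; "
            f"non-case reports: {dataset.n_noncase_reports}")
        if dataset.n_case_reports == 0:
            log("warning: no target-drug case reports; signal tables will be empty")
    except Exception as exc:
        raise PipelineError(f"flag: {exc}") from exc

    outputs: dict[str, Path] = {}
    try:
        parts = [cohort.demographic_summary(dataset),
                 cohort.outcome_summary(dataset),
                 cohort.tto_summary(dataset)]
        parts = [p for p in parts if not p.empty]
        summary = (pd.concat(parts, ignore_index=True) if parts else
                   pd.DataFrame(columns=["category", "level", "count",
                                         "percentage"]))
        path = out_dir / "descriptive_summary.tsv"
        summary.to_csv(path, sep="\t", index=False, lineterminator="\n")
        outputs["descriptive_summary"] = path
    except Exception as exc:
        raise PipelineError(f"summaries: {exc}") from exc

    try:
        for level, fname in (("soc", "soc_signals.tsv"), ("pt", "pt_signals.tsv")):
            tables = dp.build_tables(dataset, level=level, mapping=soc_map,
                                     denominator=config.denominator)
            scores = dp.score_tables(tables,
                                     zero_correction=config.zero_correction,
                                     fit_prior=config.fit_mgps_prior)
            frame = signal_report.ranked_signal_frame(scores, config.thresholds)
            path = out_dir / fname
            signal_report.write_signal_tsv(frame, path)
            outputs[fname.removesuffix(".tsv")] = path
            log(f"{level} tables: {len(tables)} terms scored")
            if level == "pt":
                points = signal_report.volcano_points(scores)
                vpath = out_dir / "volcano.tsv"
                signal_report.write_volcano_tsv(points, vpath)
                outputs["volcano"] = vpath
        log(f"unmapped PT lookups: {soc_map.unmapped_tally}")
    except Exception as exc:
        raise PipelineError(f"signals: {exc}") from exc

    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["run_log"] = log_path
    return outputs
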