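"""Multiplicity adjustment, volcano coordinates and ranked signal tables.

Each event's Yates χ² (1 df, upper tail) yields a raw p-value; across all
events at a level these are Benjamini–Hochberg adjusted.  The volcano view
plots x = log₂(PRR) against y = −log₁₀(adjusted p); points with x > 0 and
y > 1.3 (p_adj < 0.05) are the statistically significant signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .disproportionality import (SignalFlags, SignalScores, SignalThresholds,
                                 evaluate_criteria)

__all__ = [
    "VolcanoPoint",
    "bh_adjust",
    "chisq_pvalues",
    "volcano_points",
    "ranked_signal_frame",
    "write_signal_tsv",
    "write_volcano_tsv",
    "SIGNIFICANCE_LINE",
]

#: −log10(0.05): the dashed significance line of the volcano view.
SIGNIFICANCE_LINE = -math.log10(0.05)


@dataclass(frozen=True)
class VolcanoPoint:
    term: str
    x: float  # log2(PRR)
    y: float  # −log10(adjusted p)
    significant: bool
    excluded: bool = False  # infinite/undefined PRR: no coordinates


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_pvalues(chisq: Sequence[float]) -> np.ndarray:
    """Upper-tail p-values of χ² statistics with one degree of freedom."""
    return stats.chi2.sf(np.asarray(chisq, dtype=float), df=1)


def volcano_points(scores: Sequence[SignalScores]) -> list[VolcanoPoint]:
    """Volcano coordinates for a batch of scored events.

    Raw p-values come from each event's Yates χ² and are BH-adjusted across
    the whole batch.  Events whose PRR is infinite or undefined are flagged
    as excluded (they still consume a multiplicity slot).
    """
    if not scores:
        return []
    p_adj = bh_adjust(chisq_pvalues([s.chisq for s in scores]))
    points = []
    for s, pa in zip(scores, p_adj):
        if not np.isfinite(s.prr) or s.prr <= 0:
            points.append(VolcanoPoint(s.term, math.nan, math.nan, False, True))
            continue
        x = math.log2(s.prr)
        y = -math.log10(pa) if pa > 0 else math.inf
        points.append(VolcanoPoint(s.term, x, y,
                                   bool(x > 0 and y > SIGNIFICANCE_LINE)))
    return points


def _fmt(v: float, nd: int = 2) -> str:
    return "inf" if not np.isfinite(v) else f"{v:.{nd}f}"


def ranked_signal_frame(scores: Sequence[SignalScores],
                        thresholds: SignalThresholds = SignalThresholds(),
                        ) -> pd.DataFrame:
    """Assemble the ranked signal table in the published column layout.

    One row per event with case reports, ROR (95% CI), PRR (95% CI), χ²,
    IC (IC − 2SD) and EBGM (EBGM05), the per-algorithm signal flags and the
    conservative combined flag; sorted by descending ROR with
    infinite-estimate rows pushed to the bottom.  Raw numeric columns are
    kept alongside the formatted ones.
    """
    rows = []
    for s in scores:
        flags: SignalFlags = evaluate_criteria(s, thresholds=thresholds)
        rows.append({
            "term": s.term,
            "case_reports": int(round(s.a)),
            "ror_fmt": f"{_fmt(s.ror)} ({_fmt(s.ror_ci_low)}, {_fmt(s.ror_ci_high)})",
            "prr_fmt": f"{_fmt(s.prr)} ({_fmt(s.prr_ci_low)}, {_fmt(s.prr_ci_high)})",
            "chisq": round(s.chisq, 2),
            "ic_fmt": f"{_fmt(s.eic)} ({_fmt(s.ic_2sd)})",
            "ebgm_fmt": f"{_fmt(s.ebgm)} ({_fmt(s.ebgm05)})",
            "ror": s.ror, "ror_ci_low": s.ror_ci_low, "ror_ci_high": s.ror_ci_high,
            "prr": s.prr, "prr_ci_low": s.prr_ci_low, "prr_ci_high": s.prr_ci_high,
            "eic": s.eic, "ic_2sd": s.ic_2sd, "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "ror_signal": flags.ror_signal,
            "prr_signal": flags.prr_signal,
            "bcpnn_signal": flags.bcpnn_signal,
            "combined_signal": flags.combined,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    finite = np.isfinite(df["ror"].to_numpy(dtype=float))
    df = df.assign(_finite=finite).sort_values(
        ["_finite", "ror"], ascending=[False, False], kind="mergesort",
    ).drop(columns="_finite").reset_index(drop=True)
    return df


def write_signal_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a ranked signal table as TSV (formatted + flag columns)."""
    path = Path(path)
    cols = ["term", "case_reports", "ror_fmt", "prr_fmt", "chisq",
            "ic_fmt", "ebgm_fmt", "ror_signal", "prr_signal",
            "bcpnn_signal", "combined_signal"]
    out = df[cols] if not df.empty else pd.DataFrame(columns=cols)
    out = out.rename(columns={
        "ror_fmt": "ROR (95% CI)", "prr_fmt": "PRR (95% CI)",
        "chisq": "chisq", "ic_fmt": "IC (IC-2SD)", "ebgm_fmt": "EBGM (EBGM05)",
    })
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_volcano_tsv(points: Sequence[VolcanoPoint], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{
        "term": p.term, "log2_prr": p.x, "neg_log10_p_adj": p.y,
        "significant": p.significant, "excluded": p.excluded,
    } for p in points], columns=["term", "log2_prr", "neg_log10_p_adj",
                                 "significant", "excluded"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def plot_volcano(points: Sequence[VolcanoPoint], path: str | Path) -> Path:
    """Optional rendering of the volcano coordinates (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.x for p in points if not p.excluded]
    ys = [p.y for p in points if not p.excluded]
    sig = [p.significant for p in points if not p.excluded]
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = ["#d62728" if s else "#7f7f7f" for s in sig]
    ax.scatter(xs, ys, s=12, c=colors, alpha=0.7)
    ax.axhline(SIGNIFICANCE_LINE, ls="--", lw=1, c="k")
    ax.axvline(0.0, ls=":", lw=1, c="k")
    ax.set_xlabel("log2(PRR)")
    ax.set_ylabel("-log10(adjusted p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
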