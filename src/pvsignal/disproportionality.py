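"""Disproportionality statistics on case/non-case 2×2 tables.

For every event term the reports are cross-classified as

    ==================  ================  ============
                        event of interest  other events
    target-drug (case)  a                  b
    other drugs         c                  d
    ==================  ================  ============

and four families of signal statistics are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with the log-Wald 95% CI
  ``exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Yates continuity-corrected χ² statistic.
* **BCPNN IC** — the information component ``log₂`` of the shrunken
  observed/expected reporting ratio under the Bayesian confidence propagation
  neural network priors, with its variance-based lower bound IC − 2·√VIC.
* **MGPS EBGM** — DuMouchel's empirical-Bayes gamma-Poisson shrinker: the
  posterior geometric mean of the observed/expected ratio λ under a
  two-component gamma mixture prior fitted to all tables jointly, and its 5th
  posterior percentile EBGM05.

The classical screening thresholds (a ≥ 3; ROR ≥ 2 with CI lower bound > 1;
PRR ≥ 2 with χ² ≥ 4; IC − 2SD > 0) are evaluated per algorithm.  A
``reconstruct_table`` inverse solves for the full 2×2 table from a published
(a, n, ROR, PRR) quadruple, allowing published rows to be re-audited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import AnalysisDataset
from .vocabulary import PtSocMap, UNMAPPED

__all__ = [
    "ContingencyTable",
    "BcpnnHyperparams",
    "MgpsPrior",
    "SignalScores",
    "SignalFlags",
    "SignalThresholds",
    "build_tables",
    "ror_with_ci",
    "prr_with_chisq",
    "yates_chisq",
    "bcpnn_ic",
    "mgps_ebgm",
    "fit_mgps_prior",
    "evaluate_criteria",
    "reconstruct_table",
    "score_tables",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 case/non-case table for one drug–event pair.

    Cells may be real-valued: :func:`reconstruct_table` returns unrounded
    solutions.  Margins follow the BCPNN notation: C = n, Cx = a+b (reports
    with the drug), Cy = a+c (reports with the event), Cxy = a.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n <= 0:
            raise ValueError("table must contain at least one report")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def Cx(self) -> float:
        return self.a + self.b

    @property
    def Cy(self) -> float:
        return self.a + self.c

    @property
    def Cxy(self) -> float:
        return self.a

    @property
    def expected(self) -> float:
        """Expected count E = Cx·Cy/n under independence."""
        return self.Cx * self.Cy / self.n

    def with_correction(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: add ``k`` to every cell."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Prior hyperparameters of the BCPNN information component."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        """Joint-cell prior scale tied to the margins so that E[IC] ≈ 0
        under independence."""
        return (self.gamma11 * (t.n + self.alpha) * (t.n + self.beta)
                / ((t.Cx + self.alpha1) * (t.Cy + self.beta1)))


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    The default is DuMouchel's published starting prior: a long-tailed
    component Gamma(0.2, 0.1) mixed with a null-centred Gamma(2, 4)
    (shape/rate parameterisation) with mixing weight 1/3 on the first.
    """

    shape1: float = 0.2
    rate1: float = 0.1
    shape2: float = 2.0
    rate2: float = 4.0
    mixing_weight: float = 1.0 / 3.0

    def __post_init__(self):
        if not (0.0 < self.mixing_weight < 1.0):
            raise ValueError("mixing_weight must lie strictly in (0, 1)")
        if min(self.shape1, self.rate1, self.shape2, self.rate2) <= 0:
            raise ValueError("gamma parameters must be positive")


@dataclass
class SignalScores:
    """All per-table statistics for one event term."""

    term: str
    a: float
    expected: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    chisq: float
    eic: float
    vic: float
    ic_2sd: float
    ebgm: float = float("nan")
    ebgm05: float = float("nan")


@dataclass(frozen=True)
class SignalThresholds:
    """The classical screening thresholds, exposed for sensitivity analyses."""

    min_a: float = 3.0
    min_ror: float = 2.0
    min_ror_ci_low: float = 1.0
    min_prr: float = 2.0
    min_chisq: float = 4.0
    min_ic_2sd: float = 0.0


@dataclass(frozen=True)
class SignalFlags:
    ror_signal: bool
    prr_signal: bool
    bcpnn_signal: bool

    @property
    def combined(self) -> bool:
        """Conservative all-of labelling across the three criteria sets."""
        return self.ror_signal and self.prr_signal and self.bcpnn_signal


def build_tables(dataset: AnalysisDataset, level: str = "pt",
                 mapping: PtSocMap | None = None,
                 denominator: str = "reports",
                 ) -> list[tuple[str, ContingencyTable]]:
    """Cross-classify the dataset into one 2×2 table per event term.

    ``level`` is ``"pt"`` or ``"soc"`` (the latter requires ``mapping``; a
    report counts once per SOC however many of its PTs fall in it, and
    unmapped PTs are excluded after bumping the map's tally).  With the
    default report-level denominator, a/b/c/d count *reports*; with
    ``denominator="units"`` the margins count distinct (report, event) units,
    the convention matching databases whose published total is the reaction-
    record count.
    """
    units = dataset.units
    if units.empty:
        return []
    if level not in ("pt", "soc"):
        raise ValueError("level must be 'pt' or 'soc'")
    if level == "soc":
        if mapping is None:
            raise ValueError("SOC-level tables require a PtSocMap")
        socs = units["pt"].map(mapping.lookup)
        units = units.assign(term=socs)
        units = units[units["term"] != UNMAPPED]
        units = units.drop_duplicates(subset=["report_id", "term"])
    else:
        units = units.assign(term=units["pt"])

    if denominator not in ("reports", "units"):
        raise ValueError("denominator must be 'reports' or 'units'")

    counts = (units.groupby(["term", "is_case"], sort=True, observed=True)
              .size().unstack(fill_value=0))
    a = counts[True] if True in counts.columns else pd.Series(0, index=counts.index)
    c = counts[False] if False in counts.columns else pd.Series(0, index=counts.index)

    if denominator == "reports":
        n_case = dataset.n_case_reports
        n_noncase = dataset.n_noncase_reports
    else:
        n_case = int(units["is_case"].sum())
        n_noncase = int((~units["is_case"]).sum())

    out = []
    for term in counts.index:
        ai, ci = float(a.get(term, 0)), float(c.get(term, 0))
        out.append((str(term), ContingencyTable(ai, n_case - ai, ci,
                                                n_noncase - ci)))
    return out


def ror_with_ci(t: ContingencyTable,
                zero_correction: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio ``ad/bc`` with its 95% log-Wald interval.

    A zero ``b`` or ``c`` makes the estimate infinite; by default this is
    reported as an infinite-estimate marker (``inf`` with NaN bounds) so the
    caller can exclude the pair from ranked output.  ``zero_correction``
    applies the Haldane–Anscombe +0.5 instead.
    """
    if zero_correction and min(t.a, t.b, t.c, t.d) == 0:
        t = t.with_correction()
    if t.b == 0 or t.c == 0:
        return math.inf, math.nan, math.nan
    if t.a == 0 or t.d == 0:
        return 0.0, math.nan, math.nan
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se)


def yates_chisq(t: ContingencyTable) -> float:
    """Yates continuity-corrected χ²: ``n(|ad−bc| − n/2)² / (Cx·Cy·(c+d)(b+d))``.

    Floors at zero when the correction exceeds |ad − bc|.
    """
    diff = abs(t.a * t.d - t.b * t.c)
    if diff <= t.n / 2:
        return 0.0
    denom = (t.a + t.b) * (t.a + t.c) * (t.c + t.d) * (t.b + t.d)
    if denom == 0:
        return 0.0
    return t.n * (diff - t.n / 2) ** 2 / denom


def prr_with_chisq(t: ContingencyTable, zero_correction: bool = False,
                   ) -> tuple[float, float, float, float]:
    """PRR with its 95% log-Wald interval and the Yates χ² statistic.

    The CI uses the delta-method variance ``1/a − 1/(a+b) + 1/c − 1/(c+d)``.
    A zero ``c`` gives the infinite-estimate marker; the χ² is always
    computed on the uncorrected table.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR requires at least one case and one non-case report")
    chisq = yates_chisq(t)
    tt = t
    if zero_correction and min(t.a, t.b, t.c, t.d) == 0:
        tt = t.with_correction()
    if tt.c == 0:
        return math.inf, math.nan, math.nan, chisq
    if tt.a == 0:
        return 0.0, math.nan, math.nan, chisq
    prr = (tt.a / (tt.a + tt.b)) / (tt.c / (tt.c + tt.d))
    var = 1 / tt.a - 1 / (tt.a + tt.b) + 1 / tt.c - 1 / (tt.c + tt.d)
    se = math.sqrt(max(var, 0.0))
    return prr, prr * math.exp(-Z_95 * se), prr * math.exp(Z_95 * se), chisq


def bcpnn_ic(t: ContingencyTable,
             h: BcpnnHyperparams = BcpnnHyperparams(),
             ) -> tuple[float, float, float]:
    """BCPNN information component: (EIC, VIC, IC − 2·√VIC).

    EIC = log₂[(Cxy+γ11)(C+α)(C+β) / ((C+γ)(Cx+α1)(Cy+β1))] with γ tied to
    the margins, so an exactly independent table has EIC = 0; VIC is the
    matching three-term posterior variance on the log₂ scale.
    """
    C, Cx, Cy, Cxy = t.n, t.Cx, t.Cy, t.Cxy
    g = h.gamma(t)
    eic = math.log2(
        (Cxy + h.gamma11) * (C + h.alpha) * (C + h.beta)
        / ((C + g) * (Cx + h.alpha1) * (Cy + h.beta1))
    )
    ln2 = math.log(2.0)
    vic = (1 / ln2 ** 2) * (
        (C - Cxy + g - h.gamma11) / ((Cxy + h.gamma11) * (1 + C + g))
        + (C - Cx + h.alpha - h.alpha1) / ((Cx + h.alpha1) * (1 + C + h.alpha))
        + (C - Cy + h.beta - h.beta1) / ((Cy + h.beta1) * (1 + C + h.beta))
    )
    return eic, vic, eic - 2.0 * math.sqrt(vic)


# ---------------------------------------------------------------------------
# MGPS / EBGM


def _log_nb_mixture(a: np.ndarray, E: np.ndarray, prior: MgpsPrior) -> np.ndarray:
    """Log marginal likelihood of observed counts under the mixture prior.

    Integrating the Poisson(λE) likelihood against each gamma component gives
    a negative binomial; the marginal is their weighted mixture.
    """
    def log_nb(shape, rate):
        return (special.gammaln(a + shape) - special.gammaln(shape)
                - special.gammaln(a + 1.0)
                + shape * np.log(rate / (rate + E))
                + a * np.log(E / (rate + E)))

    l1 = np.log(prior.mixing_weight) + log_nb(prior.shape1, prior.rate1)
    l2 = np.log1p(-prior.mixing_weight) + log_nb(prior.shape2, prior.rate2)
    return np.logaddexp(l1, l2)


def fit_mgps_prior(tables: Sequence[ContingencyTable],
                   start: MgpsPrior = MgpsPrior()) -> MgpsPrior:
    """Fit the mixture prior by maximising the marginal likelihood.

    Optimises over log-transformed gamma parameters and a logit-transformed
    weight (Nelder-Mead).  On failure, falls back to ``start`` with a
    warning rather than aborting the analysis.
    """
    a = np.array([t.a for t in tables], dtype=float)
    E = np.array([t.expected for t in tables], dtype=float)

    def unpack(x) -> MgpsPrior:
        s1, r1, s2, r2 = np.exp(np.clip(x[:4], -20, 20))
        w = 1.0 / (1.0 + math.exp(-float(np.clip(x[4], -30, 30))))
        w = min(max(w, 1e-9), 1 - 1e-9)
        return MgpsPrior(s1, r1, s2, r2, w)

    def nll(x) -> float:
        p = unpack(x)
        with np.errstate(all="ignore"):
            ll = _log_nb_mixture(a, E, p)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    x0 = np.array([math.log(start.shape1), math.log(start.rate1),
                   math.log(start.shape2), math.log(start.rate2),
                   math.log(start.mixing_weight / (1 - start.mixing_weight))])
    try:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6,
                                         "fatol": 1e-8})
        if not res.success or not np.isfinite(res.fun):
            raise RuntimeError(res.message)
        return unpack(res.x)
    except Exception as exc:  # non-convergence: keep going with the default
        warnings.warn(f"MGPS prior fit did not converge ({exc}); "
                      "falling back to the default prior", RuntimeWarning)
        return start


def _posterior_mixture(a: float, E: float, prior: MgpsPrior,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior of λ given a count: gamma mixture with updated weights."""
    shapes = np.array([prior.shape1 + a, prior.shape2 + a])
    rates = np.array([prior.rate1 + E, prior.rate2 + E])

    def log_nb(shape, rate):
        return (special.gammaln(a + shape) - special.gammaln(shape)
                - special.gammaln(a + 1.0)
                + shape * math.log(rate / (rate + E))
                + a * math.log(E / (rate + E)) if E > 0 else
                (0.0 if a == 0 else -math.inf))

    lw = np.array([
        math.log(prior.mixing_weight) + log_nb(prior.shape1, prior.rate1),
        math.log1p(-prior.mixing_weight) + log_nb(prior.shape2, prior.rate2),
    ])
    lw -= special.logsumexp(lw)
    return np.exp(lw), shapes, rates


def _ebgm_from_posterior(weights, shapes, rates) -> float:
    # geometric mean: 2^{E[log2 λ]} = exp(Σ Q_i (ψ(shape_i) − ln rate_i))
    return float(np.exp(np.sum(weights * (special.digamma(shapes)
                                          - np.log(rates)))))


def _quantile_from_posterior(weights, shapes, rates, q: float) -> float:
    def cdf(x):
        return float(np.sum(weights * stats.gamma.cdf(x, shapes,
                                                      scale=1.0 / rates)))
    lo, hi = 1e-12, 1.0
    while cdf(hi) < q:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    return optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-12,
                           rtol=1e-12)


def mgps_ebgm(tables: Sequence[ContingencyTable],
              prior: MgpsPrior | None = None,
              ) -> list[tuple[float, float]]:
    """Empirical-Bayes geometric mean and 5th percentile per table.

    With ``prior=None`` the mixture prior is fitted to all supplied tables
    first (at least ~10 tables recommended for a stable fit); a fixed prior
    skips the fit.  For each table the posterior of the relative reporting
    rate λ is the conjugate gamma mixture with components
    (shapeᵢ+a, rateᵢ+E); EBGM = 2^{E[log₂ λ]} and EBGM05 is the 5th posterior
    percentile found by root-finding on the mixture CDF.
    """
    if not tables:
        raise ValueError("mgps_ebgm requires at least one table")
    if prior is None:
        prior = fit_mgps_prior(tables)
    out = []
    for t in tables:
        w, sh, rt = _posterior_mixture(t.a, t.expected, prior)
        out.append((_ebgm_from_posterior(w, sh, rt),
                    _quantile_from_posterior(w, sh, rt, 0.05)))
    return out


def evaluate_criteria(s: SignalScores, a: float | None = None,
                      thresholds: SignalThresholds = SignalThresholds(),
                      ) -> SignalFlags:
    """Apply the per-algorithm screening thresholds to one event's scores."""
    if a is None:
        a = s.a
    base = a >= thresholds.min_a
    ror_ok = (base and np.isfinite(s.ror) and s.ror >= thresholds.min_ror
              and np.isfinite(s.ror_ci_low)
              and s.ror_ci_low > thresholds.min_ror_ci_low)
    prr_ok = (base and np.isfinite(s.prr) and s.prr >= thresholds.min_prr
              and s.chisq >= thresholds.min_chisq)
    bcpnn_ok = bool(base and s.ic_2sd > thresholds.min_ic_2sd)
    return SignalFlags(bool(ror_ok), bool(prr_ok), bcpnn_ok)


def reconstruct_table(a: float, n: float, ror: float, prr: float,
                      rtol: float = 1e-10) -> ContingencyTable:
    """Recover the full 2×2 table from a published (a, n, ROR, PRR) row.

    Eliminates Cy via the PRR identity
    ``Cy = a + a(n − Cx)/(PRR·Cx)`` and solves the remaining one-dimensional
    ROR equation for Cx by bracketed root-finding on (a, n − a).  Requires
    the solvable branch ``ROR > PRR > 1`` and returns real-valued
    (unrounded) cells.
    """
    if not (ror > prr > 1.0):
        raise ValueError("reconstruction requires ROR > PRR > 1")
    if not (0 < a < n):
        raise ValueError("requires 0 < a < n")

    def cells(Cx: float) -> tuple[float, float, float]:
        Cy = a + a * (n - Cx) / (prr * Cx)
        return Cx - a, Cy - a, n - Cx - Cy + a

    def resid(Cx: float) -> float:
        b, c, d = cells(Cx)
        if min(b, c, d) <= 0:
            return math.nan
        return a * d / (b * c) - ror

    lo, hi = a * (1 + 1e-12), n - a
    # shrink the bracket to where all cells are positive and a sign change exists
    grid = np.geomspace(lo + 1e-9, hi, 512)
    vals = np.array([resid(x) for x in grid])
    ok = np.isfinite(vals)
    sign_change = None
    idx = np.where(ok)[0]
    for i, j in zip(idx[:-1], idx[1:]):
        if vals[i] == 0.0:
            sign_change = (grid[i], grid[i])
            break
        if vals[i] * vals[j] < 0:
            sign_change = (grid[i], grid[j])
            break
    if sign_change is None:
        raise ValueError("no feasible table reproduces the given ROR and PRR")
    if sign_change[0] == sign_change[1]:
        Cx = sign_change[0]
    else:
        Cx = optimize.brentq(resid, sign_change[0], sign_change[1],
                             xtol=1e-12, rtol=rtol)
    b, c, d = cells(Cx)
    return ContingencyTable(a, b, c, d)


def score_tables(tables: Sequence[tuple[str, ContingencyTable]],
                 prior: MgpsPrior | None = None,
                 hyper: BcpnnHyperparams = BcpnnHyperparams(),
                 zero_correction: bool = False,
                 fit_prior: bool = True) -> list[SignalScores]:
    """Compute the full score set for a batch of named tables.

    The MGPS prior is shared across the batch (fitted when ``prior`` is None
    and ``fit_prior`` is true, else the documented default).
    """
    if not tables:
        return []
    cts = [t for _, t in tables]
    if prior is None:
        prior = fit_mgps_prior(cts) if fit_prior else MgpsPrior()
    eb = mgps_ebgm(cts, prior)
    out = []
    nan = float("nan")
    for (term, t), (ebgm, ebgm05) in zip(tables, eb):
        if t.a + t.b == 0 or t.c + t.d == 0:
            # degenerate margin (e.g. no case reports at all): undefined scores
            eic, vic, ic2 = bcpnn_ic(t, hyper)
            out.append(SignalScores(term=term, a=t.a, expected=t.expected,
                                    ror=nan, ror_ci_low=nan, ror_ci_high=nan,
                                    prr=nan, prr_ci_low=nan, prr_ci_high=nan,
                                    chisq=0.0, eic=eic, vic=vic, ic_2sd=ic2,
                                    ebgm=ebgm, ebgm05=ebgm05))
            continue
        ror, rlo, rhi = ror_with_ci(t, zero_correction)
        prr, plo, phi, chisq = prr_with_chisq(t, zero_correction)
        eic, vic, ic2 = bcpnn_ic(t, hyper)
        out.append(SignalScores(
            term=term, a=t.a, expected=t.expected,
            ror=ror, ror_ci_low=rlo, ror_ci_high=rhi,
            prr=prr, prr_ci_low=plo, prr_ci_high=phi, chisq=chisq,
            eic=eic, vic=vic, ic_2sd=ic2, ebgm=ebgm, ebgm05=ebgm05,
        ))
    return out
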