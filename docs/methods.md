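# Methods

## The case/non-case design

Spontaneous-report databases record events, not exposures, so all inference
here is *within-database* disproportionality. A deduplicated report is a
**case** when it lists the target drug with the primary-suspect (PS) role
code and a name matching the user-supplied synonym list; every other report
is a **non-case**. The analysis unit is the distinct (report, PT) pair: a
report with k distinct preferred terms contributes k units, but each 2×2
cell counts *reports*, so a report counts at most once per event term. At
SOC level a report again counts once per SOC regardless of how many of its
PTs fall in that SOC — published SOC tables describe case reports, and this
convention makes SOC counts the report-level union of their PT counts.

Two margin conventions exist in the literature for the table total n:
report counts, and reaction-record (unit) counts. `build_tables` defaults
to report counting, which makes the four cells a partition of the reports
(the contract the rest of the package assumes), and offers
`denominator="units"` for comparability with analyses whose printed n is
the database's reaction-record total. `reconstruct_table` is agnostic: it
takes n as an input.

## Deduplication and cleaning

FAERS distributes revised versions of the same case across quarters. The
FDA's published recommendation is followed: group DEMO records by case id
across *all* supplied quarters jointly, keep the version with the latest
receipt date, break ties by the largest report id. The rule is
deterministic, idempotent and independent of input order; records lacking a
case id are dropped and tallied. Cleaning then removes empty/whitespace
event terms, removes any event PT exactly equal (case-insensitively) to an
indication PT recorded for the same report — adverse-event listings that
merely restate the treated disease — and drops reports left with no events.
Demographic blanks are *kept* as explicit "unknown" levels: published
characteristic tables carry unknown rows, so blanks cannot be discarded
without distorting denominators. Partial dates (YYYYMM, YYYY) resolve to
the first day of the period, which keeps time-to-onset computable and, by
construction, never shortens it. Dedup order relative to the indication
filter is fixed as dedup → join → filter.

## The four statistics

All four act on (a, b, c, d) with n = a+b+c+d, Cx = a+b, Cy = a+c,
E = Cx·Cy/n.

**ROR** = ad/bc; 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
**PRR** = [a/(a+b)]/[c/(c+d)]; its CI uses the standard delta-method
variance 1/a − 1/(a+b) + 1/c − 1/(c+d) (published screens print PRR CIs
without stating a formula; this is the conventional choice). The
**Yates χ²** is n(|ad−bc| − n/2)²/[(a+b)(a+c)(c+d)(b+d)], floored at 0 when
the correction exceeds |ad−bc|; it agrees with
`scipy.stats.chi2_contingency(correction=True)` to 1e-9 (tested).

**BCPNN.** The information component uses the classical hyperparameters
α₁=β₁=1, α=β=2, γ₁₁=1 with the joint-cell prior scale
γ = γ₁₁(C+α)(C+β)/((Cx+α₁)(Cy+β₁)) tied to the margins, so an exactly
independent table has EIC = 0 identically. EIC, the three-term posterior
variance VIC (on the log₂ scale), and the lower bound IC − 2√VIC are
returned; the lower bound is labelled `ic_2sd` rather than "IC025" because
the variance-based bound and the exact posterior 2.5th percentile differ
slightly and published tables rarely say which they print.

**MGPS.** The paper-trail for the "multi-item gamma-Poisson shrinker"
usually stops at the name, so the canonical DuMouchel (1999) model is
implemented: a ~ Poisson(λE), λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)
(shape/rate), default prior (0.2, 0.1, 2, 4, w = 1/3). The prior is fitted
by maximising the negative-binomial-mixture marginal likelihood over all
tables of a batch (Nelder–Mead on log/logit-transformed parameters; on
non-convergence the default prior is used with a warning). The posterior is
the conjugate mixture with components (αᵢ+a, βᵢ+E) and weights updated by
the component marginals; EBGM = 2^E[log₂ λ] via the digamma identity
E[ln λ] = ψ(shape) − ln(rate) per component, and EBGM05 by Brent
root-finding on the posterior mixture CDF. EBGM values depend on the whole
batch through the fitted prior, so two analyses with different table sets
legitimately produce different EBGMs for the same table; the tested
guarantees are the shrinkage bounds (EBGM between 1 and a/E under any
mean-1 prior) and monotonicity, not any particular published EBGM column.

**Zero cells.** b = 0 or c = 0 makes ROR/PRR infinite; the default reports
an infinite-estimate marker (excluded from ranked output, flagged in the
volcano) and an optional Haldane–Anscombe +0.5 correction is available
behind a flag. Screening criteria are the classical a ≥ 3 gates: ROR ≥ 2
with CI low > 1; PRR ≥ 2 with χ² ≥ 4; IC − 2SD > 0. The exported "combined"
flag is the conservative all-of conjunction; per-algorithm flags are always
exported so any other labelling convention can be recovered downstream.

## Descriptive summaries

Percentages are count/denominator·100 rounded to 2 decimals. Denominators
differ by category, following the arithmetic of published characteristic
tables: demographics use all case reports with unknowns as a level;
outcomes reduce each report to its single most serious code (priority
DE > LT > HO > DS > CA > RI > OT — the conventional seriousness ranking)
and exclude reports with no outcome code from the denominator; time to
onset (event date − therapy start, whole days, bins [0,7), [7,28), [28,60),
[60,∞)) keeps negative/missing intervals as an "unknown" level inside the
denominator. Age bins [0,18), [18,45), [45,65), [65,75), [75,∞) are
half-open on the right (45 belongs to 45–65); units convert to years via
month/12, week/52, day/365.25, decade×10, hour/8766.

## Multiplicity and volcano coordinates

Each event's raw p-value is the upper tail of its Yates χ² at 1 df — the
only test statistic the screening framework defines. Across all events at a
level the p-values are Benjamini–Hochberg adjusted (the standard volcano
convention for "adjusted p"; both raw and adjusted values are exported).
Coordinates are x = log₂ PRR, y = −log₁₀ p_adj; points with x > 0 and
y > 1.3 ≈ −log₁₀ 0.05 are flagged significant. BH is *not* idempotent in
general (re-adjusting adjusted values can inflate them further), so the
tested invariants are pointwise dominance, the cap at 1 and preservation of
the raw ordering.

## Table reconstruction

Published rows print (a, n, ROR, PRR) but not b, c, d. Given ROR > PRR > 1,
the PRR identity yields Cy = a + a(n−Cx)/(PRR·Cx), leaving a
one-dimensional equation in Cx for the ROR; it is solved by bracketed Brent
root-finding on (a, n−a) after a grid scan locates the sign change
(relative tolerance 1e-10). Cells are returned unrounded. ROR = PRR is
degenerate (no interior solution) and rejected. Round-tripping a table
through (ROR, PRR) and back recovers it to 6 significant figures (tested);
applying the reconstruction to a published row and recomputing its χ², IC
and CI bound checks the row's internal consistency to within the
propagation of the printed two-decimal rounding — about ±0.05% on ROR/PRR,
which moves the χ² by a few tenths of a percent.

## The synthetic generator

`synthetic_data` emulates what the pipeline must survive, not FAERS content:
multi-table $-delimited quarters keyed by case/report ids; revised case
versions with earlier receipt dates and smaller ids (so FDA-rule dedup
recovers the pre-duplication reports exactly, which is tested); a PS drug
per report plus Poisson-mean-1 concomitants; field-level missingness; an
indication PT occasionally repeated as an event to exercise the overlap
filter.

Events come through two channels. Background events — 1 + Poisson(μ−1) per
report, μ = 2 by default — are drawn from a Zipf-weighted categorical
(exponent 1) over the non-planted PTs, identically for cases and non-cases,
so every background pair has true odds ratio exactly 1. Each planted
(drug, PT) pair is included per report as an independent Bernoulli whose
baseline probability (0.01) has its *odds* multiplied by the planted factor
when the report's PS drug matches; planted PTs are excluded from the
background channel. The multiplier is therefore exactly the report-level
odds ratio the ROR estimates — the property that makes null calibration and
parameter recovery well-posed. A multiplier applied multiplicatively to
probabilities inside a renormalised categorical (the obvious alternative)
biases the implied odds ratio by several percent at realistic rates, which
would conflate generator bias with estimator error.

Defaults are chosen for stable simulation studies at laptop scale: 50,000
reports per replicate and a 10% target-drug share give ~5,000 case reports,
enough that every background PT has expected a ≳ 20 and Wald intervals are
in their asymptotic regime. (Real FAERS target-drug shares are far smaller —
of order 0.03% — but at that share a 50k-report replicate would carry ~15
case reports and every statistic would sit in its small-sample regime;
scaling share up rather than n is what keeps the calibration experiments
meaningful at this problem size.) The generator does not attempt real drug
vocabularies, country codes, reporting-trend seasonality, correlated event
clusters or signal leakage through concomitant drugs; passing calibration
here validates the estimators and the pipeline plumbing, not robustness to
those real-data features.

Simulation studies in the test suite use 200 replicates of 50,000 reports
(both the null-calibration and recovery experiments run in well under a
minute each thanks to a vectorised fast path, `simulate_dataset`, that
shares the event-generation core with the full ASCII-emitting `generate`).

## Pipeline and interfaces

A single YAML config names the quarter directory, synonym file, PT→SOC TSV
and output directory; every screening threshold is exposed but defaulted to
the classical values, and the run log records the active settings and every
dropped-record tally. Outputs are TSV throughout. Given fixed inputs the
outputs are byte-stable (tested end-to-end: generate → write → parse → run
twice, compare bytes). The CLI (`pvsignal simulate|run|stats|reconstruct`)
is a thin wrapper; the library API is the primary interface.

## Known limitations

No stratified (age/sex/year) disproportionality; no multi-item drug-pair
MGPS; single primary-SOC mapping only (no secondary SOCs, HLT/HLGT);
synonym matching is exact after case-folding (no active-ingredient
resolution); the XML/SGML FAERS dialects are not read. Disproportionality
measures association within a reporting database, not causality or
incidence.
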