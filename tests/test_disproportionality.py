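"""The four signal statistics, their criteria, and the table reconstruction."""

import math
import warnings

import numpy as np
import pytest
from scipy import special, stats
from scipy.stats import chi2_contingency

from pvsignal.cohort import AnalysisDataset
from pvsignal.disproportionality import (BcpnnHyperparams, ContingencyTable,
                                         MgpsPrior, SignalScores,
                                         SignalThresholds, bcpnn_ic,
                                         build_tables, evaluate_criteria,
                                         fit_mgps_prior, mgps_ebgm,
                                         prr_with_chisq, reconstruct_table,
                                         ror_with_ci, score_tables,
                                         yates_chisq)

import pandas as pd


def random_tables(n, rng, low=1, high=500):
    out = []
    for _ in range(n):
        a, b, c = rng.integers(low, high, size=3)
        d = rng.integers(high, 100 * high)
        out.append(ContingencyTable(float(a), float(b), float(c), float(d)))
    return out


class TestContingencyTable:
    def test_margins(self):
        t = ContingencyTable(1, 2, 3, 4)
        assert (t.n, t.Cx, t.Cy, t.Cxy) == (10, 3, 4, 1)
        assert t.expected == pytest.approx(1.2)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_build_from_dataset_counts_reports_once_per_event(self):
        units = pd.DataFrame({
            "report_id": ["c1", "n1", "n2", "n3", "n4"],
            "pt": ["x", "x", "x", "x", "y"],
            "is_case": [True, False, False, False, False],
        })
        reports = pd.DataFrame({
            "report_id": ["c1"] + [f"n{i}" for i in range(1, 10)],
            "is_case": [True] + [False] * 9,
        })
        ds = AnalysisDataset(reports=reports, units=units)
        tables = dict(build_tables(ds, level="pt"))
        t = tables["x"]
        assert (t.a, t.b, t.c, t.d) == (1, 0, 3, 6)
        # margin property: a+b equals total case reports for every term
        assert all(t.a + t.b == 1 for t in tables.values())


class TestRor:
    def test_point_and_wald_ci(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(20, 80, 100, 9800))
        assert ror == pytest.approx(24.5)
        assert lo == pytest.approx(14.4481, abs=1e-3)
        assert hi == pytest.approx(41.5452, abs=1e-3)

    def test_balanced_table_symmetric_on_log_scale(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_zero_cell_gives_infinite_marker(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(5, 0, 3, 10))
        assert math.isinf(ror) and math.isnan(lo)

    def test_haldane_anscombe_option(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(5, 0, 3, 10),
                                  zero_correction=True)
        expected = (5.5 * 10.5) / (0.5 * 3.5)
        assert ror == pytest.approx(expected) and np.isfinite(lo)


class TestPrrChisq:
    def test_derived_values(self):
        prr, lo, hi, chisq = prr_with_chisq(ContingencyTable(20, 80, 100, 9800))
        assert prr == pytest.approx(19.8)
        assert chisq == pytest.approx(285.3178, abs=1e-3)

    def test_independent_table(self):
        prr, _, _, chisq = prr_with_chisq(ContingencyTable(10, 10, 10, 10))
        assert prr == 1.0 and chisq == 0.0

    def test_continuity_correction_floors_at_zero(self):
        # |ad - bc| = 2 < n/2 = 21
        assert yates_chisq(ContingencyTable(3, 4, 5, 6)) == 0.0

    def test_zero_c_gives_infinite_marker(self):
        prr, lo, _, _ = prr_with_chisq(ContingencyTable(5, 5, 0, 10))
        assert math.isinf(prr) and math.isnan(lo)

    def test_yates_matches_independent_oracle(self):
        rng = np.random.default_rng(12345)
        for t in random_tables(100, rng):
            oracle = chi2_contingency(np.array([[t.a, t.b], [t.c, t.d]]),
                                      correction=True).statistic
            assert yates_chisq(t) == pytest.approx(oracle, abs=1e-9)


class TestBcpnn:
    def test_unit_table_has_exactly_zero_ic(self):
        eic, vic, ic2 = bcpnn_ic(ContingencyTable(1, 1, 1, 1))
        assert eic == 0.0

    def test_unit_table_variance_and_lower_bound(self):
        # hand evaluation of the three-term variance at default priors:
        # (1/ln^2 2) * (6/18 + 3/21 + 3/21)
        eic, vic, ic2 = bcpnn_ic(ContingencyTable(1, 1, 1, 1))
        expected_vic = (1 / math.log(2) ** 2) * (6 / 18 + 3 / 21 + 3 / 21)
        assert vic == pytest.approx(expected_vic, rel=1e-12)
        assert ic2 == pytest.approx(-2 * math.sqrt(expected_vic), rel=1e-12)

    def test_independence_gives_near_zero_ic_at_scale(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = float(rng.integers(5, 200))
            k = float(rng.integers(2, 50))
            m = float(rng.integers(50, 500))
            # ad = bc by construction; inflate to n >= 1e4
            t = ContingencyTable(a, a * k, a * m, a * k * m)
            if t.n < 1e4:
                continue
            eic, _, _ = bcpnn_ic(t)
            assert abs(eic) < 0.01

    def test_custom_hyperparameters_change_gamma(self):
        t = ContingencyTable(10, 20, 30, 40)
        h = BcpnnHyperparams(alpha1=2, beta1=2)
        assert h.gamma(t) != BcpnnHyperparams().gamma(t)


class TestMgps:
    def test_ebgm_matches_digamma_closed_form(self):
        # identical mixture components collapse to a single Gamma(2, 2) prior;
        # posterior for (20,80,100,9800), E = 1.2 is Gamma(22, 3.2)
        t = ContingencyTable(20, 80, 100, 9800)
        (ebgm, ebgm05), = mgps_ebgm([t], prior=MgpsPrior(2, 2, 2, 2, 0.5))
        assert ebgm == pytest.approx(math.exp(special.digamma(22)) / 3.2,
                                     abs=1e-9)
        assert ebgm05 == pytest.approx(stats.gamma.ppf(0.05, 22, scale=1 / 3.2),
                                       abs=1e-9)

    def test_shrinkage_bounds_under_mean_one_prior(self):
        # mixture mean = 0.5*(2/2) + 0.5*(1/1) = 1
        prior = MgpsPrior(2, 2, 1, 1, 0.5)
        rng = np.random.default_rng(99)
        for t in random_tables(30, rng):
            if t.a / t.expected <= 1:
                continue
            (ebgm, ebgm05), = mgps_ebgm([t], prior=prior)
            assert 1.0 <= ebgm <= t.a / t.expected + 1e-9
            assert ebgm05 < ebgm

    def test_large_null_table_shrinks_to_one(self):
        # a/E = 1 with a = 1000
        t = ContingencyTable(1000, 9000, 99000, 891000)
        assert t.expected == pytest.approx(1000.0)
        (ebgm, _), = mgps_ebgm([t], prior=MgpsPrior())
        assert ebgm == pytest.approx(1.0, abs=0.05)

    def test_prior_fit_recovers_plausible_mixture(self):
        rng = np.random.default_rng(5)
        # counts drawn from the default prior's marginal
        prior = MgpsPrior()
        tables = []
        for _ in range(300):
            E = float(rng.uniform(0.5, 50.0))
            if rng.random() < prior.mixing_weight:
                lam = rng.gamma(prior.shape1, 1 / prior.rate1)
            else:
                lam = rng.gamma(prior.shape2, 1 / prior.rate2)
            a = float(rng.poisson(lam * E))
            n = 1e6
            Cx = 1e3
            Cy = E * n / Cx
            d = n - Cx - Cy + a
            tables.append(ContingencyTable(a, Cx - a, Cy - a, max(d, 0)))
        fitted = fit_mgps_prior(tables)
        mean = (fitted.mixing_weight * fitted.shape1 / fitted.rate1
                + (1 - fitted.mixing_weight) * fitted.shape2 / fitted.rate2)
        true_mean = (prior.mixing_weight * prior.shape1 / prior.rate1
                     + (1 - prior.mixing_weight) * prior.shape2 / prior.rate2)
        assert mean == pytest.approx(true_mean, rel=0.5)

    def test_fit_failure_falls_back_with_warning(self, monkeypatch):
        from pvsignal import disproportionality as dp

        def boom(*args, **kwargs):
            raise RuntimeError("synthetic failure")

        monkeypatch.setattr(dp.optimize, "minimize", boom)
        with pytest.warns(RuntimeWarning, match="falling back"):
            prior = fit_mgps_prior([ContingencyTable(1, 2, 3, 4)])
        assert prior == MgpsPrior()


class TestMonotonicity:
    def test_increasing_a_with_fixed_margins_increases_all(self):
        prior = MgpsPrior()
        prev = None
        for a in (5, 10, 20, 40):
            t = ContingencyTable(a, 100 - a, 200 - a, 9700 + a)
            ror, _, _ = ror_with_ci(t)
            prr, _, _, _ = prr_with_chisq(t)
            eic, _, _ = bcpnn_ic(t)
            (ebgm, _), = mgps_ebgm([t], prior=prior)
            cur = (ror, prr, eic, ebgm)
            if prev is not None:
                assert all(x > y for x, y in zip(cur, prev))
            prev = cur


class TestCriteria:
    def _scores(self, t):
        ror, rlo, rhi = ror_with_ci(t)
        prr, plo, phi, chisq = prr_with_chisq(t)
        eic, vic, ic2 = bcpnn_ic(t)
        return SignalScores("x", t.a, t.expected, ror, rlo, rhi, prr, plo,
                            phi, chisq, eic, vic, ic2)

    def test_minimum_case_count_gates_everything(self):
        flags = evaluate_criteria(self._scores(ContingencyTable(2, 2, 1, 1000)))
        assert not flags.ror_signal and not flags.prr_signal

    def test_independent_table_is_never_a_signal(self):
        flags = evaluate_criteria(self._scores(ContingencyTable(10, 10, 10, 10)))
        assert not (flags.ror_signal or flags.prr_signal or flags.bcpnn_signal)

    def test_strong_table_fires_ror_and_prr(self):
        flags = evaluate_criteria(self._scores(ContingencyTable(20, 80, 100, 9800)))
        assert flags.ror_signal and flags.prr_signal

    def test_thresholds_configurable(self):
        strict = SignalThresholds(min_ror=30.0)
        flags = evaluate_criteria(self._scores(ContingencyTable(20, 80, 100, 9800)),
                                  thresholds=strict)
        assert not flags.ror_signal


class TestReconstruct:
    def test_round_trip_recovers_cells(self):
        t = ContingencyTable(20, 80, 100, 9800)
        ror, _, _ = ror_with_ci(t)
        prr, _, _, _ = prr_with_chisq(t)
        rt = reconstruct_table(t.a, t.n, ror, prr)
        for got, want in ((rt.b, 80), (rt.c, 100), (rt.d, 9800)):
            assert got == pytest.approx(want, rel=1e-6)

    def test_round_trip_property_on_random_tables(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for t in random_tables(50, rng, low=5, high=300):
            ror, _, _ = ror_with_ci(t)
            prr, _, _, _ = prr_with_chisq(t)
            if not (np.isfinite(ror) and ror > prr > 1.0001):
                continue
            rt = reconstruct_table(t.a, t.n, ror, prr)
            assert rt.b == pytest.approx(t.b, rel=1e-6)
            assert rt.c == pytest.approx(t.c, rel=1e-6)
            checked += 1
        assert checked >= 10

    def test_equal_ror_prr_is_infeasible(self):
        with pytest.raises(ValueError):
            reconstruct_table(20, 10000, 5.0, 5.0)

    def test_published_row_reproduces_chisq(self):
        rt = reconstruct_table(3481, 48766547, 5.94, 5.48)
        assert yates_chisq(rt) == pytest.approx(12905.25, rel=0.05)


class TestScoreTables:
    def test_batch_scoring_shares_prior(self):
        rng = np.random.default_rng(11)
        tables = [(f"pt{i}", t) for i, t in enumerate(random_tables(20, rng))]
        scores = score_tables(tables, fit_prior=False)
        assert len(scores) == 20
        assert all(np.isfinite(s.ebgm) for s in scores)
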