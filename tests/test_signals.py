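"""Disproportionality statistics: closed forms, Bayesian shrinkage, calling."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import faerspv
from faerspv.signals import (MGPS_CONVENTIONAL_START, ContingencyTable,
                             MgpsPrior, SignalScores, Thresholds, bcpnn_stats,
                             call_signal, fit_mgps_prior, mgps_score,
                             nb_mixture_loglik, prr_stats, ror_stats)
from tests.conftest import DEMO_HEADER, DRUG_HEADER, REAC_HEADER, write_faers

WORKED = ContingencyTable(5, 15, 5, 75)


def brute_force_stats(a, b, c, d, yates):
    """Independent re-coding of the closed forms, digit by digit."""
    N = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    y = N / 2 if yates else 0.0
    num = max(abs(a * d - b * c) - y, 0.0)
    chi2 = N * num * num / ((a + b) * (c + d) * (a + c) * (b + d))
    ror = a * d / (b * c)
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    lo = math.exp(math.log(ror) - 1.959963984540054 * se)
    hi = math.exp(math.log(ror) + 1.959963984540054 * se)
    return prr, chi2, ror, lo, hi


class TestContingency:
    def _universe(self, tmp_path):
        demo = [DEMO_HEADER]
        drug = [DRUG_HEADER]
        reac = [REAC_HEADER]
        # 100 reports: 20 with DRUGX as PS; event PTE in 5 of those and 5 others
        for i in range(100):
            pid = 2000 + i
            demo.append(f"{pid}${pid}$20240101$F$60$YR$70$KG$MD$US")
            name = "DRUGX" if i < 20 else "OTHER"
            drug.append(f"{pid}$1$PS${name}${name}")
            if i < 5 or (20 <= i < 25):
                reac.append(f"{pid}$PTE")
        paths = write_faers(tmp_path, {"DEMO": demo, "DRUG": drug, "REAC": reac})
        store = faerspv.read_faers_tables(paths)
        d = faerspv.DrugDictionary(entries={"drugx": ["DRUGX"]},
                                   classes={"drugx": "X"})
        cohort = faerspv.build_cohort(store, "drugx", d)
        return store, cohort

    def test_worked_counts(self, tmp_path):
        store, cohort = self._universe(tmp_path)
        t = faerspv.build_contingency(store, cohort, "PTE")
        assert (t.a, t.b, t.c, t.d) == (5, 15, 5, 75)
        assert t.N == 100 and t.E == pytest.approx(2.0)

    def test_absent_event(self, tmp_path):
        store, cohort = self._universe(tmp_path)
        t = faerspv.build_contingency(store, cohort, "NO SUCH PT")
        assert t.a == 0 and t.c == 0 and t.E == 0.0

    def test_cohort_equals_universe(self, tmp_path):
        store, cohort = self._universe(tmp_path)
        whole = faerspv.Cohort("drugx", list(store.reports))
        t = faerspv.build_contingency(store, whole, "PTE")
        assert t.c == 0 and t.d == 0

    def test_cohort_must_be_subset(self, tmp_path):
        store, cohort = self._universe(tmp_path)
        stranger = faerspv.Cohort("drugx", cohort.reports + [
            faerspv.ReportRecord("99999", "x", None, "F", None, None, None,
                                 "missing", frozenset(), [], frozenset(), [])])
        with pytest.raises(ValueError, match="subset"):
            faerspv.build_contingency(store, stranger, "PTE")

    def test_bulk_matches_single(self, tmp_path):
        store, cohort = self._universe(tmp_path)
        bulk = faerspv.contingency_tables(store, cohort)
        assert bulk["PTE"] == faerspv.build_contingency(store, cohort, "PTE")


class TestClosedForms:
    def test_worked_example(self):
        prr, chi2_p = prr_stats(WORKED, "pearson")
        _, chi2_y = prr_stats(WORKED, "yates")
        ror, lo, hi = ror_stats(WORKED)
        assert prr == pytest.approx(4.0)
        assert chi2_p == pytest.approx(6.25)
        assert chi2_y == pytest.approx(6250000 / 1440000)
        assert ror == pytest.approx(5.0)
        assert lo == pytest.approx(1.2859979, abs=1e-6)
        assert hi == pytest.approx(19.4401554, abs=1e-6)

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 501, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            for yates in (False, True):
                prr, chi2 = prr_stats(t, "yates" if yates else "pearson")
                ror, lo, hi = ror_stats(t)
                e_prr, e_chi2, e_ror, e_lo, e_hi = brute_force_stats(
                    a, b, c, d, yates)
                for got, want in [(prr, e_prr), (chi2, e_chi2), (ror, e_ror),
                                  (lo, e_lo), (hi, e_hi)]:
                    assert got == pytest.approx(want, rel=1e-9)

    def test_prr_ror_ordering(self):
        """PRR > 1 implies ROR > PRR; both 1 on exact independence."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
            t = ContingencyTable(a, b, c, d)
            prr, _ = prr_stats(t)
            ror, _, _ = ror_stats(t)
            if prr > 1:
                assert ror > prr
        indep = ContingencyTable(4, 16, 16, 64)  # ad = bc, proportional margins
        assert prr_stats(indep)[0] == pytest.approx(1.0)
        assert ror_stats(indep)[0] == pytest.approx(1.0)

    def test_zero_margins_soft_undefined(self):
        t = ContingencyTable(0, 10, 0, 90)  # event absent
        prr, _ = prr_stats(t)
        ror, lo, hi = ror_stats(t)
        assert np.isnan(prr) and np.isnan(ror) and np.isnan(lo)
        s = call_signal(SignalScores(a=0, prr=prr, ror_lo=lo))
        assert not s.key

    def test_symmetric_ror_ci(self):
        ror, lo, hi = ror_stats(ContingencyTable(1, 1, 1, 1))
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            prr_stats(WORKED, "bonferroni")


class TestBcpnn:
    def test_symmetric_table_gives_zero_ic(self):
        ic, ic025 = bcpnn_stats(ContingencyTable(25, 25, 25, 25))
        assert ic == 0.0
        assert ic025 < 0.0

    def test_worked_example_chi_square_identity(self):
        # Gamma(5.5, rate 2.5) == chi2(11)/5, so the exact posterior 2.5th
        # percentile has a chi-square closed form
        ic, ic025 = bcpnn_stats(WORKED)
        assert ic == pytest.approx(math.log2(5.5 / 2.5))
        assert ic025 == pytest.approx(math.log2(stats.chi2.ppf(0.025, 11) / 5),
                                      abs=1e-9)

    def test_ic025_below_ic_always(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
            if a + b + c + d == 0:
                continue
            ic, ic025 = bcpnn_stats(ContingencyTable(a, b, c, d))
            assert ic025 < ic

    def test_large_count_limit(self):
        # at fixed a/E the shrinkage washes out: IC -> log2(a/E)
        t = ContingencyTable(4000, 996000, 1000, 8999000)
        ic, _ = bcpnn_stats(t)
        assert ic == pytest.approx(math.log2(t.a / t.E), abs=0.01)

    def test_two_sigma_variant(self):
        ic, ic025 = bcpnn_stats(WORKED, method="two_sigma")
        sd = math.sqrt(special.polygamma(1, 5.5)) / math.log(2)
        assert ic025 == pytest.approx(ic - 2 * sd)


class TestMgps:
    def test_conjugate_closed_form(self):
        """Identical Gamma(1,1) components reduce to textbook conjugacy."""
        prior = MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        t = ContingencyTable(3, 1, 0, 8)  # a=3, E=1
        ebgm, eb05 = mgps_score(t, prior)
        assert ebgm == pytest.approx(math.exp(special.digamma(4) - math.log(2)),
                                     abs=1e-6)
        assert eb05 == pytest.approx(stats.chi2.ppf(0.05, 8) / 4, abs=1e-6)

    def test_quantile_satisfies_cdf(self):
        prior = MgpsPrior(0.3, 0.2, 2.5, 3.0, 0.4)
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
            t = ContingencyTable(a, b, c, d)
            ebgm, eb05 = mgps_score(t, prior)
            assert eb05 < ebgm
            from faerspv.signals import _posterior_weight
            Q = _posterior_weight(t.a, t.E, prior)
            cdf = (Q * stats.gamma.cdf(eb05, prior.alpha1 + t.a,
                                       scale=1 / (prior.beta1 + t.E))
                   + (1 - Q) * stats.gamma.cdf(eb05, prior.alpha2 + t.a,
                                               scale=1 / (prior.beta2 + t.E)))
            assert cdf == pytest.approx(0.05, abs=1e-6)

    def test_asymptotic_consistency(self):
        # a = 500 with a/E = 2 fixed: shrinkage becomes negligible
        prior = MgpsPrior(*MGPS_CONVENTIONAL_START)
        t = ContingencyTable(500, 999500, 24500, 98975500)
        assert abs(t.a / t.E - 2.0) / 2.0 < 0.01
        ebgm, _ = mgps_score(t, prior)
        assert ebgm == pytest.approx(t.a / t.E, rel=0.01)

    def test_zero_expected_undefined(self):
        prior = MgpsPrior(1, 1, 1, 1, 0.5)
        ebgm, eb05 = mgps_score(ContingencyTable(0, 10, 0, 90), prior)
        assert np.isnan(ebgm) and np.isnan(eb05)

    def test_fit_dominates_truth_loglik(self):
        rng = np.random.default_rng(11)
        truth = MGPS_CONVENTIONAL_START
        n = 800
        E = rng.uniform(0.5, 20, n)
        comp = rng.random(n) < truth[4]
        lam = np.where(comp, rng.gamma(truth[0], 1 / truth[1], n),
                       rng.gamma(truth[2], 1 / truth[3], n))
        a = rng.poisson(lam * E)
        prior = fit_mgps_prior((a, E), include_zeros=True, seed=11)
        assert prior.loglik >= nb_mixture_loglik(a.astype(float), E, *truth)

    def test_all_zero_counts_rejected(self):
        a = np.zeros(10)
        E = np.ones(10)
        with pytest.raises(ValueError, match="a >= 1"):
            fit_mgps_prior((a, E))

    def test_invalid_prior_parameters_rejected(self):
        with pytest.raises(ValueError):
            MgpsPrior(-1.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            MgpsPrior(1.0, 1.0, 1.0, 1.0, 1.5)


class TestCalling:
    def test_worked_example_fails_bayesian_criteria(self):
        s = call_signal(SignalScores(a=5, prr=4.0, chi2=6.25, ror_lo=1.286,
                                     ic025=-0.390, eb05=0.683))
        assert s.prr_flag and s.ror_flag
        assert not s.ic_flag and not s.ebgm_flag and not s.key

    def test_all_criteria_met(self):
        s = call_signal(SignalScores(a=20, prr=5.0, chi2=40.0, ror_lo=2.5,
                                     ic025=0.8, eb05=2.4))
        assert s.key

    def test_minimum_report_count_gates_key(self):
        s = call_signal(SignalScores(a=2, prr=5.0, chi2=40.0, ror_lo=2.5,
                                     ic025=0.8, eb05=2.4))
        assert not s.prr_flag and not s.key

    def test_boundary_conventions(self):
        # >= for PRR/chi2/EB05, strict > for ROR025 and IC025
        s = call_signal(SignalScores(a=3, prr=2.0, chi2=4.0, ror_lo=1.0,
                                     ic025=0.0, eb05=2.0))
        assert s.prr_flag and s.ebgm_flag
        assert not s.ror_flag and not s.ic_flag

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 50), st.floats(0, 100), st.integers(0, 50),
           st.floats(0, 5), st.floats(-2, 2), st.floats(0, 5),
           st.floats(0.01, 10))
    def test_monotone_in_each_statistic(self, prr, chi2, a, ror_lo, ic025,
                                        eb05, bump):
        """Increasing any one statistic never flips its flag true -> false."""
        base = call_signal(SignalScores(a=a, prr=prr, chi2=chi2, ror_lo=ror_lo,
                                        ic025=ic025, eb05=eb05))
        for attr in ("prr", "chi2", "ror_lo", "ic025", "eb05"):
            kwargs = dict(a=a, prr=prr, chi2=chi2, ror_lo=ror_lo,
                          ic025=ic025, eb05=eb05)
            kwargs[attr] = kwargs[attr] + bump
            bumped = call_signal(SignalScores(**kwargs))
            flag = {"prr": "prr_flag", "chi2": "prr_flag", "ror_lo": "ror_flag",
                    "ic025": "ic_flag", "eb05": "ebgm_flag"}[attr]
            assert getattr(bumped, flag) >= getattr(base, flag)


class TestRanking:
    def _scores(self):
        mk = lambda a, ebgm, key: call_signal(
            SignalScores(a=a, prr=5, chi2=40, ror_lo=2, ic025=1, eb05=3,
                         ebgm=ebgm)) if key else SignalScores(a=a, ebgm=ebgm)
        return {"P1": mk(10, 3.0, True), "P2": mk(7, 5.0, True),
                "P3": mk(7, 4.0, True), "P4": mk(2, 9.0, False)}

    def test_rank_by_count_with_tiebreak(self):
        top = faerspv.rank_signals(self._scores(), by="count", k=3)
        assert top == ["P1", "P2", "P3"]  # tie on a=7 broken by EBGM

    def test_rank_by_ebgm(self):
        top = faerspv.rank_signals(self._scores(), by="ebgm", k=2)
        assert top == ["P2", "P3"]  # P4 is not a key signal

    def test_fewer_than_k(self):
        assert len(faerspv.rank_signals(self._scores(), k=10)) == 3

    def test_no_key_signals(self):
        assert faerspv.rank_signals({"P": SignalScores(a=5)}, k=5) == []


class TestSignalMatrix:
    def test_row_sums_and_union_columns(self):
        key = call_signal(SignalScores(a=9, prr=5, chi2=40, ror_lo=2, ic025=1,
                                       eb05=3))
        non = SignalScores(a=1)
        m = faerspv.signal_matrix({"d1": {"P1": key, "P2": key},
                                   "d2": {"P2": key, "P3": non},
                                   "d3": {"P3": non}})
        assert m.pts == ["P1", "P2"]
        assert m.set_sizes == {"d1": 2, "d2": 1, "d3": 0}
        assert m.signal_set("d3") == frozenset()
        assert m.values.shape == (3, 2)
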