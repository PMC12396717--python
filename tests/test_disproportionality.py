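"""The four disproportionality statistics, their intervals and flags."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency

from pvsignal import disproportionality as dp
from pvsignal.contingency import ContingencyTable

cells = st.integers(min_value=1, max_value=50_000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def back_pain_table() -> ContingencyTable:
    n, drug_total, a = 51_009_924, 12_281, 1_979
    c = (a / drug_total) / 41.49 * (n - drug_total)
    return ContingencyTable(a, drug_total - a, c, n - drug_total - c)


class TestRor:
    def test_published_worked_example(self):
        est, (lo, hi) = dp.ror(back_pain_table())
        assert round(est, 2) == 49.27
        assert round(lo, 2) == pytest.approx(46.94, abs=0.02)
        assert round(hi, 2) == pytest.approx(51.71, abs=0.02)

    def test_symmetric_table_is_null(self):
        est, _ = dp.ror(ContingencyTable(10, 10, 10, 10))
        assert est == 1.0

    def test_cross_product(self):
        est, _ = dp.ror(ContingencyTable(5, 5, 10, 90))
        assert est == pytest.approx(9.0)

    def test_zero_cell_undefined_without_continuity(self):
        t = ContingencyTable(0, 10, 10, 100)
        est, (lo, hi) = dp.ror(t)
        assert math.isnan(est) and math.isnan(lo)
        est_c, _ = dp.ror(t.with_continuity())
        assert est_c > 0


class TestPrr:
    def test_published_worked_example(self):
        est, _ = dp.prr(back_pain_table())
        assert round(est, 2) == 41.49

    def test_proportional_table_is_null(self):
        est, _ = dp.prr(ContingencyTable(5, 45, 10, 90))
        assert est == pytest.approx(1.0)

    def test_hand_computed(self):
        est, _ = dp.prr(ContingencyTable(5, 5, 10, 90))
        assert est == pytest.approx(5.0)


class TestChi2:
    def test_equal_proportions_zero(self):
        assert dp.chi2(ContingencyTable(10, 90, 20, 180)) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert dp.chi2(ContingencyTable(20, 80, 100, 800)) == pytest.approx(6.734006734)

    def test_agrees_with_generic_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 10_000, size=4)
            ours = dp.chi2(ContingencyTable(a, b, c, d))
            ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            assert abs(ours - ref) <= 1e-9 * max(1.0, ref)


class TestBcpnn:
    def test_published_worked_example(self):
        assert round(dp.ic(back_pain_table()), 2) == 5.36

    def test_independence_gives_zero(self):
        # a equals its expectation (a+b)(a+c)/N exactly
        t = ContingencyTable(10, 990, 990, 98_010)
        assert dp.ic(t) == pytest.approx(0.0, abs=1e-12)

    def test_doubled_observed_gives_one_bit(self):
        t = ContingencyTable(20, 980, 990, 98_010)
        ratio = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
        assert ratio == pytest.approx(2.0, rel=2e-2)
        assert dp.ic(t) == pytest.approx(math.log2(ratio))

    def test_credible_bound_defined_even_at_zero_count(self):
        e_ic, v_ic, ic025 = dp.ic_credible(ContingencyTable(0, 100, 100, 10_000))
        assert math.isfinite(e_ic) and v_ic > 0 and ic025 < e_ic

    def test_e_ic_near_zero_under_independence_at_scale(self):
        t = ContingencyTable(100, 9_900, 9_900, 980_100)
        e_ic, _, _ = dp.ic_credible(t)
        assert abs(e_ic) < 0.05

    def test_posterior_mean_shrinks_toward_zero(self):
        t = ContingencyTable(4, 8, 6, 10_000)
        e_ic, _, _ = dp.ic_credible(t)
        assert 0 < e_ic < dp.ic(t)


class TestEbgm:
    def test_published_worked_examples(self):
        assert round(dp.ebgm(back_pain_table())[0], 2) == 41.09
        n, drug_total = 51_009_924, 12_281
        for a, prr, expected in [(4, 89.30, 87.44), (6, 212.95, 202.61)]:
            c = (a / drug_total) / prr * (n - drug_total)
            t = ContingencyTable(a, drug_total - a, c, n - drug_total - c)
            assert round(dp.ebgm(t)[0], 2) == expected

    def test_independence_is_unity(self):
        est, _ = dp.ebgm(ContingencyTable(10, 990, 990, 98_010))
        assert est == pytest.approx(1.0)


class TestWaldP:
    def test_null_estimate_p_one(self):
        assert dp.wald_p(0.0, 0.5) == 1.0

    def test_huge_z_hits_floor(self):
        assert dp.wald_p(100.0, 0.01) == dp.P_FLOOR

    def test_z_1p96_is_5_percent(self):
        assert dp.wald_p(1.96 * 0.5, 0.5) == pytest.approx(0.05, abs=1e-3)


class TestBonferroni:
    def test_published_threshold(self):
        assert 0.05 / 12_281 == pytest.approx(4.07e-6, rel=1e-3)
        assert dp.bonferroni(4.0e-6, 12_281) is dp.BonferroniClass.STRONG
        assert dp.bonferroni(4.1e-6, 12_281) is dp.BonferroniClass.POTENTIAL

    def test_nominal_only_is_potential(self):
        assert dp.bonferroni(0.04, 12_281) is dp.BonferroniClass.POTENTIAL

    def test_m_one_reduces_to_nominal(self):
        assert dp.bonferroni(0.04, 1) is dp.BonferroniClass.STRONG
        assert dp.bonferroni(0.06, 1) is dp.BonferroniClass.NON_SIGNIFICANT


class TestConsensus:
    def test_two_records_never_signal(self):
        t = ContingencyTable(2, 10, 5, 100_000)
        e = dp.evaluate(t)
        assert e.ror > 100 and not e.consensus_signal

    def test_back_pain_is_a_signal(self):
        assert dp.evaluate(back_pain_table()).consensus_signal

    def test_null_table_is_not(self):
        assert not dp.evaluate(ContingencyTable(10, 10, 10, 10)).consensus_signal


class TestCrossStatisticProperties:
    @given(tables)
    def test_ic_is_log2_ebgm(self, t):
        assert dp.ic(t) == pytest.approx(math.log2(dp.ebgm(t)[0]), abs=1e-12)

    @given(tables)
    def test_direction_coherence(self, t):
        def sign(x):
            return 0 if abs(x) < 1e-12 else math.copysign(1, x)

        ror_est, _ = dp.ror(t)
        prr_est, _ = dp.prr(t)
        assert sign(math.log(ror_est)) == sign(math.log(prr_est)) == sign(dp.ic(t))

    @given(tables)
    def test_ror_more_extreme_than_prr(self, t):
        ror_est, _ = dp.ror(t)
        prr_est, _ = dp.prr(t)
        if prr_est > 1:
            assert ror_est >= prr_est * (1 - 1e-12)
        elif prr_est < 1:
            assert ror_est <= prr_est * (1 + 1e-12)

    @given(tables)
    def test_signal_estimate_invariants(self, t):
        e = dp.evaluate(t)
        assert e.ror > 0 and e.prr > 0 and e.ebgm > 0
        assert e.ic == pytest.approx(math.log2(e.ebgm), abs=1e-12)
        assert dp.P_FLOOR <= e.p_ror <= 1.0
        assert e.ror_ci95[0] <= e.ror <= e.ror_ci95[1]
        assert e.ic025 <= e.e_ic


def test_signal_table_sorted_by_ebgm_then_count_then_term():
    tables_in = {
        "B": ContingencyTable(10, 90, 10, 890),
        "A": ContingencyTable(10, 90, 10, 890),
        "C": ContingencyTable(50, 50, 10, 890),
        "D": ContingencyTable(2, 98, 500, 400),
    }
    df = dp.signal_table(tables_in)
    assert list(df["PT"]) == ["C", "A", "B", "D"]
    assert list(df.columns) == dp.SIGNAL_TABLE_COLUMNS
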