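import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.optimize import brentq

from pvkit import dispro
from pvkit.dispro import (
    DUMOUCHEL_START,
    BcpnnPriors,
    GammaMixturePrior,
    bcpnn_ic,
    bonferroni,
    ebgm,
    fit_mgps_prior,
    prr,
    ror,
    signal_table,
)

from conftest import table

cells = st.integers(min_value=1, max_value=5_000)
tables_strategy = st.builds(table, cells, cells, cells, cells)


class TestRor:
    def test_independence_gives_one(self):
        assert ror(table(10, 90, 100, 900)).ror == pytest.approx(1.0)

    def test_value_and_ci_against_log_scale_oracle(self):
        r = ror(table(20, 80, 100, 9800))
        assert r.ror == pytest.approx(24.5)
        # independent log-scale evaluation
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800)
        assert r.ci_low == pytest.approx(math.exp(math.log(24.5) - 1.959964 * se),
                                         rel=1e-6)
        assert r.ci_high == pytest.approx(math.exp(math.log(24.5) + 1.959964 * se),
                                          rel=1e-6)

    def test_haldane_correction_on_zero_cell(self):
        r = ror(table(0, 10, 10, 100))
        assert r.corrected
        assert r.ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))

    def test_zero_cell_without_correction_flags_undefined(self):
        r = ror(table(0, 10, 10, 100), haldane=False)
        assert math.isnan(r.ror)

    @settings(deadline=None, max_examples=100)
    @given(tables_strategy)
    def test_ci_brackets_estimate(self, t):
        r = ror(t)
        assert r.ci_low <= r.ror <= r.ci_high


class TestPrr:
    def test_independence(self):
        p = prr(table(10, 90, 100, 900))
        assert p.prr == pytest.approx(1.0)
        assert p.chi2 == pytest.approx(0.0)
        assert p.p == pytest.approx(1.0)

    def test_value_and_chi2_against_expected_counts_oracle(self):
        t = table(20, 80, 100, 9800)
        p = prr(t)
        assert p.prr == pytest.approx(19.8)
        # oracle: sum (O-E)^2/E over the four cells
        n = t.n
        exp = [
            (t.a + t.b) * (t.a + t.c) / n,
            (t.a + t.b) * (t.b + t.d) / n,
            (t.c + t.d) * (t.a + t.c) / n,
            (t.c + t.d) * (t.b + t.d) / n,
        ]
        obs = [t.a, t.b, t.c, t.d]
        chi2_oracle = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert p.chi2 == pytest.approx(chi2_oracle, rel=1e-12)
        assert p.p == pytest.approx(stats.chi2.sf(chi2_oracle, 1))

    @settings(deadline=None, max_examples=100)
    @given(tables_strategy)
    def test_chi2_equals_squared_two_proportion_z(self, t):
        p = prr(t)
        p1 = t.a / (t.a + t.b)
        p2 = t.c / (t.c + t.d)
        pool = (t.a + t.c) / t.n
        z = (p1 - p2) / math.sqrt(
            pool * (1 - pool) * (1 / (t.a + t.b) + 1 / (t.c + t.d))
        )
        assert p.chi2 == pytest.approx(z * z, rel=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(1, 20), st.integers(2_000, 5_000),
           st.integers(1, 200), st.integers(100_000, 500_000))
    def test_rare_event_ror_close_to_prr(self, a, b, c, d):
        # when a << a+c and b << b+d the odds ratio and the proportional
        # reporting ratio agree closely
        t = table(a, b, c, d)
        r, p = ror(t), prr(t)
        assert abs(r.ror - p.prr) / p.prr < 0.05

    def test_zero_c_flag(self):
        p = prr(table(5, 10, 0, 100), haldane=False)
        assert math.isnan(p.prr)


class TestBcpnn:
    def test_near_independence_large_table(self):
        ic = bcpnn_ic(table(1000, 9000, 10000, 90000))
        assert abs(ic.e_ic) < 0.02

    def test_term_by_term_oracle(self):
        t = table(25, 75, 150, 9750)
        ic = bcpnn_ic(t)
        # independent re-evaluation of the closed form
        a, n = 25.0, 10_000.0
        row, col = 100.0, 175.0
        a1 = b1 = g11 = 1.0
        al = be = 2.0
        gamma = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
        e = math.log2((a + g11) * (n + al) * (n + be)
                      / ((n + gamma) * (row + a1) * (col + b1)))
        v = (
            (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - row + al - a1) / ((row + a1) * (1 + n + al))
            + (n - col + be - b1) / ((col + b1) * (1 + n + be))
        ) / math.log(2) ** 2
        assert ic.e_ic == pytest.approx(e, rel=1e-12)
        assert ic.v_ic == pytest.approx(v, rel=1e-12)
        assert ic.ic025 == pytest.approx(e - 2 * math.sqrt(v), rel=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.builds(table, st.integers(0, 500), cells, cells, cells))
    def test_ic025_below_expectation(self, t):
        ic = bcpnn_ic(t)
        assert ic.ic025 < ic.e_ic
        assert ic.v_ic > 0


class TestMgps:
    def test_prior_recovery_from_single_gamma_simulation(self):
        # relative risks drawn from Gamma(shape 2, rate 2), prior mean 1
        rng = np.random.default_rng(42)
        lam = rng.gamma(2.0, 1 / 2.0, size=5_000)
        e = rng.uniform(0.5, 20.0, size=5_000)
        a = rng.poisson(lam * e)
        prior = fit_mgps_prior(a=a, expected=e)
        assert abs(prior.mean - 1.0) < 0.10

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_mgps_prior(a=np.zeros(30), expected=np.ones(30))

    def test_fit_not_worse_than_start(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(1, 10, size=200)
        a = rng.poisson(e)
        prior = fit_mgps_prior(a=a, expected=e)
        theta_fit = np.array([
            math.log(prior.alpha1), math.log(prior.beta1),
            math.log(prior.alpha2), math.log(prior.beta2),
            math.log(prior.w / (1 - prior.w)),
        ])
        s = DUMOUCHEL_START
        theta0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                           math.log(s[3]), math.log(s[4] / (1 - s[4]))])
        assert dispro._mixture_loglik(theta_fit, a, e) >= \
            dispro._mixture_loglik(theta0, a, e) - 1e-6

    def test_invalid_prior_parameters_rejected(self):
        with pytest.raises(ValueError):
            GammaMixturePrior(0.0, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            GammaMixturePrior(1, 1, 1, 1, 1.5)


class _FakeTable:
    level = "PT"
    label = "x"

    def __init__(self, a, expected):
        self.a = a
        self.expected = expected


class TestEbgm:
    prior = GammaMixturePrior(*DUMOUCHEL_START)

    def test_large_count_limit(self):
        r = ebgm(_FakeTable(500, 500.0), self.prior)
        assert 0.9 <= r.ebgm <= 1.1

    def test_quadrature_oracle(self):
        r = ebgm(_FakeTable(5, 1.0), self.prior)
        p = self.prior

        def prior_pdf(lam):
            return (p.w * stats.gamma.pdf(lam, p.alpha1, scale=1 / p.beta1)
                    + (1 - p.w) * stats.gamma.pdf(lam, p.alpha2, scale=1 / p.beta2))

        def unnorm(lam):
            return prior_pdf(lam) * stats.poisson.pmf(5, lam)

        z, _ = integrate.quad(unnorm, 0, 200, limit=200)
        m, _ = integrate.quad(lambda l: math.log(l) * unnorm(l), 1e-12, 200,
                              limit=200)
        oracle_ebgm = math.exp(m / z)
        oracle_q05 = brentq(
            lambda x: integrate.quad(unnorm, 0, x, limit=200)[0] / z - 0.05,
            1e-6, 50,
        )
        assert r.ebgm == pytest.approx(oracle_ebgm, rel=1e-3)
        assert r.ebgm05 == pytest.approx(oracle_q05, rel=1e-3)

    def test_strictly_increasing_in_a(self):
        vals = [ebgm(_FakeTable(a, 5.0), self.prior).ebgm for a in range(1, 40)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_shrinkage_toward_one_weakens_with_evidence(self):
        # non-marginal grid: 1 <= EBGM <= a/E, shrinkage decreasing in a
        e = 2.0
        shrinks = []
        for a in (5, 10, 20, 50, 100):
            r = ebgm(_FakeTable(a, e), self.prior)
            ratio = a / e
            assert 1.0 <= r.ebgm <= ratio * 1.001
            assert r.ebgm05 <= r.ebgm
            shrinks.append((ratio - r.ebgm) / ratio)
        assert all(x > y for x, y in zip(shrinks, shrinks[1:]))

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            ebgm(_FakeTable(5, 0.0), self.prior)


class TestBonferroni:
    def test_identity_at_m_one(self):
        assert bonferroni(0.03, 1) == 0.03

    def test_direct_product(self):
        assert bonferroni(0.0002, 100) == pytest.approx(0.02)

    def test_cap_at_one(self):
        assert bonferroni(0.01, 153) == 1.0

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02], 1)


class TestSignalTable:
    def test_columns_and_invariants(self, toy_reports):
        from pvkit.contingency import build_tables

        # a larger synthetic batch so the prior fit is meaningful
        rng = np.random.default_rng(3)
        tables = [table(int(a) + 1, 200, int(c) + 1, 20_000, label=f"L{i}")
                  for i, (a, c) in enumerate(zip(rng.poisson(5, 40),
                                                 rng.poisson(50, 40)))]
        df = signal_table(tables)
        assert len(df) == 40
        assert (df["ror_ci_low"] <= df["ror"]).all()
        assert (df["ror"] <= df["ror_ci_high"]).all()
        assert (df["ic025"] <= df["e_ic"]).all()
        assert (df["ebgm05"] <= df["ebgm"]).all()
        assert df["p_adj"].between(0, 1).all()
        assert (df["p_adj"] >= df["p_chi2"] - 1e-15).all()
        assert df.attrs["bonferroni_m"] == 40
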