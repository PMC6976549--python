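"""Kendall auxiliaries, single-lineage occupancy, and the master equation."""

import numpy as np
import pytest

from bdlik import (
    alpha,
    make_constant_rates,
    make_linear_dd_rates,
    make_time_dependent_rates,
    single_lineage_distribution,
    solve_master_equation,
    xi_eta,
    xi_eta_rho,
)
from bdlik.errors import DomainError, OrderingError, TruncationError, UnsupportedModelError

LN2 = float(np.log(2.0))


class TestAlpha:
    def test_constant_closed_form(self):
        m = make_constant_rates(0.8, 0.1)
        assert alpha(m, 0.0, 2.0) == pytest.approx(np.exp(-1.4), rel=1e-12)

    def test_empty_interval_is_one(self, td_model):
        assert alpha(td_model, 1.3, 1.3) == 1.0

    def test_time_dependent_quadrature(self):
        # lambda(t) = 0.5 + 0.1 t, mu = 0.1: integral of (mu - lambda) over
        # [0,1] is -(0.4 + 0.05) = -0.45 (exact antiderivative)
        m = make_time_dependent_rates(lambda t: 0.5 + 0.1 * t, lambda t: 0.1)
        assert alpha(m, 0.0, 1.0) == pytest.approx(np.exp(-0.45), abs=1e-10)

    def test_ordering_and_model_errors(self, const_model, dd_model):
        with pytest.raises(OrderingError):
            alpha(const_model, 2.0, 1.0)
        with pytest.raises(UnsupportedModelError):
            alpha(dd_model, 0.0, 1.0)


class TestXiEta:
    def test_empty_interval(self, const_model):
        pair = xi_eta(const_model, 2.0, 2.0)
        assert pair.xi == 0.0 and pair.eta == 0.0

    def test_pure_birth_closed_form(self):
        # eta = 1 - e^(-lambda dt) for pure birth; xi = 0
        m = make_constant_rates(LN2, 0.0)
        pair = xi_eta(m, 0.0, 1.0)
        assert pair.xi == 0.0
        assert pair.eta == pytest.approx(0.5, rel=1e-12)

    def test_quadrature_path_matches_constant_closed_form(self):
        lam, mu, dt = 0.8, 0.4, 1.0
        via_fn = make_time_dependent_rates(lambda t: lam, lambda t: mu)
        pair_q = xi_eta(via_fn, 0.0, dt)
        e = np.exp(-(lam - mu) * dt)
        assert pair_q.xi == pytest.approx(mu * (1 - e) / (lam - mu * e), abs=1e-10)
        assert pair_q.eta == pytest.approx(lam * (1 - e) / (lam - mu * e), abs=1e-10)

    def test_critical_limit_continuous(self):
        # closed forms are 0/0 at lambda = mu; the limit is lam*dt/(1+lam*dt)
        dt = 2.0
        at = xi_eta(make_constant_rates(0.5, 0.5), 0.0, dt)
        near = xi_eta(make_constant_rates(0.5 + 1e-10, 0.5), 0.0, dt)
        assert np.isfinite(at.xi) and np.isfinite(at.eta)
        assert at.xi == pytest.approx(1.0 / 2.0, rel=1e-9)  # 0.5*2/(1+1) = 0.5
        assert at.xi == pytest.approx(near.xi, abs=1e-8)
        assert at.eta == pytest.approx(near.eta, abs=1e-8)

    def test_monotone_in_window_length(self, const_model):
        dts = np.linspace(0.1, 5.0, 12)
        xis = [xi_eta(const_model, 0.0, d).xi for d in dts]
        etas = [xi_eta(const_model, 0.0, d).eta for d in dts]
        assert np.all(np.diff(xis) >= 0)
        assert np.all(np.diff(etas) >= 0)


class TestXiEtaRho:
    def test_full_sampling_reduces_to_plain(self, const_model):
        a = xi_eta(const_model, 0.0, 2.0)
        b = xi_eta_rho(const_model, 1.0, 0.0, 2.0)
        assert (a.xi, a.eta) == (b.xi, b.eta)

    def test_empty_interval(self, const_model):
        pair = xi_eta_rho(const_model, 0.3, 1.5, 1.5)
        assert pair.xi == 0.0 and pair.eta == 0.0

    def test_quadrature_matches_constant_closed_form(self):
        lam, mu, f, dt = 0.8, 0.4, 0.5, 1.0
        via_fn = make_time_dependent_rates(lambda t: lam, lambda t: mu)
        pair = xi_eta_rho(via_fn, f, 0.0, dt)
        e = np.exp(-(lam - mu) * dt)
        denom = f * lam + ((1 - f) * lam - mu) * e
        assert pair.xi == pytest.approx((f * mu + ((1 - f) * lam - mu) * e) / denom, abs=1e-10)
        assert pair.eta == pytest.approx(f * lam * (1 - e) / denom, abs=1e-10)

    def test_thinned_geometric_first_principles(self, const_model):
        """xi~ = G(1-f) and eta~ = f eta / (1 - (1-f) eta): sampling each
        descendant independently thins the geometric occupancy law."""
        f, t_p = 0.35, 3.0
        plain = xi_eta(const_model, 0.0, t_p)
        tilde = xi_eta_rho(const_model, f, 0.0, t_p)
        z = 1.0 - f
        g_at_z = (plain.xi + (1 - plain.xi - plain.eta) * z) / (1 - z * plain.eta)
        assert tilde.xi == pytest.approx(g_at_z, rel=1e-10)
        assert tilde.eta == pytest.approx(f * plain.eta / (1 - z * plain.eta), rel=1e-10)

    def test_consistent_with_thinned_master_equation(self, const_model):
        """xi~ and eta~ agree with the master-equation occupancy after a
        discrete mass-extinction step (binomial survival thinning) at the
        present."""
        from scipy.stats import binom

        f, t_p, N = 0.4, 2.0, 150
        init = np.zeros(N + 1)
        init[1] = 1.0
        p = solve_master_equation(const_model, init, 0.0, t_p, N, tol=1e-10)
        thinned = np.zeros(N + 1)
        for n in range(N + 1):
            thinned[: n + 1] += p[n] * binom.pmf(np.arange(n + 1), n, f)
        pair = xi_eta_rho(const_model, f, 0.0, t_p)
        assert thinned[0] == pytest.approx(pair.xi, abs=1e-7)
        ratios = thinned[2:20] / thinned[1:19]
        np.testing.assert_allclose(ratios, pair.eta, atol=1e-6)

    def test_domain(self, const_model):
        with pytest.raises(DomainError):
            xi_eta_rho(const_model, 0.0, 0.0, 1.0)
        with pytest.raises(DomainError):
            xi_eta_rho(const_model, 1.2, 0.0, 1.0)


class TestSingleLineage:
    def test_degenerate_interval(self, const_model):
        d = single_lineage_distribution(const_model, 1.0, 1.0, 5)
        assert d.probabilities[1] == 1.0
        assert d.probabilities[0] == 0.0
        assert np.all(d.probabilities[2:] == 0.0)

    def test_yule_closed_form(self):
        m = make_constant_rates(LN2, 0.0)
        d = single_lineage_distribution(m, 0.0, 1.0, 12)
        n = np.arange(1, 13)
        assert d.probabilities[0] == 0.0
        np.testing.assert_allclose(d.probabilities[1:], 0.5**n, rtol=1e-10)

    def test_geometric_ratio(self, const_model):
        d = single_lineage_distribution(const_model, 0.0, 2.0, 10)
        pair = xi_eta(const_model, 0.0, 2.0)
        ratios = d.probabilities[2:] / d.probabilities[1:-1]
        np.testing.assert_allclose(ratios, pair.eta, rtol=1e-10)

    def test_normalization_with_tail(self, const_model):
        d = single_lineage_distribution(const_model, 0.0, 2.0, 60)
        assert d.probabilities.sum() + d.tail_mass == pytest.approx(1.0, abs=1e-12)


class TestMasterEquation:
    def test_zero_interval_identity(self, const_model):
        init = np.zeros(21)
        init[2] = 1.0
        out = solve_master_equation(const_model, init, 1.0, 1.0, 20)
        np.testing.assert_array_equal(out, init)

    def test_single_lineage_geometric(self, const_model):
        N = 120
        init = np.zeros(N + 1)
        init[1] = 1.0
        out = solve_master_equation(const_model, init, 0.0, 2.0, N, tol=1e-10)
        oracle = single_lineage_distribution(const_model, 0.0, 2.0, N)
        np.testing.assert_allclose(out, oracle.probabilities, atol=1e-8)

    def test_two_lineages_convolution(self, const_model):
        """Starting from two independent lineages, the count distribution is
        the self-convolution of the single-lineage law."""
        N = 160
        init = np.zeros(N + 1)
        init[2] = 1.0
        out = solve_master_equation(const_model, init, 0.0, 2.0, N, tol=1e-10)
        single = single_lineage_distribution(const_model, 0.0, 2.0, N).probabilities
        conv = np.convolve(single, single)[: N + 1]
        np.testing.assert_allclose(out, conv, atol=1e-8)

    def test_probability_conserved_at_adequate_truncation(self, const_model):
        N = 200
        init = np.zeros(N + 1)
        init[2] = 1.0
        out = solve_master_equation(const_model, init, 0.0, 2.0, N, tol=1e-10)
        assert abs(out.sum() - 1.0) < 1e-8

    def test_truncation_error_raised_when_n_too_small(self):
        m = make_constant_rates(2.0, 0.0)
        init = np.zeros(6)
        init[2] = 1.0
        with pytest.raises(TruncationError):
            solve_master_equation(m, init, 0.0, 3.0, 5)

    def test_diversity_dependent_stays_within_capacity(self):
        m = make_linear_dd_rates(1.0, 8.0, 0.0)
        N = 12
        init = np.zeros(N + 1)
        init[2] = 1.0
        out = solve_master_equation(m, init, 0.0, 50.0, N, tol=1e-10)
        assert out.sum() == pytest.approx(1.0, abs=1e-7)
        assert np.all(out[9:] < 1e-7)  # capacity 8 caps the support
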