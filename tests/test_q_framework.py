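"""Q-vector propagation: branch ODE, node operator, conditioning, assembly."""

import numpy as np
import pytest

from bdlik import (
    BranchingTimes,
    SamplingScheme,
    apply_node,
    choose_truncation,
    conditioning_probability,
    initial_q_vector,
    kendall,
    loglik_div_indep_n,
    loglik_pure_birth_dd,
    loglik_q_n,
    loglik_q_rho,
    make_constant_rates,
    make_linear_dd_rates,
    propagate_branch,
    q_at_present,
    q_rhs,
)
from bdlik.q_framework import QVector
from bdlik.errors import TruncationError


def tridiagonal_generator(model, k, M, t):
    """Independent dense construction of the ODE generator matrix."""
    V = np.zeros((M + 1, M + 1))
    for m in range(M + 1):
        lam_km = model.speciation(k + m, t)
        mu_km = model.extinction(k + m, t)
        V[m, m] = -(lam_km + mu_km) * (m + k)
        if m >= 1:
            V[m, m - 1] = model.speciation(k + m - 1, t) * (m - 1 + 2 * k)
        if m + 1 <= M:
            V[m, m + 1] = model.extinction(k + m + 1, t) * (m + 1)
    return V


class TestRhs:
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_dense_matrix(self, dd_model, k):
        M = 8
        rng = np.random.default_rng(42)
        v = rng.random(M + 1)
        q = QVector(k=k, values=v, t=0.7)
        V = tridiagonal_generator(dd_model, k, M, 0.7)
        np.testing.assert_allclose(q_rhs(q, dd_model, 0.7), V @ v, rtol=1e-13)

    def test_zero_vector_maps_to_zero(self, const_model):
        q = QVector(k=2, values=np.zeros(6), t=0.0)
        assert np.all(q_rhs(q, const_model, 0.0) == 0.0)


class TestPropagateBranch:
    def test_zero_length_identity(self, const_model):
        q = initial_q_vector(0.0, 10)
        assert propagate_branch(q, const_model, 0.0, 0.0) is q

    def test_pure_birth_q0_closed_form(self):
        # dQ_0/dt = -k lambda Q_0 with zero extinction
        m = make_constant_rates(0.8, 0.0)
        for k in (2, 4):
            q = QVector(k=k, values=np.eye(40)[0], t=0.0)
            out = propagate_branch(q, m, 0.0, 1.5, tail_threshold=np.inf)
            assert out.component(0) == pytest.approx(np.exp(-k * 0.8 * 1.5), rel=1e-9)

    def test_matches_generating_function_coefficients(self, const_model):
        """Propagating delta_0 with k=2 yields the coefficients of
        H^2(z, t_c, t)."""
        from bdlik import H_series

        M = 120
        q = propagate_branch(initial_q_vector(0.0, M), const_model, 0.0, 1.0)
        h = H_series(const_model, 0.0, 1.0, M)
        h2 = (h * h).coefficients
        got = q.values * np.exp(q.log_scale)
        np.testing.assert_allclose(got, h2, atol=1e-10)

    def test_truncation_tail_error(self, const_model):
        with pytest.raises(TruncationError):
            propagate_branch(initial_q_vector(0.0, 4), const_model, 0.0, 3.0)


class TestApplyNode:
    def test_constant_rate_arithmetic(self, const_model):
        q = QVector(k=2, values=np.array([0.3, 0.1]), t=1.0)
        out = apply_node(q, make_constant_rates(1.0, 0.0), 1.0)
        np.testing.assert_allclose(out.values, [0.6, 0.2])
        assert out.k == 3

    def test_diversity_dependent_slots(self):
        m = make_linear_dd_rates(1.0, 10.0, 0.0)
        q = QVector(k=2, values=np.array([1.0, 1.0]), t=0.5)
        out = apply_node(q, m, 0.5)
        # m=0 slot: 2 * lambda_2 = 2*0.8; m=1 slot: 2 * lambda_3 = 2*0.7
        np.testing.assert_allclose(out.values, [1.6, 1.4])

    def test_zero_maps_to_zero(self, const_model):
        q = QVector(k=3, values=np.zeros(5), t=0.2)
        assert np.all(apply_node(q, const_model, 0.2).values == 0.0)


class TestQAtPresent:
    def test_two_tips_is_single_branch(self, const_model, two_tip_tree):
        direct = propagate_branch(initial_q_vector(0.0, 60), const_model, 0.0, 1.0)
        via_tree = q_at_present(const_model, two_tip_tree, 60)
        np.testing.assert_allclose(via_tree.values, direct.values, rtol=1e-12)

    def test_pure_birth_dd_product_formula(self):
        """Q_0 at the present equals prod i*lambda_i(t_i) *
        prod exp(-j int lambda_j)."""
        m = make_linear_dd_rates(1.0, 10.0, 0.0)
        bt = BranchingTimes(0.0, [1.0], 2.0)
        q = q_at_present(m, bt, 30, tol=1e-12, tail_threshold=np.inf)
        lam2, lam3 = 0.8, 0.7
        expected = 2 * lam2 * np.exp(-2 * lam2 * 1.0) * np.exp(-3 * lam3 * 1.0)
        assert q.component(0) == pytest.approx(expected, rel=1e-9)


class TestConditioning:
    def test_pure_birth_is_one(self):
        m = make_constant_rates(0.9, 0.0)
        p = conditioning_probability(m, 0.0, 2.0, 200, tail_threshold=np.inf)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_matches_one_minus_xi_squared(self, const_model):
        p = conditioning_probability(const_model, 0.0, 5.0, 700)
        pair = kendall.xi_eta(const_model, 0.0, 5.0)
        assert p == pytest.approx((1 - pair.xi) ** 2, rel=1e-8)

    def test_crown_weight_at_m_zero(self):
        assert 6.0 / ((0 + 2) * (0 + 3)) == 1.0


class TestLikelihoodAssembly:
    def test_two_tip_pure_birth_hand_value(self, two_tip_tree):
        m = make_constant_rates(0.8, 0.0)
        res = loglik_q_n(m, two_tip_tree, 0, 60)
        assert res.log_likelihood == pytest.approx(-1.6, abs=1e-9)

    @pytest.mark.parametrize("m_p", [0, 1, 2])
    def test_agrees_with_analytic_n(self, four_tip_tree, m_p):
        model = make_constant_rates(0.8, 0.3)
        lq = loglik_q_n(model, four_tip_tree, m_p, 700).log_likelihood
        la = loglik_div_indep_n(model, four_tip_tree, m_p).log_likelihood
        assert lq == pytest.approx(la, abs=1e-6)

    def test_agrees_with_pure_birth_dd(self):
        m = make_linear_dd_rates(1.0, 10.0, 0.0)
        bt = BranchingTimes(0.0, [1.0], 2.0)
        lq = loglik_q_n(m, bt, 0, 30, tail_threshold=np.inf).log_likelihood
        la = loglik_pure_birth_dd(m, bt).log_likelihood
        assert lq == pytest.approx(la, abs=1e-8)

    def test_rho_full_sampling_equals_n_zero(self, four_tip_tree):
        model = make_constant_rates(0.8, 0.3)
        a = loglik_q_rho(model, four_tip_tree, 1.0, 700).log_likelihood
        b = loglik_q_n(model, four_tip_tree, 0, 700).log_likelihood
        assert a == pytest.approx(b, abs=1e-12)

    def test_decomposition_identity(self, four_tip_tree):
        model = make_constant_rates(0.8, 0.3)
        res = loglik_q_n(model, four_tip_tree, 1, 700)
        assert res.log_likelihood == pytest.approx(
            res.log_numerator - res.log_combinatorial - res.log_conditioning,
            abs=1e-12,
        )


class TestChooseTruncation:
    def test_floor_rule(self):
        # high turnover over a long window keeps the deep m_p = 50 component
        # numerically resolvable
        model = make_constant_rates(0.8, 0.7)
        bt = BranchingTimes(0.0, [], 6.0)
        M = choose_truncation(bt, SamplingScheme.n_sampling(50), model)
        assert M >= 70

    def test_pure_birth_converges_quickly(self, two_tip_tree):
        m = make_constant_rates(0.8, 0.0)
        M, hist = choose_truncation(
            two_tip_tree, SamplingScheme.n_sampling(0), m, return_history=True
        )
        assert M >= 30
        assert abs(hist[-1][1] - hist[-2][1]) < 1e-9

    def test_longer_window_needs_larger_truncation(self, const_model):
        short = BranchingTimes(0.0, [], 1.0)
        long = BranchingTimes(0.0, [], 6.0)
        scheme = SamplingScheme.n_sampling(0)
        m_short = choose_truncation(short, scheme, const_model)
        m_long = choose_truncation(long, scheme, const_model)
        assert m_long > m_short

    def test_doubling_beyond_choice_is_stable(self, const_model):
        bt = BranchingTimes(0.0, [0.7, 1.5], 2.0)
        M = choose_truncation(bt, SamplingScheme.n_sampling(2), const_model)
        a = loglik_q_n(const_model, bt, 2, M).log_likelihood
        b = loglik_q_n(const_model, bt, 2, 2 * M).log_likelihood
        assert abs(a - b) < 1e-9
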