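"""Randomized cross-validation suites.

Each function draws random model/tree configurations from a seeded stream,
evaluates the same likelihood through two independent code paths, and
returns the observed discrepancies.  These are the executable versions of
the equivalence results the package is built around:

* diversity-independent rates, n-sampling: Q-framework vs breaking-the-tree
  closed form;
* diversity-independent rates, rho-sampling: Q-framework vs the tilded
  closed form, plus the generating-function identity
  P_s = f_p^{k_p} F_{k_p}(1 - f_p, t_p);
* diversity-dependent pure birth: Q-framework vs the finite product formula;
* the conditioning identity P_c = (1 - xi)^2;
* the oracle triangle: ODE propagation vs series coefficients vs composition
  sums.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from . import analytic, generating_oracle, kendall, q_framework
from .containers import BranchingTimes
from .rates import RateModel, make_constant_rates, make_linear_dd_rates, make_time_dependent_rates

__all__ = [
    "random_di_model",
    "random_branching_times",
    "n_sampling_equivalence",
    "rho_sampling_equivalence",
    "pure_birth_equivalence",
    "conditioning_identity",
    "oracle_triangle",
]

# Truncation used across the randomized diversity-independent sweeps; sized
# for the worst draws below (exponentially growing rates near criticality),
# where the missing-species distribution is widest.
SWEEP_M = 900


def random_di_model(rng: np.random.Generator, time_dependent: bool = False) -> RateModel:
    """Draw lambda in [0.1, 1], mu in [0, 0.9 lambda]; optionally modulate
    both exponentially in time (rate exponents in [-0.3, 0.3])."""
    lam = rng.uniform(0.1, 1.0)
    mu = rng.uniform(0.0, 0.9 * lam)
    if not time_dependent:
        return make_constant_rates(lam, mu)
    a = rng.uniform(-0.3, 0.3)
    b = rng.uniform(-0.3, 0.3)
    return make_time_dependent_rates(
        lambda t, lam=lam, a=a: lam * np.exp(a * t),
        lambda t, mu=mu, b=b: mu * np.exp(b * t),
    )


def random_branching_times(
    rng: np.random.Generator, k_p: int, t_c: float = 0.0, max_age: float = 3.0
) -> BranchingTimes:
    """Random strictly increasing branching times on a crown age in [1, max_age]."""
    depth = rng.uniform(1.0, max_age)
    internal = np.sort(rng.uniform(t_c, t_c + depth, size=k_p - 2))
    return BranchingTimes(t_c, internal.tolist(), t_c + depth)


def n_sampling_equivalence(
    n_configs: int,
    seed: int,
    *,
    time_dependent_fraction: float = 0.5,
    M: int = SWEEP_M,
    tol: float = 1e-10,
) -> np.ndarray:
    """|logL(Q-framework) - logL(closed form)| over random diversity-
    independent configurations with n-sampling."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_configs)
    for i in range(n_configs):
        model = random_di_model(rng, rng.random() < time_dependent_fraction)
        bt = random_branching_times(rng, int(rng.integers(2, 7)))
        m_p = int(rng.integers(0, 5))
        lq = q_framework.loglik_q_n(model, bt, m_p, M, tol=tol).log_likelihood
        la = analytic.loglik_div_indep_n(model, bt, m_p, tol=tol).log_likelihood
        out[i] = abs(lq - la)
    return out


def rho_sampling_equivalence(
    n_configs: int,
    seed: int,
    *,
    f_values=(0.2, 0.5, 0.9, 1.0),
    time_dependent_fraction: float = 0.5,
    M: int = SWEEP_M,
    tol: float = 1e-10,
):
    """Returns (|dlogL| array, |P_s - f^k F_k(1-f)| relative-error array)
    over random diversity-independent configurations with rho-sampling."""
    rng = np.random.default_rng(seed)
    dlog = np.empty(n_configs)
    ps_err = np.empty(n_configs)
    for i in range(n_configs):
        model = random_di_model(rng, rng.random() < time_dependent_fraction)
        bt = random_branching_times(rng, int(rng.integers(2, 7)))
        f_p = float(f_values[int(rng.integers(len(f_values)))])
        res_q = q_framework.loglik_q_rho(model, bt, f_p, M, tol=tol)
        res_a = analytic.loglik_div_indep_rho(model, bt, f_p, tol=tol)
        dlog[i] = abs(res_q.log_likelihood - res_a.log_likelihood)
        # generating-function identity for the sampling probability
        log_p_s = res_q.log_numerator
        series = generating_oracle.F_series(model, bt, bt.t_p, SWEEP_M, k=bt.k_p, tol=tol)
        p_s_gf = f_p**bt.k_p * series(1.0 - f_p)
        ps_err[i] = abs(np.exp(log_p_s) - p_s_gf) / abs(p_s_gf)
    return dlog, ps_err


def pure_birth_equivalence(
    n_trees: int, seed: int, *, M: int = 80, tol: float = 1e-12
) -> np.ndarray:
    """|dlogL| between the Q-framework and the finite product formula for
    linear diversity-dependent speciation without extinction.

    The tighter default ODE tolerance matches the sharper agreement this
    small, non-stiff pure-birth system admits."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_trees)
    for i in range(n_trees):
        k_p = int(rng.integers(2, 7))
        lam0 = rng.uniform(0.5, 1.5)
        K = rng.uniform(k_p + 2.0, 40.0)
        model = make_linear_dd_rates(lam0, K, 0.0)
        bt = random_branching_times(rng, k_p)
        # with zero extinction the m > 0 components never feed back into Q_0,
        # so the tail of the truncated vector cannot contaminate the result
        lq = q_framework.loglik_q_n(
            model, bt, 0, M, tol=tol, tail_threshold=np.inf
        ).log_likelihood
        la = analytic.loglik_pure_birth_dd(model, bt, tol=tol).log_likelihood
        out[i] = abs(lq - la)
    return out


def conditioning_identity(
    lambdas, mus_rel, *, delta: float = 3.0, M: int = 600, tol: float = 1e-10
) -> np.ndarray:
    """Relative error |P_c - (1 - xi)^2| / (1 - xi)^2 over a (lambda, mu)
    grid; mu = mu_rel * lambda for each mu_rel."""
    out = []
    for lam in lambdas:
        for rel in mus_rel:
            model = make_constant_rates(lam, rel * lam)
            p_c = q_framework.conditioning_probability(model, 0.0, delta, M, tol=tol)
            pair = kendall.xi_eta(model, 0.0, delta, tol=tol)
            exact = (1.0 - pair.xi) ** 2
            out.append(abs(p_c - exact) / exact)
    return np.asarray(out)


def oracle_triangle(
    n_configs: int, seed: int, *, M: int = SWEEP_M, tol: float = 1e-10
):
    """Pairwise discrepancies between the three routes to Q_{m_p}^{k_p}(t_p)
    for diversity-independent rates: ODE propagation, series coefficients,
    and the closed form with composition sums.

    Returns (ode_vs_series, series_vs_closed) arrays of relative errors.
    """
    rng = np.random.default_rng(seed)
    ode_vs_series = np.empty(n_configs)
    series_vs_closed = np.empty(n_configs)
    for i in range(n_configs):
        model = random_di_model(rng, rng.random() < 0.5)
        bt = random_branching_times(rng, int(rng.integers(2, 7)))
        m_p = int(rng.integers(0, 5))
        q = q_framework.q_at_present(model, bt, M, tol=tol)
        q_ode = q.component(m_p)
        q_series = generating_oracle.q_oracle(model, bt, m_p, tol=tol)
        # closed form: (k_p-1)! (1-xi_c)^2 (1-eta_c)^2 prod lambda (1-xi)(1-eta)
        # times the composition sum over the k_p branch slots
        pair_c = kendall.xi_eta(model, bt.t_c, bt.t_p, tol=tol)
        log_q = float(gammaln(bt.k_p)) + 2.0 * (
            np.log1p(-pair_c.xi) + np.log1p(-pair_c.eta)
        )
        etas = [pair_c.eta, pair_c.eta]
        for t_i in bt.internal:
            pair = kendall.xi_eta(model, t_i, bt.t_p, tol=tol)
            log_q += (
                np.log(model.speciation_t(t_i))
                + np.log1p(-pair.xi)
                + np.log1p(-pair.eta)
            )
            etas.append(pair.eta)
        q_closed = np.exp(log_q) * analytic.composition_sum(etas, m_p)
        scale = max(abs(q_series), abs(q_closed))
        ode_vs_series[i] = abs(q_ode - q_series) / scale
        series_vs_closed[i] = abs(q_series - q_closed) / scale
    return ode_vs_series, series_vs_closed
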