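"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by enumeration or direct
formula evaluation, independent of the library code paths they are used to
check."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from bdlik import (
    BranchingTimes,
    make_constant_rates,
    make_linear_dd_rates,
    make_time_dependent_rates,
)
from bdlik import kendall


@pytest.fixture
def const_model():
    return make_constant_rates(0.8, 0.4)


@pytest.fixture
def pure_birth_model():
    return make_constant_rates(0.8, 0.0)


@pytest.fixture
def dd_model():
    return make_linear_dd_rates(1.0, 10.0, 0.1)


@pytest.fixture
def td_model():
    """Time-dependent diversity-independent rates, constant in disguise-free
    form (forces the quadrature code path)."""
    return make_time_dependent_rates(lambda t: 0.5 + 0.1 * t, lambda t: 0.1)


@pytest.fixture
def two_tip_tree():
    return BranchingTimes(0.0, [], 1.0)


@pytest.fixture
def four_tip_tree():
    return BranchingTimes(0.0, [2.5, 4.0], 5.0)


def enumerate_compositions(total: int, parts: int):
    """All vectors of `parts` nonnegative integers summing to `total`."""
    if parts == 0:
        if total == 0:
            yield ()
        return
    for first in range(total + 1):
        for rest in enumerate_compositions(total - first, parts - 1):
            yield (first,) + rest


def composition_sum_bruteforce(etas, m_p: int) -> float:
    """Direct enumeration of sum over compositions of prod (m_j+1) eta_j^m_j."""
    total = 0.0
    for comp in enumerate_compositions(m_p, len(etas)):
        term = 1.0
        for m_j, eta in zip(comp, etas):
            term *= (m_j + 1) * eta**m_j
        total += term
    return total


def loglik_n_bruteforce(model, bt: BranchingTimes, m_p: int) -> float:
    """Breaking-the-tree likelihood with the composition sum evaluated by
    explicit enumeration (independent of the library's convolution route)."""
    k_p = bt.k_p
    pair_c = kendall.xi_eta(model, bt.t_c, bt.t_p)
    pairs = [kendall.xi_eta(model, t, bt.t_p) for t in bt.internal]
    value = math.factorial(k_p - 1) / math.comb(k_p + m_p, m_p)
    value *= (1.0 - pair_c.eta) ** 2
    for t_i, pair in zip(bt.internal, pairs):
        value *= model.speciation_t(t_i) * (1.0 - pair.xi) * (1.0 - pair.eta)
    etas = [pair_c.eta, pair_c.eta] + [p.eta for p in pairs]
    value *= composition_sum_bruteforce(etas, m_p)
    return math.log(value)


def chi_square_pvalue(observed_counts, expected_probs, n_total, min_expected=5.0):
    """Chi-square goodness-of-fit with automatic pooling of sparse bins."""
    from scipy.stats import chi2

    exp = np.asarray(expected_probs, dtype=float) * n_total
    obs = np.asarray(observed_counts, dtype=float)
    # pool trailing sparse bins
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        pooled_obs.append(acc_o)
        pooled_exp.append(acc_e)
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp)
    # renormalize expected to the observed total (tail beyond the bins)
    pooled_exp *= pooled_obs.sum() / pooled_exp.sum()
    stat = float(np.sum((pooled_obs - pooled_exp) ** 2 / pooled_exp))
    dof = max(len(pooled_obs) - 1, 1)
    return float(chi2.sf(stat, dof))
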