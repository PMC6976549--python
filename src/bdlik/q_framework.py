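"""Numerical likelihood framework via Q-vector propagation.

The quantity Q_m^k(t) tracks the probability that a realization of the
diversification process is consistent with the observed phylogeny up to time
t while carrying k observed lineages (ancestral to sampled tips) and m
missing species (extinct-to-be or unsampled).  Arranged as a vector over m,
it evolves by a tridiagonal linear ODE system along each branch interval

    dQ_m/dt = mu_{k+m+1} (m+1) Q_{m+1}
              + lambda_{k+m-1} (m - 1 + 2k) Q_{m-1}
              - (lambda_{m+k} + mu_{m+k}) (m + k) Q_m,

is multiplied through each node by the diagonal operator k * lambda_{k+m}(t_k)
(with k -> k + 1), and starts from Q_m^{k=2}(t_c) = delta_{m,0} (no missing
species at crown age).  At the present the likelihood is assembled as

    n-sampling:    L = Q_{m_p}^{k_p}(t_p) / (C(k_p + m_p, m_p) P_c)
    rho-sampling:  L = sum_m f_p^{k_p} (1 - f_p)^m Q_m^{k_p}(t_p) / P_c

where the conditioning probability P_c (both crown lineages survive to the
present, sampling ignored) is obtained by propagating the same system with
k = 2 and no node operators and weighting with 6 / ((m + 2)(m + 3)).

Numerics: the infinite system is truncated at m = M (no inflow from M + 1),
solved with a stiff-capable implicit method whose Jacobian is the exact
tridiagonal generator, and rescaled into a log-scale factor to avoid
underflow on old or species-rich trees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .analytic import log_binomial
from .containers import BranchingTimes, LikelihoodResult, SamplingScheme
from .errors import (
    DomainError,
    NumericalError,
    OrderingError,
    ResourceError,
    TruncationError,
)
from .rates import RateModel

__all__ = [
    "QVector",
    "initial_q_vector",
    "q_rhs",
    "propagate_branch",
    "apply_node",
    "q_at_present",
    "conditioning_probability",
    "loglik_q_n",
    "loglik_q_rho",
    "choose_truncation",
]

DEFAULT_TOL = 1e-10
# Q_M / max_m Q_m above this after a branch propagation signals that the
# truncation window is too small for the requested accuracy.
DEFAULT_TAIL_THRESHOLD = 1e-6


@dataclass(frozen=True)
class QVector:
    """Truncated Q-vector at a time point.

    The represented quantity is ``values * exp(log_scale)`` elementwise;
    ``values`` is kept near unit scale by periodic rescaling.
    """

    k: int
    values: np.ndarray
    t: float
    log_scale: float = 0.0

    @property
    def M(self) -> int:
        return len(self.values) - 1

    def component(self, m: int) -> float:
        """True (unscaled) value of Q_m."""
        return float(self.values[m] * np.exp(self.log_scale))


def initial_q_vector(t_c: float, M: int) -> QVector:
    """Q_m^{k=2}(t_c) = delta_{m,0}: no missing species at crown age."""
    if M < 0:
        raise DomainError(f"M must be >= 0, got {M}")
    values = np.zeros(M + 1)
    values[0] = 1.0
    return QVector(k=2, values=values, t=t_c, log_scale=0.0)


def _coefficient_builder(model: RateModel, k: int, M: int):
    """Return coeffs(t) -> (diag, sub, sup) for the tridiagonal generator.

    ``sub[i]`` multiplies Q_{m-1} in row m = i + 1; ``sup[i]`` multiplies
    Q_{m+1} in row m = i.  Rates are evaluated vectorized over diversity.
    """
    m = np.arange(M + 1, dtype=float)
    n_grid = np.arange(k - 1, k + M + 2)  # diversities k+m-1 .. k+M+1

    def coeffs(t):
        lam = np.asarray(model.speciation(n_grid, t), dtype=float)
        mu = np.asarray(model.extinction(n_grid, t), dtype=float)
        lam_km = lam[1 : M + 2]  # lambda_{k+m},  m = 0..M
        mu_km = mu[1 : M + 2]
        diag = -(lam_km + mu_km) * (m + k)
        sub = lam[1 : M + 1] * (m[1:] - 1.0 + 2.0 * k)  # lambda_{k+m-1}, m>=1
        sup = mu[2 : M + 2] * (m[: M] + 1.0)  # mu_{k+m+1}, m = 0..M-1
        return diag, sub, sup

    if model.is_time_independent:
        cached = coeffs(0.0)
        return lambda t: cached
    return coeffs


def q_rhs(q: QVector, model: RateModel, t: float) -> np.ndarray:
    """Right-hand side of the Q-vector ODE system at time ``t``."""
    diag, sub, sup = _coefficient_builder(model, q.k, q.M)(t)
    v = q.values
    dv = diag * v
    dv[1:] += sub * v[:-1]
    dv[:-1] += sup * v[1:]
    return dv


def propagate_branch(
    q: QVector,
    model: RateModel,
    t_start: float,
    t_end: float,
    *,
    tol: float = DEFAULT_TOL,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> QVector:
    """Integrate the Q-vector along a branch interval [t_start, t_end]."""
    if t_start > t_end:
        raise OrderingError(f"requires t_start <= t_end, got {t_start} > {t_end}")
    if abs(q.t - t_start) > 1e-9 * max(1.0, abs(t_start)):
        raise OrderingError(f"QVector is at t={q.t}, expected t_start={t_start}")
    if t_start == t_end:
        return q
    coeffs = _coefficient_builder(model, q.k, q.M)

    def rhs(t, v):
        diag, sub, sup = coeffs(t)
        dv = diag * v
        dv[1:] += sub * v[:-1]
        dv[:-1] += sup * v[1:]
        return dv

    def jac(t, v):
        diag, sub, sup = coeffs(t)
        return sparse.diags_array((sub, diag, sup), offsets=(-1, 0, 1), format="csc")

    sol = solve_ivp(
        rhs,
        (t_start, t_end),
        q.values,
        method="BDF",
        jac=jac,
        rtol=tol,
        atol=tol * 1e-4,
    )
    if not sol.success:
        raise NumericalError(f"Q-vector branch solve failed: {sol.message}")
    values = np.clip(sol.y[:, -1], 0.0, None)
    mx = values.max()
    if mx <= 0.0:
        raise NumericalError("Q-vector vanished during branch propagation")
    log_scale = q.log_scale
    if mx < 1e-2 or mx > 1e2:
        values = values / mx
        log_scale += float(np.log(mx))
        mx = 1.0
    if q.M >= 1 and values[-1] / values.max() > tail_threshold:
        raise TruncationError(
            f"tail ratio Q_M/max = {values[-1] / values.max():.2e} exceeds "
            f"{tail_threshold:.1e}; increase M (was {q.M})"
        )
    return QVector(k=q.k, values=values, t=t_end, log_scale=log_scale)


def apply_node(q: QVector, model: RateModel, t_k: float) -> QVector:
    """Apply the node operator at branching time t_k: Q_m *= k lambda_{k+m},
    and increment the observed-lineage count k."""
    if abs(q.t - t_k) > 1e-9 * max(1.0, abs(t_k)):
        raise OrderingError(f"QVector is at t={q.t}, expected node time {t_k}")
    n_grid = np.arange(q.k, q.k + q.M + 1)
    lam = np.asarray(model.speciation(n_grid, t_k), dtype=float)
    return QVector(k=q.k + 1, values=q.k * lam * q.values, t=t_k, log_scale=q.log_scale)


def q_at_present(
    model: RateModel,
    bt: BranchingTimes,
    M: int,
    *,
    tol: float = DEFAULT_TOL,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> QVector:
    """Propagate delta_{m,0} from the crown through all branches and nodes to
    the present, returning Q^{k_p}(t_p)."""
    q = initial_q_vector(bt.t_c, M)
    t_prev = bt.t_c
    for t_i in bt.internal:
        q = propagate_branch(q, model, t_prev, t_i, tol=tol, tail_threshold=tail_threshold)
        q = apply_node(q, model, t_i)
        t_prev = t_i
    return propagate_branch(q, model, t_prev, bt.t_p, tol=tol, tail_threshold=tail_threshold)


def conditioning_probability(
    model: RateModel,
    t_c: float,
    t_p: float,
    M: int = 200,
    *,
    tol: float = DEFAULT_TOL,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> float:
    """Probability that both crown lineages survive to the present.

    Propagates delta_{m,0} with k = 2 (no node operators) over [t_c, t_p] and
    returns sum_m 6 / ((m + 2)(m + 3)) Q_m.
    """
    q = propagate_branch(
        initial_q_vector(t_c, M), model, t_c, t_p, tol=tol, tail_threshold=tail_threshold
    )
    m = np.arange(M + 1, dtype=float)
    weights = 6.0 / ((m + 2.0) * (m + 3.0))
    p_c = float(np.sum(weights * q.values) * np.exp(q.log_scale))
    return min(p_c, 1.0)


def _assemble_n(model, bt, m_p, M, tol, tail_threshold) -> LikelihoodResult:
    q = q_at_present(model, bt, M, tol=tol, tail_threshold=tail_threshold)
    if q.values[m_p] <= 0.0:
        raise NumericalError(
            f"degenerate likelihood: Q_{m_p} = {q.values[m_p]} after propagation "
            f"(k_p={bt.k_p}, M={M})"
        )
    p_c = conditioning_probability(
        model, bt.t_c, bt.t_p, M, tol=tol, tail_threshold=tail_threshold
    )
    tail_ratio = float(q.values[-1] / q.values.max()) if M >= 1 else 0.0
    return LikelihoodResult(
        log_numerator=float(np.log(q.values[m_p]) + q.log_scale),
        log_combinatorial=log_binomial(bt.k_p + m_p, m_p),
        log_conditioning=float(np.log(p_c)),
        diagnostics={
            "method": "q-framework n-sampling",
            "M": M,
            "tol": tol,
            "tail_ratio": tail_ratio,
            "conditioning_probability": p_c,
        },
    )


def loglik_q_n(
    model: RateModel,
    bt: BranchingTimes,
    m_p: int,
    M: int | None = None,
    *,
    tol: float = DEFAULT_TOL,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> LikelihoodResult:
    """Likelihood under n-sampling: L = Q_{m_p}^{k_p}(t_p) /
    (C(k_p + m_p, m_p) P_c), assembled in log space."""
    if int(m_p) != m_p or m_p < 0:
        raise DomainError(f"m_p must be a nonnegative integer, got {m_p}")
    m_p = int(m_p)
    history = None
    if M is None:
        M, history = choose_truncation(
            bt, SamplingScheme.n_sampling(m_p), model, tol=tol, return_history=True
        )
    if M < m_p:
        raise DomainError(f"truncation M={M} must be >= m_p={m_p}")
    res = _assemble_n(model, bt, m_p, M, tol, tail_threshold)
    if history is not None:
        res.diagnostics["truncation_history"] = history
    return res


def _assemble_rho(model, bt, f_p, M, tol, tail_threshold) -> LikelihoodResult:
    q = q_at_present(model, bt, M, tol=tol, tail_threshold=tail_threshold)
    m = np.arange(M + 1, dtype=float)
    weighted = (1.0 - f_p) ** m * q.values
    total = float(weighted.sum())
    if total <= 0.0:
        raise NumericalError("degenerate likelihood: weighted Q-sum vanished")
    if f_p < 1.0 and weighted[-1] / total > 1e-12:
        raise TruncationError(
            f"rho-sampling series tail {(weighted[-1] / total):.2e} above 1e-12; "
            f"increase M (was {M})"
        )
    p_c = conditioning_probability(
        model, bt.t_c, bt.t_p, M, tol=tol, tail_threshold=tail_threshold
    )
    log_p_s = float(bt.k_p * np.log(f_p) + np.log(total) + q.log_scale)
    return LikelihoodResult(
        log_numerator=log_p_s,
        log_combinatorial=0.0,
        log_conditioning=float(np.log(p_c)),
        diagnostics={
            "method": "q-framework rho-sampling",
            "M": M,
            "tol": tol,
            "f_p": f_p,
            "series_tail": float(weighted[-1] / total),
            "conditioning_probability": p_c,
        },
    )


def loglik_q_rho(
    model: RateModel,
    bt: BranchingTimes,
    f_p: float,
    M: int | None = None,
    *,
    tol: float = DEFAULT_TOL,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
) -> LikelihoodResult:
    """Likelihood under rho-sampling:
    L = sum_m f_p^{k_p} (1 - f_p)^m Q_m^{k_p}(t_p) / P_c."""
    if not 0.0 < f_p <= 1.0:
        raise DomainError(f"f_p must be in (0, 1], got {f_p}")
    history = None
    if M is None:
        M, history = choose_truncation(
            bt, SamplingScheme.rho_sampling(f_p), model, tol=tol, return_history=True
        )
    res = _assemble_rho(model, bt, f_p, M, tol, tail_threshold)
    if history is not None:
        res.diagnostics["truncation_history"] = history
    return res


def choose_truncation(
    bt: BranchingTimes,
    scheme: SamplingScheme,
    model: RateModel,
    *,
    tol: float = DEFAULT_TOL,
    convergence: float = 1e-9,
    max_M: int = 10_000,
    return_history: bool = False,
):
    """Pick a truncation M such that doubling M moves the log-likelihood by
    less than ``convergence``.

    Starts at max(3 k_p, m_p + 20, 30) and doubles until converged; the probe
    history (M, logL) is available via ``return_history``.
    """
    m_p = scheme.m_p if scheme.variant == "n_sampling" else 0
    M = max(3 * bt.k_p, m_p + 20, 30)
    history = []

    def eval_at(M_probe):
        # tail check disabled during probing: the doubling loop is the check
        if scheme.variant == "n_sampling":
            res = _assemble_n(model, bt, scheme.m_p, M_probe, tol, np.inf)
        else:
            res = _assemble_rho(model, bt, scheme.f_p, M_probe, tol, np.inf)
        return res.log_likelihood

    current = eval_at(M)
    history.append((M, current))
    while True:
        nxt = eval_at(2 * M)
        history.append((2 * M, nxt))
        if abs(nxt - current) < convergence:
            break
        M *= 2
        current = nxt
        if M > max_M:
            raise ResourceError(
                f"truncation did not converge by M={max_M}; history={history}"
            )
    if return_history:
        return M, history
    return M
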