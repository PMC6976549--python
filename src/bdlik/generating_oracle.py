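"""Generating-function oracle for the diversity-independent case.

For diversity-independent rates the generating function of the Q-vector has
the closed product form

    F_k(z, t) = H^2(z, t_c, t) * prod_{j=2}^{k-1} j lambda(t_j) H(z, t_j, t),

where H(z, s, t) = (1 - xi)(1 - eta) / (1 - z eta)^2 is the z-derivative of
Kendall's single-lineage generating function.  Expanding these products as
truncated power series in z and reading off coefficients gives Q_m^k(t)
without ever touching the ODE propagation code path, making this module an
independent oracle for the Q-framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kendall
from .containers import BranchingTimes
from .errors import DomainError, OrderingError, UnsupportedModelError
from .rates import RateModel

__all__ = ["TruncatedSeries", "H_series", "F_series", "q_oracle"]


@dataclass(frozen=True)
class TruncatedSeries:
    """A truncated formal power series in z: coefficients c_0..c_D."""

    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or len(c) == 0 or not np.all(np.isfinite(c)):
            raise DomainError("coefficients must be a nonempty finite 1-d vector")
        object.__setattr__(self, "coefficients", c)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __mul__(self, other: "TruncatedSeries") -> "TruncatedSeries":
        d = max(self.degree, other.degree)
        full = np.convolve(self.coefficients, other.coefficients)
        return TruncatedSeries(full[: d + 1])

    def scaled(self, factor: float) -> "TruncatedSeries":
        return TruncatedSeries(self.coefficients * factor)

    def __call__(self, z: float) -> float:
        """Evaluate the truncated series at a scalar z (Horner)."""
        acc = 0.0
        for c in self.coefficients[::-1]:
            acc = acc * z + c
        return float(acc)


def _require_di(model: RateModel) -> None:
    if not model.is_diversity_independent:
        raise UnsupportedModelError(
            "the generating-function oracle requires a diversity-independent model"
        )


def H_series(
    model: RateModel, s: float, t: float, D: int, *, tol: float = 1e-10
) -> TruncatedSeries:
    """Coefficients of H(z, s, t) = (1 - xi)(1 - eta) / (1 - z eta)^2 up to
    degree D: c_m = (1 - xi)(1 - eta)(m + 1) eta^m."""
    _require_di(model)
    if s > t:
        raise OrderingError(f"requires s <= t, got s={s} > t={t}")
    if D < 0:
        raise DomainError(f"degree must be >= 0, got {D}")
    pair = kendall.xi_eta(model, s, t, tol=tol)
    m = np.arange(D + 1)
    c = (1.0 - pair.xi) * (1.0 - pair.eta) * (m + 1.0) * pair.eta**m
    return TruncatedSeries(c)


def F_series(
    model: RateModel,
    bt: BranchingTimes,
    t: float,
    D: int,
    *,
    k: int | None = None,
    tol: float = 1e-10,
) -> TruncatedSeries:
    """Coefficients of F_k(z, t), the generating function of Q_m^k(t).

    ``k`` defaults to the number of branches implied by ``t`` relative to the
    branching times (k_p when t >= last branching time).  Only the branching
    times strictly before ``t`` enter the product.
    """
    _require_di(model)
    if k is None:
        k = 2 + sum(1 for t_j in bt.internal if t_j <= t)
    if not 2 <= k <= bt.k_p:
        raise DomainError(f"k={k} outside 2..{bt.k_p}")
    h_c = H_series(model, bt.t_c, t, D, tol=tol)
    series = h_c * h_c
    for j in range(2, k):
        t_j = bt.t_k(j)
        h_j = H_series(model, t_j, t, D, tol=tol)
        series = (series * h_j).scaled(j * model.speciation_t(t_j))
    return series


def q_oracle(
    model: RateModel, bt: BranchingTimes, m_p: int, *, tol: float = 1e-10
) -> float:
    """Q_{m_p}^{k_p}(t_p) extracted as the degree-m_p coefficient of
    F_{k_p}(z, t_p)."""
    if int(m_p) != m_p or m_p < 0:
        raise DomainError(f"m_p must be a nonnegative integer, got {m_p}")
    series = F_series(model, bt, bt.t_p, int(m_p), k=bt.k_p, tol=tol)
    return float(series.coefficients[int(m_p)])
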