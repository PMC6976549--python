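"""Shared domain containers: branching times, sampling schemes, likelihoods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError

__all__ = ["BranchingTimes", "SamplingScheme", "LikelihoodResult"]


@dataclass(frozen=True)
class BranchingTimes:
    """Branching times of an ultrametric reconstructed tree.

    The process starts from a crown (two ancestor species) at ``t_c`` and runs
    to the present ``t_p``; time increases from past to present.  ``internal``
    holds the ordered times (t_2, ..., t_{k_p - 1}) at which the reconstructed
    tree goes from k to k + 1 branches; it is empty for a two-tip tree.
    Conventions t_0 = t_1 = t_c and t_{k_p} = t_p are exposed as accessors.
    """

    t_c: float
    internal: tuple
    t_p: float

    def __init__(self, t_c: float, internal: Sequence[float], t_p: float):
        internal = tuple(float(t) for t in internal)
        t_c, t_p = float(t_c), float(t_p)
        seq = (t_c,) + internal + (t_p,)
        for a, b in zip(seq, seq[1:]):
            if not a < b:
                raise DomainError(
                    f"branching times must satisfy t_c < t_2 < ... < t_p strictly; "
                    f"violated at {a} >= {b}"
                )
        object.__setattr__(self, "t_c", t_c)
        object.__setattr__(self, "internal", internal)
        object.__setattr__(self, "t_p", t_p)

    @property
    def k_p(self) -> int:
        """Number of tips of the reconstructed tree."""
        return len(self.internal) + 2

    @property
    def crown_to_present(self) -> tuple:
        """(t_0, t_1, t_2, ..., t_{k_p-1}) with t_0 = t_1 = t_c."""
        return (self.t_c, self.t_c) + self.internal

    def t_k(self, k: int) -> float:
        """t_k with the conventions t_0 = t_1 = t_c and t_{k_p} = t_p."""
        if k in (0, 1):
            return self.t_c
        if k == self.k_p:
            return self.t_p
        if 2 <= k <= self.k_p - 1:
            return self.internal[k - 2]
        raise DomainError(f"k={k} outside 0..{self.k_p}")

    def shifted(self, dt: float) -> "BranchingTimes":
        """The same tree translated in time by ``dt``."""
        return BranchingTimes(self.t_c + dt, [t + dt for t in self.internal], self.t_p + dt)


@dataclass(frozen=True)
class SamplingScheme:
    """Incomplete sampling at the present.

    Either a fixed known number ``m_p`` of unsampled extant species
    (n-sampling) or an independent inclusion probability ``f_p`` for each
    extant species (rho-sampling).
    """

    variant: str
    m_p: Optional[int] = None
    f_p: Optional[float] = None

    def __post_init__(self):
        if self.variant == "n_sampling":
            if self.m_p is None or self.f_p is not None:
                raise DomainError("n_sampling requires m_p (and only m_p)")
            if int(self.m_p) != self.m_p or self.m_p < 0:
                raise DomainError(f"m_p must be a nonnegative integer, got {self.m_p}")
        elif self.variant == "rho_sampling":
            if self.f_p is None or self.m_p is not None:
                raise DomainError("rho_sampling requires f_p (and only f_p)")
            if not 0.0 < self.f_p <= 1.0:
                raise DomainError(f"f_p must be in (0, 1], got {self.f_p}")
        else:
            raise DomainError(f"unknown sampling variant: {self.variant!r}")

    @classmethod
    def n_sampling(cls, m_p: int) -> "SamplingScheme":
        return cls(variant="n_sampling", m_p=int(m_p))

    @classmethod
    def rho_sampling(cls, f_p: float) -> "SamplingScheme":
        return cls(variant="rho_sampling", f_p=float(f_p))


@dataclass(frozen=True)
class LikelihoodResult:
    """A log-likelihood with its decomposition and numerical diagnostics.

    The decomposition satisfies
    ``log_likelihood = log_numerator - log_combinatorial - log_conditioning``.
    Formulas in which the conditioning or the combinatorial factor is absorbed
    into the closed form record zero for the corresponding term.
    """

    log_numerator: float
    log_combinatorial: float = 0.0
    log_conditioning: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def log_likelihood(self) -> float:
        return self.log_numerator - self.log_combinatorial - self.log_conditioning

    @property
    def likelihood(self) -> float:
        return float(np.exp(self.log_likelihood))
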