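"""Speciation/extinction rate models.

A :class:`RateModel` maps a diversity ``n`` (number of extant species) and a
time ``t`` to per-species speciation and extinction rates.  Three families are
provided:

* constant rates ``lambda``, ``mu`` (the classic birth-death model),
* purely time-dependent, diversity-independent rates ``lambda(t)``, ``mu(t)``,
* linear diversity dependence ``lambda_n = max(0, lambda0 (1 - n/K))`` with
  constant extinction, the canonical diversity-dependent instance used
  throughout the test suite.

Rates are per lineage per unit time and are clamped at zero inside the model,
so downstream consumers never see negative transition rates.  The two flags
``is_diversity_independent`` and ``is_time_independent`` let downstream code
pick closed forms (constant rates) or quadrature (time-dependent rates)
without probing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "RateModel",
    "make_constant_rates",
    "make_linear_dd_rates",
    "make_time_dependent_rates",
    "rate_model_from_config",
]


def _eval(fn: Callable, n, t: float):
    """Evaluate a raw rate function, broadcasting over ``n`` and validating.

    Returns a float for scalar ``n`` and an ndarray matching ``n`` otherwise.
    """
    n_arr = np.asarray(n)
    out = np.asarray(fn(n_arr, t), dtype=float)
    if out.shape != n_arr.shape:
        out = np.broadcast_to(out, n_arr.shape).copy()
    if not np.all(np.isfinite(out)):
        raise DomainError(f"rate function returned a non-finite value at t={t}")
    if np.any(out < 0):
        raise DomainError(f"rate function returned a negative value at t={t}")
    if n_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RateModel:
    """Per-species speciation and extinction rates lambda_n(t), mu_n(t)."""

    _speciation: Callable = field(repr=False)
    _extinction: Callable = field(repr=False)
    is_diversity_independent: bool
    is_time_independent: bool
    label: str = "custom"

    def speciation(self, n, t: float = 0.0):
        """Per-species speciation rate at diversity ``n`` and time ``t``.

        ``n`` may be a scalar or an integer array (vectorized evaluation).
        """
        return _eval(self._speciation, n, t)

    def extinction(self, n, t: float = 0.0):
        """Per-species extinction rate at diversity ``n`` and time ``t``."""
        return _eval(self._extinction, n, t)

    def speciation_t(self, t: float) -> float:
        """lambda(t) for a diversity-independent model."""
        return self.speciation(1, t)

    def extinction_t(self, t: float) -> float:
        """mu(t) for a diversity-independent model."""
        return self.extinction(1, t)


def make_constant_rates(lam: float, mu: float) -> RateModel:
    """Constant per-species rates: the diversity-independent, time-independent
    birth-death model."""
    if lam < 0:
        raise DomainError(f"speciation rate must be >= 0, got lambda={lam}")
    if mu < 0:
        raise DomainError(f"extinction rate must be >= 0, got mu={mu}")
    lam, mu = float(lam), float(mu)
    return RateModel(
        _speciation=lambda n, t: lam + 0.0 * np.asarray(n, dtype=float),
        _extinction=lambda n, t: mu + 0.0 * np.asarray(n, dtype=float),
        is_diversity_independent=True,
        is_time_independent=True,
        label=f"constant(lambda={lam}, mu={mu})",
    )


def make_linear_dd_rates(lambda0: float, carrying_capacity: float, mu: float) -> RateModel:
    """Linear diversity-dependent speciation with constant extinction.

    ``lambda_n = max(0, lambda0 * (1 - n / K))``; the clamp at zero keeps the
    generator of the process valid for n > K.
    """
    if lambda0 < 0:
        raise DomainError(f"lambda0 must be >= 0, got {lambda0}")
    if carrying_capacity <= 0:
        raise DomainError(f"carrying capacity must be > 0, got {carrying_capacity}")
    if mu < 0:
        raise DomainError(f"extinction rate must be >= 0, got mu={mu}")
    lam0, kk, mu = float(lambda0), float(carrying_capacity), float(mu)
    return RateModel(
        _speciation=lambda n, t: np.maximum(
            0.0, lam0 * (1.0 - np.asarray(n, dtype=float) / kk)
        ),
        _extinction=lambda n, t: mu + 0.0 * np.asarray(n, dtype=float),
        is_diversity_independent=False,
        is_time_independent=True,
        label=f"linear_dd(lambda0={lam0}, K={kk}, mu={mu})",
    )


def make_time_dependent_rates(
    lambda_fn: Callable[[float], float], mu_fn: Callable[[float], float]
) -> RateModel:
    """Diversity-independent model with user-supplied time functions.

    The functions must be nonnegative on the process window; a negative value
    raises :class:`DomainError` at the point of use.
    """
    return RateModel(
        _speciation=lambda n, t: float(lambda_fn(t)) + 0.0 * np.asarray(n, dtype=float),
        _extinction=lambda n, t: float(mu_fn(t)) + 0.0 * np.asarray(n, dtype=float),
        is_diversity_independent=True,
        is_time_independent=False,
        label="time_dependent",
    )


def rate_model_from_config(block: dict) -> RateModel:
    """Build a rate model from a tagged config record.

    Supported tags: ``constant`` (lambda, mu), ``linear_dd`` (lambda0, K, mu),
    ``exponential_time`` (lambda0, lambda_rate, mu0, mu_rate) with
    ``lambda(t) = lambda0 * exp(lambda_rate * t)`` and similarly for mu.
    """
    if not isinstance(block, dict) or "type" not in block:
        raise ConfigError("rate-model config must be a mapping with a 'type' key")
    kind = block["type"]
    try:
        if kind == "constant":
            return make_constant_rates(block["lambda"], block["mu"])
        if kind == "linear_dd":
            return make_linear_dd_rates(block["lambda0"], block["K"], block["mu"])
        if kind == "exponential_time":
            l0 = float(block["lambda0"])
            lr = float(block.get("lambda_rate", 0.0))
            m0 = float(block["mu0"])
            mr = float(block.get("mu_rate", 0.0))
            if l0 < 0 or m0 < 0:
                raise DomainError("exponential_time requires lambda0 >= 0 and mu0 >= 0")
            return make_time_dependent_rates(
                lambda t: l0 * np.exp(lr * t), lambda t: m0 * np.exp(mr * t)
            )
    except KeyError as exc:
        raise ConfigError(f"rate-model config missing parameter {exc}") from exc
    raise ConfigError(f"unknown rate-model type: {kind!r}")
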