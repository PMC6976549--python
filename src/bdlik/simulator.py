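"""Exact stochastic simulation of the diversification process.

Gillespie simulation of the (possibly diversity-dependent, time-dependent)
birth-death process from a crown of two species at t_c to the present t_p,
with total event rates n * lambda_n(t) and n * mu_n(t).  Time-dependent
rates are handled by thinning against a per-interval envelope (the maximum
of the total rate over a bracketing grid, refreshed after every event).

The complete tree is recorded as a flat lineage table; incomplete sampling
at the present (n-sampling or rho-sampling) and pruning to the reconstructed
tree of sampled tips are applied afterwards.  This module is the fixture
generator for all end-to-end checks against the likelihood code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import BranchingTimes, SamplingScheme
from .errors import ConfigError, DomainError
from .rates import RateModel

__all__ = [
    "Lineage",
    "LineageTable",
    "ReconstructionResult",
    "simulate_complete_tree",
    "reconstruct",
    "survival_fraction",
    "write_newick",
    "ltt",
]

_ENVELOPE_GRID = 65
_ENVELOPE_SAFETY = 1.05


@dataclass
class Lineage:
    """One species lineage of the complete tree."""

    id: int
    parent: int  # -1 for the two crown lineages
    birth: float
    death: Optional[float] = None  # None = extant at the present
    sampled: bool = True  # meaningful for extant lineages only
    crown: int = 0  # which crown ancestor (0 or 1) it descends from


@dataclass
class LineageTable:
    """Complete realization of the process on [t_c, t_p]."""

    lineages: list
    t_c: float
    t_p: float

    def extant_ids(self) -> list:
        return [l.id for l in self.lineages if l.death is None]

    def sampled_ids(self) -> list:
        return [l.id for l in self.lineages if l.death is None and l.sampled]

    def children_of(self) -> dict:
        kids: dict = {l.id: [] for l in self.lineages}
        for l in self.lineages:
            if l.parent >= 0:
                kids[l.parent].append(l.id)
        for v in kids.values():
            v.sort(key=lambda i: self.lineages[i].birth)
        return kids

    def to_tsv(self) -> str:
        rows = ["id\tparent\tbirth\tdeath\tsampled"]
        for l in self.lineages:
            death = "" if l.death is None else f"{l.death:.12g}"
            rows.append(f"{l.id}\t{l.parent}\t{l.birth:.12g}\t{death}\t{int(l.sampled)}")
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of sampling + pruning; ``status == 'ok'`` iff a valid
    reconstructed tree (>= 2 sampled tips, both crown lineages represented)
    was obtained."""

    status: str  # ok | too_few_tips | crown_lineage_unrepresented | infeasible_sampling
    branching_times: Optional[BranchingTimes] = None
    m_realized: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _total_rate(model: RateModel, n: int, t: float):
    lam = float(model.speciation(n, t))
    mu = float(model.extinction(n, t))
    return lam, mu, n * (lam + mu)


def simulate_complete_tree(model: RateModel, t_c: float, t_p: float, seed) -> LineageTable:
    """Simulate the complete tree from a crown pair on [t_c, t_p]."""
    if t_p <= t_c:
        raise DomainError(f"requires t_c < t_p, got {t_c} >= {t_p}")
    rng = _as_rng(seed)
    lineages = [
        Lineage(id=0, parent=-1, birth=t_c, crown=0),
        Lineage(id=1, parent=-1, birth=t_c, crown=1),
    ]
    alive = [0, 1]
    t = t_c
    while alive:
        n = len(alive)
        if model.is_time_independent:
            lam, mu, total = _total_rate(model, n, t)
            if total <= 0.0:
                break  # frozen (e.g. pure birth at carrying capacity)
            t = t + rng.exponential(1.0 / total)
            if t >= t_p:
                break
        else:
            # thinning against a grid-max envelope over the remaining window
            grid = np.linspace(t, t_p, _ENVELOPE_GRID)
            cands = [n * (float(model.speciation(n, g)) + float(model.extinction(n, g)))
                     for g in grid]
            bound = _ENVELOPE_SAFETY * max(cands)
            if not np.isfinite(bound):
                raise ConfigError("rate model is unbounded over the process window")
            if bound <= 0.0:
                break
            while True:
                t = t + rng.exponential(1.0 / bound)
                if t >= t_p:
                    break
                lam, mu, total = _total_rate(model, n, t)
                if total > bound * (1.0 + 1e-12):
                    raise ConfigError(
                        "thinning envelope undershoots the total rate; "
                        "the rate varies too sharply for the bracketing grid"
                    )
                if rng.random() < total / bound:
                    break
            if t >= t_p:
                break
        # an event happens at time t to a uniformly chosen lineage
        idx = int(rng.integers(n))
        lid = alive[idx]
        if rng.random() < lam / (lam + mu):
            new = Lineage(
                id=len(lineages),
                parent=lid,
                birth=t,
                crown=lineages[lid].crown,
            )
            lineages.append(new)
            alive.append(new.id)
        else:
            lineages[lid].death = t
            alive[idx] = alive[-1]
            alive.pop()
    return LineageTable(lineages=lineages, t_c=t_c, t_p=t_p)


def _has_sampled_descendant(table: LineageTable) -> dict:
    """hs[id] = lineage is extant-and-sampled or has such a descendant."""
    kids = table.children_of()
    hs: dict = {}
    for l in sorted(table.lineages, key=lambda x: x.birth, reverse=True):
        hs[l.id] = (l.death is None and l.sampled) or any(hs[c] for c in kids[l.id])
    return hs


def reconstruct(table: LineageTable, scheme: SamplingScheme, seed) -> ReconstructionResult:
    """Apply sampling at the present, prune to sampled tips, and return the
    ordered branching times of the reconstructed tree.

    Sets the ``sampled`` flags on the table in place.  n-sampling removes a
    uniformly chosen subset of exactly m_p extant species; rho-sampling thins
    each extant species independently with probability f_p.
    """
    rng = _as_rng(seed)
    extant = table.extant_ids()
    for l in table.lineages:
        l.sampled = l.death is None
    if scheme.variant == "n_sampling":
        if scheme.m_p >= len(extant):
            return ReconstructionResult(status="infeasible_sampling")
        if scheme.m_p > 0:
            drop = rng.choice(extant, size=scheme.m_p, replace=False)
            for i in drop:
                table.lineages[int(i)].sampled = False
        m_realized = scheme.m_p
    else:
        keep = rng.random(len(extant)) < scheme.f_p
        for i, k in zip(extant, keep):
            table.lineages[i].sampled = bool(k)
        m_realized = int(len(extant) - keep.sum())
    sampled = table.sampled_ids()
    if len(sampled) < 2:
        return ReconstructionResult(status="too_few_tips", m_realized=m_realized)
    hs = _has_sampled_descendant(table)
    if not (hs[0] and hs[1]):
        return ReconstructionResult(status="crown_lineage_unrepresented", m_realized=m_realized)
    kids = table.children_of()
    internal = []
    for l in table.lineages:
        if l.parent < 0 or not hs[l.id]:
            continue
        p = table.lineages[l.parent]
        right_has = (p.death is None and p.sampled) or any(
            hs[c] for c in kids[p.id] if table.lineages[c].birth > l.birth
        )
        if right_has:
            internal.append(l.birth)
    internal.sort()
    bt = BranchingTimes(table.t_c, internal, table.t_p)
    assert bt.k_p == len(sampled), "reconstruction inconsistency"
    return ReconstructionResult(status="ok", branching_times=bt, m_realized=m_realized)


def survival_fraction(model: RateModel, t_c: float, t_p: float, replicates: int, seed):
    """Monte-Carlo estimate of the probability that BOTH crown lineages have
    at least one extant descendant at the present (sampling ignored).

    Returns (fraction, standard_error).  Replicate r uses the substream
    ``default_rng([seed, r])`` so each replicate is reproducible in isolation.
    """
    if replicates < 100:
        raise DomainError(f"need >= 100 replicates, got {replicates}")
    hits = 0
    for r in range(replicates):
        rng = np.random.default_rng([int(seed), r])
        table = simulate_complete_tree(model, t_c, t_p, rng)
        crowns = {table.lineages[i].crown for i in table.extant_ids()}
        if crowns == {0, 1}:
            hits += 1
    frac = hits / replicates
    se = float(np.sqrt(max(frac * (1.0 - frac), 1.0 / replicates**2) / replicates))
    return frac, se


def ltt(table: LineageTable, t: float):
    """Lineages-through-time counts (k, m, n) at time t: k lineages ancestral
    to sampled tips, m other alive lineages, n = k + m alive in total."""
    hs = _has_sampled_descendant(table)
    k = m = 0
    for l in table.lineages:
        end = l.death if l.death is not None else table.t_p
        if l.birth <= t < end or (l.death is None and t == table.t_p):
            if hs[l.id]:
                k += 1
            else:
                m += 1
    return k, m, k + m


def write_newick(table: LineageTable, mode: str = "complete") -> str:
    """Serialize the tree as Newick with branch lengths.

    ``complete`` keeps every lineage (extinct tips make the tree
    non-ultrametric); ``reconstructed`` prunes to sampled extant tips and is
    ultrametric by construction.
    """
    if mode not in ("complete", "reconstructed"):
        raise DomainError(f"mode must be 'complete' or 'reconstructed', got {mode!r}")
    kids = table.children_of()
    if mode == "reconstructed":
        hs = _has_sampled_descendant(table)
        roots = [r for r in (0, 1) if hs[r]]
        if not roots:
            raise DomainError("no sampled surviving lineage to serialize")
    else:
        hs = None
        roots = [0, 1]

    def end_time(l: Lineage) -> float:
        return l.death if l.death is not None else table.t_p

    def subtree(lid: int, t_from: float) -> str:
        l = table.lineages[lid]
        events = [c for c in kids[lid]
                  if table.lineages[c].birth > t_from and (hs is None or hs[c])]
        if not events:
            tip_end = table.t_p if hs is not None else end_time(l)
            return f"L{lid}:{tip_end - t_from:.17g}"
        c = events[0]
        tb = table.lineages[c].birth
        if hs is not None:
            # pruning: the node at tb exists only if the parent's continuation
            # beyond tb still leads to a sampled tip; otherwise the
            # reconstructed tree passes straight through the child
            cont_has = (l.death is None and l.sampled) or len(events) > 1
            if not cont_has:
                return subtree(c, t_from)
        return f"({subtree(lid, tb)},{subtree(c, tb)}):{tb - t_from:.17g}"

    parts = [subtree(r, table.t_c) for r in roots]
    return "(" + ",".join(parts) + ");"
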