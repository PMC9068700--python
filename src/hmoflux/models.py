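"""Candidate-model enumeration (MILP) and per-sample flux fitting (FBA).

A *candidate model* is a subset-minimal set of network reactions
(biosynthetic + isomer-pooling) that can carry at least ``epsilon`` flux
into every observed-HMO sink simultaneously at steady state.  Enumeration
solves a cardinality-minimising MILP and excludes each found model with an
integer cut, so successive solutions sweep the subset-minimal models in
non-decreasing size order; every incumbent is post-processed by greedy
pruning to guarantee subset-minimality.

Flux fitting pins each sink flux to the sample's measured relative
abundance (the lactose input then equals the profile total by mass
balance) and resolves the remaining degeneracy parsimoniously by
minimising total flux.  Normalised flux expresses each reaction as the
fraction of the total flux entering its substrate species, limiting the
influence of upstream reactions when correlating with gene expression.

All programs are solved with HiGHS through :mod:`scipy.optimize`
(deterministic, single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .network import BIOSYNTHESIS, INPUT, POOLING, SINK, Reaction, ReactionNetwork

__all__ = [
    "EnumConfig",
    "CandidateModel",
    "FluxSolution",
    "InfeasibleSampleError",
    "minimal_cardinality",
    "enumerate_models",
    "fit_fluxes",
    "normalize_flux",
    "validate_profile",
]


class InfeasibleSampleError(RuntimeError):
    """A sample's abundance profile is not reachable under a candidate model."""


@dataclass
class EnumConfig:
    epsilon: float = 1e-3  # minimum sink flux per observed HMO
    # Flux upper bound in the coupling v <= M*y.  Kept close to the natural
    # flux scale (input flux is bounded by 1 during enumeration, so every
    # reaction flux is <= 1): with a loose M, M * (solver integrality
    # tolerance) can reach epsilon and sinks would be fed through rounded-off
    # binaries.
    big_m: float = 10.0
    cap: Optional[int] = 10_000  # max models to enumerate (None = exhaustive)
    cardinality_slack: Optional[int] = None  # admit up to min_cardinality + slack
    unique_isomer: bool = True  # at most one pooling reaction per ambiguous HMO
    seed: int = 0  # kept for interface stability; HiGHS is deterministic

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.big_m <= self.epsilon:
            raise ValueError("big_m must exceed epsilon")


def _is_pooling(rid: str) -> bool:
    return "|pool|" in rid


@dataclass(frozen=True)
class CandidateModel:
    """Binary reaction-inclusion set over a Reduced Network's model reactions.

    ``reaction_ids`` holds every included reaction (biosynthetic + isomer
    pooling); ``n_reactions`` counts the biosynthetic ones, the quantity the
    cardinality-minimising MILP optimises (pooling lines only select which
    isomer feeds a sink).
    """

    reaction_ids: frozenset

    @property
    def n_reactions(self) -> int:
        return sum(1 for rid in self.reaction_ids if not _is_pooling(rid))

    @property
    def pooling_ids(self) -> frozenset:
        return frozenset(r for r in self.reaction_ids if _is_pooling(r))

    def includes(self, rid: str) -> bool:
        return rid in self.reaction_ids

    def include_vector(self, net: ReactionNetwork) -> np.ndarray:
        return np.array(
            [r.id in self.reaction_ids for r in net.model_reactions], dtype=bool
        )


@dataclass
class FluxSolution:
    fluxes: pd.Series  # reaction id -> flux
    normalized: pd.Series  # reaction id -> flux / substrate inflow (model rxns)


# ---------------------------------------------------------------------------
# MILP core
# ---------------------------------------------------------------------------


class _Milp:
    """Reusable MILP scaffold over a reduced network with sinks attached."""

    def __init__(self, net: ReactionNetwork, cfg: EnumConfig):
        if not net.observed:
            raise ValueError("network has no observed HMOs attached")
        self.net = net
        self.cfg = cfg
        S, self.species, self.rids = net.stoichiometry()
        self.n = len(self.rids)
        self.model_idx = [
            j for j, r in enumerate(net.reactions) if r.kind in (BIOSYNTHESIS, POOLING)
        ]
        self.m = len(self.model_idx)
        nv = self.n + self.m
        # steady state on every species row
        A_eq = sparse.hstack([S, sparse.csc_matrix((S.shape[0], self.m))])
        self.eq = LinearConstraint(A_eq, 0.0, 0.0)
        # coupling v_j - M y_k <= 0
        rows, cols, vals = [], [], []
        for k, j in enumerate(self.model_idx):
            rows += [k, k]
            cols += [j, self.n + k]
            vals += [1.0, -cfg.big_m]
        self.couple = LinearConstraint(
            sparse.csc_matrix((vals, (rows, cols)), shape=(self.m, nv)), -np.inf, 0.0
        )
        self.extra: list[LinearConstraint] = []
        if cfg.unique_isomer:
            ambiguous = {k: v for k, v in net.observed.items() if len(v) > 1}
            for name in ambiguous:
                ks = [
                    k
                    for k, j in enumerate(self.model_idx)
                    if net.reactions[j].kind == POOLING
                    and net.reactions[j].site == name
                ]
                a = sparse.csc_matrix(
                    (np.ones(len(ks)), (np.zeros(len(ks), dtype=int),
                                        [self.n + k for k in ks])),
                    shape=(1, nv),
                )
                self.extra.append(LinearConstraint(a, -np.inf, 1.0))
        lb = np.zeros(nv)
        ub = np.full(nv, cfg.big_m)
        for j, r in enumerate(net.reactions):
            if r.kind == SINK:
                lb[j] = cfg.epsilon
            elif r.kind == INPUT:
                ub[j] = 1.0  # bounded lactose input sets the flux scale
        ub[self.n :] = 1.0
        self.bounds = Bounds(lb, ub)
        self.integrality = np.concatenate(
            [np.zeros(self.n), np.ones(self.m)]
        )
        # objective counts biosynthetic reactions only: pooling binaries are
        # free (they only pick the isomer feeding a sink)
        y_cost = np.array(
            [
                0.0 if net.reactions[j].kind == POOLING else 1.0
                for j in self.model_idx
            ]
        )
        self.c = np.concatenate([np.zeros(self.n), y_cost])
        self._biosynth_cols = np.array(
            [self.n + k for k, j in enumerate(self.model_idx)
             if net.reactions[j].kind == BIOSYNTHESIS]
        )

    def solve(self, cuts: Sequence[frozenset] = (), max_cardinality=None):
        nv = self.n + self.m
        cons = [self.eq, self.couple, *self.extra]
        pos = {self.net.reactions[j].id: self.n + k
               for k, j in enumerate(self.model_idx)}
        for cut in cuts:
            cols = [pos[rid] for rid in cut]
            a = sparse.csc_matrix(
                (np.ones(len(cols)), (np.zeros(len(cols), dtype=int), cols)),
                shape=(1, nv),
            )
            cons.append(LinearConstraint(a, -np.inf, len(cols) - 1.0))
        if max_cardinality is not None:
            cols = self._biosynth_cols
            a = sparse.csc_matrix(
                (np.ones(len(cols)), (np.zeros(len(cols), dtype=int), cols)),
                shape=(1, nv),
            )
            cons.append(LinearConstraint(a, -np.inf, float(max_cardinality)))
        res = milp(
            c=self.c,
            constraints=cons,
            integrality=self.integrality,
            bounds=self.bounds,
        )
        if res.status != 0 or res.x is None:
            return None
        included = frozenset(
            self.net.reactions[j].id
            for k, j in enumerate(self.model_idx)
            if res.x[self.n + k] > 0.5
        )
        return included

    def feasible(self, included: frozenset) -> bool:
        """LP feasibility of producing all sinks with only ``included`` model rxns."""
        S, _, _ = self.net.stoichiometry()
        lb = np.zeros(self.n)
        ub = np.full(self.n, self.cfg.big_m)
        for j, r in enumerate(self.net.reactions):
            if r.kind == SINK:
                lb[j] = self.cfg.epsilon
            elif r.kind in (BIOSYNTHESIS, POOLING) and r.id not in included:
                ub[j] = 0.0
        res = linprog(
            np.zeros(self.n),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        return res.status == 0


def minimal_cardinality(net: ReactionNetwork, cfg: Optional[EnumConfig] = None) -> int:
    """Smallest number of biosynthetic reactions producing every observed HMO.

    Solves one MILP minimising the count of included biosynthetic reactions
    subject to steady state and ``sink >= epsilon`` for every observed HMO
    (isomer-pooling lines are selected freely).
    """
    cfg = cfg or EnumConfig()
    prob = _Milp(net, cfg)
    sol = prob.solve()
    if sol is None:
        raise RuntimeError("infeasible: no subnetwork produces all observed HMOs")
    if not prob.feasible(sol):  # guards against big-M / tolerance leakage
        raise RuntimeError("solver returned a numerically inconsistent optimum")
    pruned = _greedy_prune(prob, sol)
    return CandidateModel(pruned).n_reactions


def _greedy_prune(prob: _Milp, included: frozenset) -> frozenset:
    """Drop any reaction whose removal preserves feasibility (deterministic)."""
    current = set(included)
    for rid in sorted(included):
        if rid in current:
            trial = frozenset(current - {rid})
            if prob.feasible(trial):
                current.discard(rid)
    return frozenset(current)


def enumerate_models(
    net: ReactionNetwork, cfg: Optional[EnumConfig] = None
) -> list[CandidateModel]:
    """Enumerate subset-minimal candidate models via integer-cut MILP.

    Each MILP incumbent is pruned to subset-minimality and excluded by a cut
    ``sum(y_r for r in model) <= |model| - 1``; a cut on a minimal model can
    never exclude a different subset-minimal model (a feasible proper
    superset is by definition not minimal), so iterating to infeasibility
    enumerates the complete set.  Stops early at ``cfg.cap`` models, or at
    ``min_cardinality + cardinality_slack`` when a slack is configured.
    """
    cfg = cfg or EnumConfig()
    if cfg.cap is not None and cfg.cap <= 0:
        raise ValueError("cap must be positive (or None for exhaustive)")
    prob = _Milp(net, cfg)
    max_card = None
    if cfg.cardinality_slack is not None:
        first = prob.solve()
        if first is None:
            raise RuntimeError("infeasible: no subnetwork produces all observed HMOs")
        max_card = len(first) + cfg.cardinality_slack
    models: list[CandidateModel] = []
    cuts: list[frozenset] = []
    while cfg.cap is None or len(models) < cfg.cap:
        sol = prob.solve(cuts, max_cardinality=max_card)
        if sol is None:
            if not models and not cuts:
                raise RuntimeError(
                    "infeasible: no subnetwork produces all observed HMOs"
                )
            break
        pruned = _greedy_prune(prob, sol)
        if any(pruned == m.reaction_ids for m in models):  # pragma: no cover
            cuts.append(pruned)
            continue
        models.append(CandidateModel(pruned))
        cuts.append(pruned)
    return models


# ---------------------------------------------------------------------------
# flux fitting
# ---------------------------------------------------------------------------


def validate_profile(profile: pd.DataFrame, atol: float = 1e-6) -> None:
    """Check a samples x HMO relative-abundance matrix (rows sum to 1, >= 0)."""
    if (profile.values < -atol).any():
        bad = profile.index[(profile.values < -atol).any(axis=1)][0]
        raise ValueError(f"negative abundance in sample {bad!r}")
    sums = profile.sum(axis=1)
    off = sums[(sums - 1.0).abs() > atol]
    if len(off):
        raise ValueError(
            f"profile rows must sum to 1: sample {off.index[0]!r} sums to "
            f"{off.iloc[0]:.6f}"
        )


def fit_fluxes(
    net: ReactionNetwork,
    model: CandidateModel,
    abundances: Mapping[str, float],
    cfg: Optional[EnumConfig] = None,
) -> FluxSolution:
    """FBA for one sample: pin sink fluxes to measured relative abundances.

    Zero abundances fix the corresponding sink to zero (the sink is kept, so
    flux vectors stay comparable across samples, e.g. non-secretors).  The
    remaining degeneracy is resolved by minimising total flux (parsimonious
    FBA).  Raises :class:`InfeasibleSampleError` when the profile cannot be
    reached under the model.
    """
    cfg = cfg or EnumConfig()
    S, spp, rids = net.stoichiometry()
    n = len(rids)
    lb = np.zeros(n)
    ub = np.full(n, cfg.big_m)
    for j, r in enumerate(net.reactions):
        if r.kind == SINK:
            a = float(abundances[r.site])
            if a < 0:
                raise ValueError(f"negative abundance for {r.site!r}")
            lb[j] = ub[j] = a
        elif r.kind in (BIOSYNTHESIS, POOLING) and r.id not in model.reaction_ids:
            ub[j] = 0.0
    res = linprog(
        np.ones(n),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleSampleError(
            "sample profile infeasible under this candidate model"
        )
    fluxes = pd.Series(res.x, index=rids)
    return FluxSolution(fluxes=fluxes, normalized=normalize_flux(fluxes, net))


def normalize_flux(
    fluxes: pd.Series, net: ReactionNetwork, tol: float = 1e-12
) -> pd.Series:
    """Flux of each model reaction as a fraction of its substrate's total inflow.

    For lactose-consuming reactions the denominator is the lactose input;
    0/0 is defined as 0.  Values are clipped to [0, 1] against solver noise.
    """
    inflow: dict[str, float] = {}
    for r in net.reactions:
        if r.product is not None:
            inflow[r.product] = inflow.get(r.product, 0.0) + float(fluxes[r.id])
    out = {}
    for r in net.model_reactions:
        denom = inflow.get(r.substrate, 0.0)
        v = float(fluxes[r.id])
        out[r.id] = 0.0 if denom <= tol else min(max(v / denom, 0.0), 1.0)
    return pd.Series(out)
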