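"""Synthetic stoichiometric networks and brute-force oracles for tests.

The oracles are deliberately independent of the package's LP/MILP route:
feasibility of a reaction subset is decided by graph reachability (exact on
these acyclic one-substrate/one-product networks) and minimal models by
exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

from hmoflux.network import (
    BIOSYNTHESIS,
    INPUT,
    POOLING,
    SINK,
    Reaction,
    ReactionNetwork,
    attach_observations,
)

ROOT = "ROOT"


def make_net(edges, observed):
    """Synthetic network from (substrate, product) edges + observed mapping.

    ``observed`` maps HMO-like names to lists of member species.  Species are
    abstract labels; the root is ``ROOT``.
    """
    species = {ROOT: None}
    reactions = []
    for sub, prod in edges:
        species.setdefault(sub, None)
        species.setdefault(prod, None)
        reactions.append(
            Reaction(f"{sub}>{prod}", sub, prod, "Lx", "", BIOSYNTHESIS)
        )
    net = ReactionNetwork(species, reactions, ROOT)
    return attach_observations(net, observed)


def random_dag_net(rng: np.random.Generator, max_model_reactions: int = 12):
    """Random small DAG network; every species is reachable from the root."""
    while True:
        n_species = int(rng.integers(3, 8))
        names = [ROOT] + [f"S{i}" for i in range(n_species)]
        edges = []
        for i, s in enumerate(names[1:], start=1):
            parents = rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False)
            for p in parents:
                edges.append((names[p], s))
        k_obs = int(rng.integers(1, 3))
        candidates = names[1:]
        observed = {}
        pool = list(rng.permutation(candidates))
        for j in range(k_obs):
            n_members = int(rng.integers(1, 3))
            members, pool = pool[:n_members], pool[n_members:]
            if not members:
                break
            observed[f"H{j}"] = members
        if not observed:
            continue
        n_pool = sum(len(v) for v in observed.values())
        if len(edges) + n_pool <= max_model_reactions:
            return make_net(edges, observed)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_feasible(net: ReactionNetwork, included: frozenset) -> bool:
    """Every observed sink producible using only the included model reactions.

    Exact for these networks: flux superposition means each sink is
    independently satisfiable iff some member with an included pooling line
    is reachable from the root through included biosynthetic edges.
    """
    edges = {}
    for r in net.reactions_of_kind(BIOSYNTHESIS):
        if r.id in included:
            edges.setdefault(r.substrate, []).append(r.product)
    reach = {net.root_code}
    stack = [net.root_code]
    while stack:
        node = stack.pop()
        for nxt in edges.get(node, ()):
            if nxt not in reach:
                reach.add(nxt)
                stack.append(nxt)
    for name, members in net.observed.items():
        ok = any(
            f"{m}|pool|{name}" in included and m in reach for m in members
        )
        if not ok:
            return False
    return True


def oracle_minimal_models(net: ReactionNetwork) -> set[frozenset]:
    """All feasible subset-minimal reaction sets by exhaustive enumeration."""
    rids = sorted(r.id for r in net.model_reactions)
    feas = {}
    for k in range(len(rids) + 1):
        for combo in itertools.combinations(rids, k):
            feas[frozenset(combo)] = oracle_feasible(net, frozenset(combo))
    minimal = set()
    for s, ok in feas.items():
        if ok and all(not feas[s - {r}] for r in s):
            minimal.add(s)
    return minimal


def oracle_min_cardinality(net: ReactionNetwork) -> int:
    """Minimum biosynthetic-reaction count over feasible subsets."""
    return min(
        sum(1 for r in s if "|pool|" not in r) for s in oracle_minimal_models(net)
    )
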