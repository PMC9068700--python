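"""Reaction-network assembly: complete network, observed sinks, FVA reduction.

The *Complete Network* is the closure of the ten linkage rules applied
iteratively to a root lactose, up to a residue-count cap (default 9).
Measured HMOs are attached as pooled *sinks*: every candidate isomer of an
observed HMO feeds one shared sink pseudo-species through a pooling
reaction, so ambiguity in structure assignment is carried into the model
rather than resolved up front.  The *Reduced Network* removes every
reaction that cannot carry flux to any observed sink, established by flux
variability analysis (per-reaction flux maximisation at steady state).

Because each biosynthetic reaction converts exactly one substrate into one
product and the network is acyclic (products are strictly larger), a
reaction can carry positive flux iff its product has a directed route to an
observed structure; the implementation prunes by graph reachability first
and then certifies every survivor with an explicit LP, which also guards
against malformed networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .glycans import Glycan, parse_glycan
from .rules import LinkageRule, apply_rule, lactose

__all__ = [
    "BuilderConfig",
    "Reaction",
    "ReactionNetwork",
    "build_complete_network",
    "attach_observations",
    "reduce_network",
]

#: reaction kinds: biosynthesis = rule application; pooling = isomer -> sink;
#: input = lactose uptake; sink = sink-species drain.
BIOSYNTHESIS, POOLING, INPUT, SINK = "biosynthesis", "pooling", "input", "sink"


@dataclass(frozen=True)
class Reaction:
    id: str
    substrate: Optional[str]  # species id; None for the input exchange
    product: Optional[str]  # species id; None for sink drains
    rule_id: Optional[str]
    site: str
    kind: str


@dataclass
class BuilderConfig:
    max_size: int = 9
    rules: Sequence[LinkageRule] = ()
    root: Optional[Glycan] = None

    def __post_init__(self):
        if self.max_size < 2:
            raise ValueError("max_size must be >= 2")
        if self.root is None:
            self.root = lactose()


def _sink_id(name: str) -> str:
    return f"sink::{name}"


class ReactionNetwork:
    """Species (glycans + sink pseudo-species), reactions, stoichiometry."""

    def __init__(
        self,
        species: Mapping[str, Glycan],
        reactions: Sequence[Reaction],
        root_code: str,
        observed: Optional[Mapping[str, Sequence[str]]] = None,
        rules: Sequence[LinkageRule] = (),
    ):
        self.species = dict(species)
        self.reactions = list(reactions)
        self.root_code = root_code
        self.observed = {k: list(v) for k, v in (observed or {}).items()}
        self.rules = list(rules)
        self._stoich = None

    # -- basic views -------------------------------------------------------
    @property
    def sink_species(self) -> list[str]:
        return [_sink_id(n) for n in self.observed]

    @property
    def species_ids(self) -> list[str]:
        return list(self.species) + self.sink_species

    def reactions_of_kind(self, *kinds: str) -> list[Reaction]:
        return [r for r in self.reactions if r.kind in kinds]

    @property
    def model_reactions(self) -> list[Reaction]:
        """Reactions eligible for model inclusion (biosynthetic + pooling)."""
        return self.reactions_of_kind(BIOSYNTHESIS, POOLING)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def producers(self, species_id: str) -> list[Reaction]:
        return [r for r in self.reactions if r.product == species_id]

    def consumers(self, species_id: str) -> list[Reaction]:
        return [r for r in self.reactions if r.substrate == species_id]

    # -- stoichiometry -----------------------------------------------------
    def stoichiometry(self):
        """(S, species_ids, reaction_ids); every species row balances to 0."""
        if self._stoich is None:
            spp = self.species_ids
            sidx = {s: i for i, s in enumerate(spp)}
            rows, cols, vals = [], [], []
            for j, r in enumerate(self.reactions):
                if r.substrate is not None:
                    rows.append(sidx[r.substrate]); cols.append(j); vals.append(-1.0)
                if r.product is not None:
                    rows.append(sidx[r.product]); cols.append(j); vals.append(1.0)
            S = sparse.csc_matrix(
                (vals, (rows, cols)), shape=(len(spp), len(self.reactions))
            )
            self._stoich = (S, spp, [r.id for r in self.reactions])
        return self._stoich

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root_code,
                "species": sorted(self.species),
                "observed": self.observed,
                "reactions": [
                    {
                        "id": r.id,
                        "substrate": r.substrate,
                        "product": r.product,
                        "rule": r.rule_id,
                        "site": r.site,
                        "kind": r.kind,
                    }
                    for r in self.reactions
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, rules: Sequence[LinkageRule] = ()) -> "ReactionNetwork":
        doc = json.loads(text)
        species = {c: parse_glycan(c) for c in doc["species"]}
        reactions = [
            Reaction(d["id"], d["substrate"], d["product"], d["rule"], d["site"], d["kind"])
            for d in doc["reactions"]
        ]
        return cls(species, reactions, doc["root"], doc.get("observed"), rules)

    def to_sif(self) -> str:
        """Substrate -> product edge list (biosynthetic + pooling reactions)."""
        lines = []
        for r in self.model_reactions:
            lines.append(f"{r.substrate}\t{r.rule_id or 'pool'}\t{r.product}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        nb = len(self.reactions_of_kind(BIOSYNTHESIS))
        return (
            f"ReactionNetwork({len(self.species)} glycans, {nb} biosynthetic "
            f"reactions, {len(self.observed)} observed HMOs)"
        )


def _reaction_id(substrate_code: str, rule_id: str, site: tuple[int, ...]) -> str:
    return f"{substrate_code}|{rule_id}|{'/'.join(map(str, site))}"


def build_complete_network(cfg: BuilderConfig) -> ReactionNetwork:
    """Breadth-first closure of the rules from the root, capped by residue count.

    Deterministic: species are processed in (size, canonical code) order and
    rules in their listed order, so two runs emit identical reaction lists.
    """
    root = cfg.root
    species: dict[str, Glycan] = {root.code: root}
    reactions: list[Reaction] = []
    frontier = [root]
    while frontier:
        frontier.sort(key=lambda g: g.code)
        next_frontier: list[Glycan] = []
        for g in frontier:
            if g.size >= cfg.max_size:
                continue
            for rule in cfg.rules:
                for product, site in apply_rule(rule, g):
                    rid = _reaction_id(g.code, rule.id, site)
                    reactions.append(
                        Reaction(rid, g.code, product.code, rule.id,
                                 "/".join(map(str, site)), BIOSYNTHESIS)
                    )
                    if product.code not in species:
                        species[product.code] = product
                        next_frontier.append(product)
        frontier = next_frontier
    species = {c: species[c] for c in sorted(species, key=lambda c: (species[c].size, c))}
    reactions.sort(key=lambda r: (species[r.substrate].size, r.substrate,
                                  r.rule_id, r.site))
    return ReactionNetwork(species, reactions, root.code, rules=cfg.rules)


def attach_observations(
    net: ReactionNetwork, observed: Mapping[str, Sequence]
) -> ReactionNetwork:
    """Attach one pooled sink per observed HMO plus the lactose input exchange.

    ``observed`` maps HMO name -> list of member structures (Glycan or code).
    Every member must already be a species of the network; a missing member
    signals a too-small ``max_size`` or a wrong structure fixture.
    """
    obs: dict[str, list[str]] = {}
    for name, members in observed.items():
        codes = []
        for m in members:
            code = m.code if isinstance(m, Glycan) else str(m)
            if code not in net.species:
                raise KeyError(
                    f"observed structure {code!r} for {name!r} is not in the network"
                )
            codes.append(code)
        if not codes:
            raise ValueError(f"observed HMO {name!r} has no member structures")
        obs[name] = sorted(set(codes))
    reactions = [r for r in net.reactions if r.kind == BIOSYNTHESIS]
    reactions.append(Reaction("EX_lactose", None, net.root_code, None, "", INPUT))
    for name in obs:
        for code in obs[name]:
            reactions.append(
                Reaction(f"{code}|pool|{name}", code, _sink_id(name), None, name, POOLING)
            )
        reactions.append(Reaction(f"EX_{name}", _sink_id(name), None, None, name, SINK))
    return ReactionNetwork(net.species, reactions, net.root_code, obs, net.rules)


def _max_fluxes(net: ReactionNetwork, targets: Iterable[int]) -> np.ndarray:
    """FVA: max feasible flux per target reaction (lactose input fixed to 1)."""
    S, spp, rids = net.stoichiometry()
    n = len(rids)
    bounds = []
    for r in net.reactions:
        bounds.append((0.0, 1.0) if r.kind == INPUT else (0.0, None))
    out = np.zeros(n)
    for j in targets:
        c = np.zeros(n)
        c[j] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 2:
            raise RuntimeError("infeasible base problem: malformed network")
        out[j] = -res.fun
    return out


def _reachability_keep(net: ReactionNetwork) -> set[str]:
    """Ids of biosynthetic reactions whose product can reach an observed structure."""
    targets = {c for members in net.observed.values() for c in members}
    # reverse edges product -> substrate over biosynthetic reactions
    by_product: dict[str, list[Reaction]] = {}
    for r in net.reactions_of_kind(BIOSYNTHESIS):
        by_product.setdefault(r.product, []).append(r)
    can_reach = set(targets)
    stack = list(targets)
    # backward BFS: a species reaches a target if some consumer's product does
    while stack:
        node = stack.pop()
        for r in by_product.get(node, []):
            if r.substrate not in can_reach:
                can_reach.add(r.substrate)
                stack.append(r.substrate)
    return {
        r.id for r in net.reactions_of_kind(BIOSYNTHESIS) if r.product in can_reach
    }


def reduce_network(net: ReactionNetwork, tol: float = 1e-9) -> ReactionNetwork:
    """Remove reactions that cannot carry flux to any observed HMO (FVA).

    Sinks must be attached.  Graph reachability performs the bulk pruning
    (provably equivalent on this acyclic unimolecular network); every
    surviving biosynthetic reaction is then certified by an LP maximising its
    flux, and dropped if the maximum is below ``tol``.  Iterates to fixpoint.
    """
    if not net.observed:
        # nothing observable: only the input exchange would remain meaningful;
        # drop all biosynthetic reactions.
        return ReactionNetwork(
            {net.root_code: net.species[net.root_code]},
            [r for r in net.reactions if r.kind == INPUT] or
            [Reaction("EX_lactose", None, net.root_code, None, "", INPUT)],
            net.root_code,
            {},
            net.rules,
        )
    current = net
    while True:
        keep = _reachability_keep(current)
        trimmed = _subnetwork(current, keep)
        S, spp, rids = trimmed.stoichiometry()
        idx = [j for j, r in enumerate(trimmed.reactions) if r.kind == BIOSYNTHESIS]
        vmax = _max_fluxes(trimmed, idx)
        dead = {trimmed.reactions[j].id for j in idx if vmax[j] < tol}
        if not dead:
            return trimmed
        keep = {r.id for r in trimmed.reactions_of_kind(BIOSYNTHESIS)} - dead
        current = _subnetwork(trimmed, keep)


def _subnetwork(net: ReactionNetwork, keep_biosynthetic: set[str]) -> ReactionNetwork:
    """Network restricted to the given biosynthetic reactions (+ exchanges)."""
    reactions = [r for r in net.reactions_of_kind(BIOSYNTHESIS) if r.id in keep_biosynthetic]
    used = {net.root_code}
    for r in reactions:
        used.add(r.substrate)
        used.add(r.product)
    for members in net.observed.values():
        used.update(members)
    species = {c: g for c, g in net.species.items() if c in used}
    out = ReactionNetwork(species, reactions, net.root_code, rules=net.rules)
    return attach_observations(out, net.observed) if net.observed else out
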