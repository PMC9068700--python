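"""Rule application, complete-network generation and FVA reduction."""

import numpy as np
import pytest

from hmoflux.glycans import match_sites, parse_glycan, parse_pattern
from hmoflux.network import (
    BIOSYNTHESIS,
    POOLING,
    BuilderConfig,
    attach_observations,
    build_complete_network,
    reduce_network,
)
from hmoflux.rules import apply_rule, lactose, load_rules

RULES = {r.id: r for r in load_rules()}


class TestApplyRule:
    @pytest.mark.parametrize(
        "rule_id, substrate, expected",
        [
            ("L1", "Ab4G", {"GNb3Ab4G"}),
            ("L2", "Ab4G", {"Fa2Ab4G"}),  # 2'FL
            ("L3", "Ab4G", {"Ab4(Fa3)G"}),  # 3FL
            ("L4", "Ab4G", {"NNa3Ab4G"}),  # 3'SL
            ("L5", "Ab4G", {"NNa6Ab4G"}),
            ("L6", "GNb3Ab4G", {"Ab3GNb3Ab4G"}),  # LNT
            ("L7", "GNb3Ab4G", {"Ab4GNb3Ab4G"}),  # LNnT
            ("L8", "GNb3Ab4G", {"GNb3(GNb6)Ab4G"}),
            ("L9", "Ab3GNb3Ab4G", {"Ab3(Fa4)GNb3Ab4G"}),  # LNFP II
            ("L10", "Ab3GNb3Ab4G", {"Ab3(NNa6)GNb3Ab4G"}),  # LSTb
        ],
    )
    def test_printed_acceptor_product_pairs(self, rule_id, substrate, expected):
        got = {g.code for g, _ in apply_rule(RULES[rule_id], parse_glycan(substrate))}
        assert got == expected

    def test_product_embeds_printed_product_pattern(self):
        # the printed product string must match inside every rule product
        for rule in RULES.values():
            for substrate in ("Ab4G", "GNb3Ab4G", "Ab3GNb3Ab4G", "Ab4GNb3Ab4G"):
                for product, _ in apply_rule(rule, parse_glycan(substrate)):
                    pat = parse_pattern(rule.product_code)
                    assert match_sites(product, pat), (rule.id, product.code)

    def test_no_acceptor_site_yields_empty(self):
        assert apply_rule(RULES["L9"], parse_glycan("Ab4GNb3Ab4G")) == []

    def test_a3_fucosylation_blocked_on_type1_glcnac(self):
        # LNT's GlcNAc carries a b3-Gal: a3FucT must skip it, a4FucT acts
        lnt = parse_glycan("Ab3GNb3Ab4G")
        products = {g.code for g, _ in apply_rule(RULES["L3"], lnt)}
        assert products == {"Ab3GNb3Ab4(Fa3)G"}  # only the reducing-end Glc

    def test_a2_fucose_caps_the_galactose(self):
        # once decorated, a galactose is no longer terminal: no elongation
        fl2 = parse_glycan("Fa2Ab4G")
        assert apply_rule(RULES["L1"], fl2) == []


class TestCompleteNetwork:
    def test_lactose_cannot_grow_at_cap_two(self, rules):
        net = build_complete_network(BuilderConfig(max_size=2, rules=rules))
        assert len(net.reactions) == 0 and list(net.species) == ["Ab4G"]

    def test_size3_closure_matches_manual_rule_application(self, rules):
        # brute-force oracle: each of the ten rules applied to lactose by hand
        net = build_complete_network(BuilderConfig(max_size=3, rules=rules))
        expected = {
            ("Ab4G", "GNb3Ab4G", "L1"),
            ("Ab4G", "Fa2Ab4G", "L2"),
            ("Ab4G", "Ab4(Fa3)G", "L3"),
            ("Ab4G", "NNa3Ab4G", "L4"),
            ("Ab4G", "NNa6Ab4G", "L5"),
        }
        got = {(r.substrate, r.product, r.rule_id) for r in net.reactions}
        assert got == expected
        assert len(net.species) == 6  # lactose + 5 products

    def test_species_count_monotone_in_max_size(self, rules):
        counts = [
            len(build_complete_network(BuilderConfig(max_size=s, rules=rules)).species)
            for s in (2, 3, 4, 5)
        ]
        assert counts == sorted(counts) and counts[-1] > counts[0]

    def test_generation_is_deterministic(self, rules):
        a = build_complete_network(BuilderConfig(max_size=5, rules=rules))
        b = build_complete_network(BuilderConfig(max_size=5, rules=rules))
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        assert list(a.species) == list(b.species)


class TestAttachObservations:
    def test_pooled_sink_per_observed_hmo(self, rules, structures):
        net = build_complete_network(BuilderConfig(max_size=6, rules=rules))
        obs = {"DFLNT": structures["DFLNT"], "2'FL": structures["2'FL"]}
        attached = attach_observations(net, obs)
        pools = attached.reactions_of_kind(POOLING)
        assert sum(1 for r in pools if r.site == "DFLNT") == 6
        assert sum(1 for r in pools if r.site == "2'FL") == 1
        assert len(attached.sink_species) == 2

    def test_unknown_structure_raises(self, rules):
        net = build_complete_network(BuilderConfig(max_size=3, rules=rules))
        with pytest.raises(KeyError, match="not in the network"):
            attach_observations(net, {"LNT": ["Ab3GNb3Ab4G"]})


class TestReduction:
    def test_toy_reduction_keeps_only_observed_paths(self, size3_net):
        red = reduce_network(size3_net)
        kept = {(r.substrate, r.product) for r in red.reactions_of_kind(BIOSYNTHESIS)}
        assert kept == {
            ("Ab4G", "Fa2Ab4G"),
            ("Ab4G", "Ab4(Fa3)G"),
            ("Ab4G", "NNa3Ab4G"),
        }

    def test_reduction_is_idempotent(self, size3_net):
        once = reduce_network(size3_net)
        twice = reduce_network(once)
        assert [r.id for r in twice.reactions] == [r.id for r in once.reactions]

    def test_observed_remain_producible(self, toy):
        net, _ = toy
        from hmoflux.network import _max_fluxes

        idx = [j for j, r in enumerate(net.reactions) if r.kind == "sink"]
        vmax = _max_fluxes(net, idx)
        assert all(vmax[j] > 1e-6 for j in idx)

    def test_empty_observed_removes_everything(self, rules):
        net = build_complete_network(BuilderConfig(max_size=4, rules=rules))
        red = reduce_network(net)
        assert red.reactions_of_kind(BIOSYNTHESIS) == []

    def test_every_reduced_reaction_carries_flux(self, size3_net):
        from hmoflux.network import _max_fluxes

        red = reduce_network(size3_net)
        idx = [j for j, r in enumerate(red.reactions) if r.kind == BIOSYNTHESIS]
        vmax = _max_fluxes(red, idx)
        assert all(vmax[j] > 1e-9 for j in idx)


def test_fva_agrees_with_cobra_oracle(size3_net):
    """Independent FBA oracle: the same network assembled in COBRApy."""
    cobra = pytest.importorskip("cobra")
    from hmoflux.network import _max_fluxes

    model = cobra.Model("toy")
    mets = {s: cobra.Metabolite(f"M{i}") for i, s in enumerate(size3_net.species_ids)}
    rxns = {}
    for r in size3_net.reactions:
        rx = cobra.Reaction(r.id.replace("|", "_""_"))
        rx.lower_bound, rx.upper_bound = 0.0, (1.0 if r.kind == "input" else 1000.0)
        model.add_reactions([rx])
        stoich = {}
        if r.substrate is not None:
            stoich[mets[r.substrate]] = -1.0
        if r.product is not None:
            stoich[mets[r.product]] = 1.0
        rx.add_metabolites(stoich)
        rxns[r.id] = rx
    ours = _max_fluxes(
        size3_net,
        [j for j, r in enumerate(size3_net.reactions) if r.kind == BIOSYNTHESIS],
    )
    for j, r in enumerate(size3_net.reactions):
        if r.kind != BIOSYNTHESIS:
            continue
        model.objective = rxns[r.id]
        assert np.isclose(model.slim_optimize(), ours[j], atol=1e-6), r.id


def test_json_roundtrip(toy):
    from hmoflux.network import ReactionNetwork

    net, _ = toy
    again = ReactionNetwork.from_json(net.to_json())
    assert [r.id for r in again.reactions] == [r.id for r in net.reactions]
    assert set(again.species) == set(net.species)
    assert again.observed == net.observed
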