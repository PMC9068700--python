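"""MILP enumeration against brute-force oracles; FBA fitting; normalisation."""

import numpy as np
import pandas as pd
import pytest
from helpers import (
    make_net,
    oracle_min_cardinality,
    oracle_minimal_models,
    random_dag_net,
)

from hmoflux.models import (
    CandidateModel,
    EnumConfig,
    InfeasibleSampleError,
    enumerate_models,
    fit_fluxes,
    minimal_cardinality,
    normalize_flux,
    validate_profile,
)
from hmoflux.network import BIOSYNTHESIS, ReactionNetwork


@pytest.fixture(scope="module")
def chain_net():
    # ROOT -> A -> B -> C -> HMO (unique 4-reaction biosynthetic path)
    return make_net(
        [("ROOT", "A"), ("A", "B"), ("B", "C"), ("C", "H")], {"HMO": ["H"]}
    )


@pytest.fixture(scope="module")
def diamond_net():
    # two 2-reaction routes ROOT->X->H / ROOT->Y->H
    return make_net(
        [("ROOT", "X"), ("X", "H"), ("ROOT", "Y"), ("Y", "H")], {"HMO": ["H"]}
    )


class TestMinimalCardinality:
    def test_unique_chain(self, chain_net):
        assert minimal_cardinality(chain_net) == 4

    def test_diamond(self, diamond_net):
        assert minimal_cardinality(diamond_net) == 2
        assert minimal_cardinality(diamond_net) == oracle_min_cardinality(diamond_net)

    def test_infeasible_raises(self):
        net = make_net([("ROOT", "A")], {"HMO": ["A"]})
        dead = ReactionNetwork(
            net.species,
            [r for r in net.reactions if r.kind != BIOSYNTHESIS],
            net.root_code,
            net.observed,
        )
        with pytest.raises(RuntimeError, match="infeasible"):
            minimal_cardinality(dead)


class TestEnumeration:
    def test_diamond_has_exactly_two_models(self, diamond_net):
        models = enumerate_models(diamond_net)
        assert {m.reaction_ids for m in models} == oracle_minimal_models(diamond_net)
        assert sorted(m.n_reactions for m in models) == [2, 2]

    def test_ambiguous_isomer_routes(self):
        # one HMO with two candidate isomers on otherwise unique paths
        net = make_net(
            [("ROOT", "I1"), ("ROOT", "I2")], {"HMO": ["I1", "I2"]}
        )
        models = enumerate_models(net)
        assert {m.reaction_ids for m in models} == oracle_minimal_models(net)
        assert len(models) == 2 and all(m.n_reactions == 1 for m in models)

    def test_cap_one(self, diamond_net):
        models = enumerate_models(diamond_net, EnumConfig(cap=1))
        assert len(models) == 1 and models[0].n_reactions == 2

    def test_oracle_equivalence_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(12):
            net = random_dag_net(rng)
            got = {m.reaction_ids for m in enumerate_models(net, EnumConfig(cap=None))}
            assert got == oracle_minimal_models(net)

    def test_sizes_bounded_by_minimum_and_network(self, toy):
        net, _ = toy
        models = enumerate_models(net, EnumConfig(cap=15))
        mc = minimal_cardinality(net)
        nb = len(net.reactions_of_kind(BIOSYNTHESIS))
        assert all(mc <= m.n_reactions <= nb for m in models)

    def test_deterministic(self, diamond_net):
        a = [sorted(m.reaction_ids) for m in enumerate_models(diamond_net)]
        b = [sorted(m.reaction_ids) for m in enumerate_models(diamond_net)]
        assert a == b


def _full_model(net):
    return CandidateModel(frozenset(r.id for r in net.model_reactions))


class TestFitFluxes:
    def test_chain_unit_abundance(self, chain_net):
        sol = fit_fluxes(chain_net, _full_model(chain_net), {"HMO": 1.0})
        for r in chain_net.reactions_of_kind(BIOSYNTHESIS):
            assert np.isclose(sol.fluxes[r.id], 1.0)
        assert np.isclose(sol.fluxes["EX_lactose"], 1.0)

    def test_two_branches(self):
        net = make_net(
            [("ROOT", "X"), ("ROOT", "Y")], {"HX": ["X"], "HY": ["Y"]}
        )
        sol = fit_fluxes(net, _full_model(net), {"HX": 0.6, "HY": 0.4})
        assert np.isclose(sol.fluxes["ROOT>X"], 0.6)
        assert np.isclose(sol.fluxes["ROOT>Y"], 0.4)
        assert np.isclose(sol.fluxes["EX_lactose"], 1.0)

    def test_shared_first_step(self):
        # hand-solved three-variable balance: shared step carries both sinks
        net = make_net(
            [("ROOT", "M"), ("M", "P"), ("M", "Q")], {"HP": ["P"], "HQ": ["Q"]}
        )
        sol = fit_fluxes(net, _full_model(net), {"HP": 0.3, "HQ": 0.3})
        assert np.isclose(sol.fluxes["ROOT>M"], 0.6)

    def test_mass_conservation(self, toy):
        net, model = toy
        rng = np.random.default_rng(5)
        ab = rng.dirichlet(np.ones(len(net.observed)))
        abundances = dict(zip(net.observed, ab))
        sol = fit_fluxes(net, model, abundances)
        sinks = sum(sol.fluxes[r.id] for r in net.reactions if r.kind == "sink")
        assert np.isclose(sinks, sol.fluxes["EX_lactose"], atol=1e-8)

    def test_linearity_in_abundances(self, toy):
        net, model = toy
        abundances = {n: 1.0 / len(net.observed) for n in net.observed}
        scaled = {n: 0.5 * v for n, v in abundances.items()}
        a = fit_fluxes(net, model, abundances).fluxes
        b = fit_fluxes(net, model, scaled).fluxes
        assert np.allclose(b.to_numpy(), 0.5 * a.to_numpy(), atol=1e-8)

    def test_zero_abundance_pins_sink(self, toy):
        net, model = toy
        abundances = {n: 0.0 for n in net.observed}
        abundances["LNT"] = 1.0
        sol = fit_fluxes(net, model, abundances)
        assert np.isclose(sol.fluxes["EX_3FL"], 0.0)
        assert np.isclose(sol.fluxes["EX_LNT"], 1.0)

    def test_infeasible_sample_reported(self, diamond_net):
        # model lacking any route to the sink cannot hit a positive abundance
        model = CandidateModel(frozenset({"ROOT>X", "H|pool|HMO"}))
        broken = CandidateModel(frozenset({"ROOT>X"}))
        fit_fluxes(diamond_net, CandidateModel(model.reaction_ids | {"X>H"}), {"HMO": 1.0})
        with pytest.raises(InfeasibleSampleError):
            fit_fluxes(diamond_net, broken, {"HMO": 1.0})


class TestNormalizeFlux:
    def test_sole_consumer_is_one(self, chain_net):
        sol = fit_fluxes(chain_net, _full_model(chain_net), {"HMO": 1.0})
        for r in chain_net.reactions_of_kind(BIOSYNTHESIS):
            assert np.isclose(sol.normalized[r.id], 1.0)

    def test_split_consumers(self):
        net = make_net(
            [("ROOT", "X"), ("ROOT", "Y")], {"HX": ["X"], "HY": ["Y"]}
        )
        sol = fit_fluxes(net, _full_model(net), {"HX": 0.6, "HY": 0.4})
        assert np.isclose(sol.normalized["ROOT>X"], 0.6)
        assert np.isclose(sol.normalized["ROOT>Y"], 0.4)

    def test_zero_over_zero_is_zero(self, toy):
        net, model = toy
        abundances = {n: 0.0 for n in net.observed}
        abundances["LNT"] = 1.0
        sol = fit_fluxes(net, model, abundances)
        assert ((sol.normalized >= 0) & (sol.normalized <= 1)).all()

    def test_consumers_of_a_node_sum_to_at_most_one(self, toy):
        net, model = toy
        rng = np.random.default_rng(17)
        for _ in range(5):
            ab = dict(zip(net.observed, rng.dirichlet(np.ones(len(net.observed)))))
            sol = fit_fluxes(net, model, ab)
            by_substrate = {}
            for r in net.model_reactions:
                by_substrate.setdefault(r.substrate, []).append(sol.normalized[r.id])
            for vals in by_substrate.values():
                assert sum(vals) <= 1.0 + 1e-8
            assert ((sol.normalized >= 0) & (sol.normalized <= 1)).all()


def test_profile_validation():
    good = pd.DataFrame({"A": [0.4, 0.5], "B": [0.6, 0.5]}, index=["s1", "s2"])
    validate_profile(good)
    bad = pd.DataFrame({"A": [0.7], "B": [0.5]}, index=["s1"])
    with pytest.raises(ValueError, match="s1"):
        validate_profile(bad)
    neg = pd.DataFrame({"A": [-0.1], "B": [1.1]}, index=["s1"])
    with pytest.raises(ValueError, match="negative"):
        validate_profile(neg)
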