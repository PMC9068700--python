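import pytest

from hmoflux.datasets import load_hmo_structures
from hmoflux.network import BuilderConfig, attach_observations, build_complete_network
from hmoflux.rules import load_rules
from hmoflux.testnets import toy_reduced_network


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def structures():
    return load_hmo_structures()


@pytest.fixture(scope="session")
def size3_net(rules, structures):
    """Complete network capped at 3 residues with the three trisaccharide sinks."""
    net = build_complete_network(BuilderConfig(max_size=3, rules=rules))
    observed = {name: structures[name] for name in ("2'FL", "3FL", "3'SL")}
    return attach_observations(net, observed)


@pytest.fixture(scope="session")
def toy():
    """(reduced toy network, deterministic true model) shared across tests."""
    return toy_reduced_network()
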