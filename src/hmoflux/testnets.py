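"""Small ready-made networks for simulation studies and fast pipeline runs.

The full 16-HMO, nine-residue network supports millions of candidate
models; for recovery benchmarks and smoke runs a trimmed observed set on a
smaller size cap gives the same structure (shared intermediates, isomer
pooling, all linkage families except branching) at a fraction of the cost.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .datasets import load_hmo_structures
from .models import CandidateModel, EnumConfig, enumerate_models
from .network import (
    BuilderConfig,
    ReactionNetwork,
    attach_observations,
    build_complete_network,
    reduce_network,
)
from .rules import load_rules

__all__ = ["toy_reduced_network", "TOY_OBSERVED"]

#: default toy observed set: nine measured HMOs reachable within six
#: residues, exercising linkages L1-L7, L9 and L10.
TOY_OBSERVED = (
    "2'FL", "3FL", "3'SL", "LNT", "LNnT", "LNFPII", "LSTb", "LSTc", "DFLNT",
)


def toy_reduced_network(
    observed: Sequence[str] = TOY_OBSERVED,
    max_size: int = 6,
    enum_cfg: Optional[EnumConfig] = None,
) -> tuple[ReactionNetwork, CandidateModel]:
    """Reduced network over a subset of the packaged HMOs + one true model.

    The true model is the first subset-minimal model of the deterministic
    enumeration (so it is reproducible across runs and machines).
    """
    rules = load_rules()
    structures = load_hmo_structures()
    subset = {}
    for name in observed:
        members = [g for g in structures[name] if g.size <= max_size]
        if not members:
            raise ValueError(f"{name!r} has no structures within max_size={max_size}")
        subset[name] = members
    net = build_complete_network(BuilderConfig(max_size=max_size, rules=rules))
    net = attach_observations(net, subset)
    reduced = reduce_network(net)
    models = enumerate_models(reduced, enum_cfg or EnumConfig(cap=1))
    return reduced, models[0]
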