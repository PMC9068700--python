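"""Reaction importance and top-paths summary network extraction.

Reaction importance aggregates (i) how often a reaction appears in the
commonly high-performing candidate models and (ii) how enriched it is
there relative to the full model ensemble (upper-tail hypergeometric).
Both components are min-max normalised over reactions and averaged.

The summary network retains, for every observed HMO, the top fraction
(default 5%) of directed biosynthetic paths from lactose to any of its
candidate structures, scored by aggregate edge importance (mean by
default; ``min`` and ``product`` are offered since path length biases
differ).  At least one path per HMO is always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .models import CandidateModel
from .network import BIOSYNTHESIS, ReactionNetwork

__all__ = [
    "SummaryConfig",
    "reaction_importance",
    "count_paths",
    "extract_summary",
    "summary_to_sif",
]


@dataclass
class SummaryConfig:
    top_frac: float = 0.05
    aggregation: str = "mean"  # mean | min | product over path edges
    max_paths: int = 200_000  # guard against path explosion

    def __post_init__(self):
        if not (0 < self.top_frac <= 1):
            raise ValueError("top_frac must be in (0, 1]")
        if self.aggregation not in ("mean", "min", "product"):
            raise ValueError("aggregation must be mean, min or product")


def reaction_importance(
    models_all: Sequence[CandidateModel],
    models_high: Sequence[CandidateModel],
    net: ReactionNetwork,
) -> pd.DataFrame:
    """Per model reaction: inclusion proportion in the high set, enrichment p,
    and the aggregated importance score in [0, 1]."""
    if not models_all or not models_high:
        raise ValueError("both model sets must be non-empty")
    rids = [r.id for r in net.model_reactions]
    n_all, n_high = len(models_all), len(models_high)
    rows = []
    for rid in rids:
        k_all = sum(m.includes(rid) for m in models_all)
        k_high = sum(m.includes(rid) for m in models_high)
        # draws = the high-performing set, successes = models containing r
        p = float(stats.hypergeom.sf(k_high - 1, n_all, k_all, n_high))
        rows.append(
            {"reaction": rid, "prop_high": k_high / n_high, "enrich_p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows).set_index("reaction")
    neglog = -np.log10(df.enrich_p.clip(lower=1e-300))
    df["importance"] = (_minmax(df.prop_high) + _minmax(neglog)) / 2.0
    return df


def _minmax(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if hi - lo <= 0:
        return pd.Series(0.5, index=s.index)
    return (s - lo) / (hi - lo)


def _species_graph(net: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for r in net.reactions_of_kind(BIOSYNTHESIS):
        g.add_edge(r.substrate, r.product, reaction=r.id)
    return g


def count_paths(net: ReactionNetwork, target: str) -> int:
    """Number of directed biosynthetic paths lactose -> target (DP on the DAG)."""
    g = _species_graph(net)
    if target == net.root_code:
        return 1
    if target not in g:
        return 0
    counts = {net.root_code: 1}
    for node in nx.topological_sort(g):
        c = counts.get(node, 0)
        if c:
            for succ in g.successors(node):
                counts[succ] = counts.get(succ, 0) + c
    return counts.get(target, 0)


def extract_summary(
    net: ReactionNetwork,
    importance: Mapping[str, float],
    cfg: Optional[SummaryConfig] = None,
) -> dict:
    """Union of the top-``top_frac`` paths from lactose to each observed HMO.

    Returns ``{"reactions": {rid: importance}, "paths": {hmo: [(score,
    [rids]), ...]}}`` where the retained paths are sorted by descending
    score.  Raises when an observed structure is unreachable (an upstream
    contract violation) or when the path count exceeds the guard.
    """
    cfg = cfg or SummaryConfig()
    g = _species_graph(net)
    agg = {
        "mean": lambda xs: float(np.mean(xs)),
        "min": lambda xs: float(np.min(xs)),
        "product": lambda xs: float(np.prod(xs)),
    }[cfg.aggregation]
    kept: dict[str, float] = {}
    paths_out: dict[str, list] = {}
    for name, members in net.observed.items():
        total = sum(count_paths(net, code) for code in members)
        if total == 0:
            raise ValueError(f"observed HMO {name!r} unreachable in the reduced network")
        if total > cfg.max_paths:
            raise RuntimeError(
                f"{total} paths to {name!r} exceed the {cfg.max_paths} guard"
            )
        scored = []
        for code in members:
            if code == net.root_code:
                continue
            for path in nx.all_simple_paths(g, net.root_code, code):
                rids = [
                    g.edges[u, v]["reaction"] for u, v in zip(path[:-1], path[1:])
                ]
                scored.append((agg([importance[r] for r in rids]), rids))
        scored.sort(key=lambda t: (-t[0], t[1]))
        n_keep = max(1, ceil(cfg.top_frac * len(scored)))
        paths_out[name] = scored[:n_keep]
        for score, rids in scored[:n_keep]:
            for rid in rids:
                kept[rid] = importance[rid]
    return {"reactions": kept, "paths": paths_out}


def summary_to_sif(net: ReactionNetwork, summary: dict) -> str:
    """SIF edge list of the summary network with importance as edge weight."""
    lines = []
    for r in net.reactions_of_kind(BIOSYNTHESIS):
        if r.id in summary["reactions"]:
            w = summary["reactions"][r.id]
            lines.append(f"{r.substrate}\t{r.rule_id}\t{r.product}\t{w:.4f}")
    return "\n".join(lines) + "\n"
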