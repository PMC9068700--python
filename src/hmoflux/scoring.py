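"""Model scoring: flux-expression concordance and high-performer selection.

For each candidate model and cohort, per-sample fluxes are fitted from the
glycoprofile, aggregated per linkage (sum of the linkage's normalised
reaction fluxes), and correlated across samples with each candidate gene's
expression (Spearman; the *gene-linkage score*, GLS).  A model's score is
the mean over its linkages of the best candidate-gene GLS; models whose
z-scored model score exceeds 1.646 (the upper 5% of a normal) are the
*high-performing* set.  Cross-cohort agreement of two high-performing sets
is assessed with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CandidateModel, EnumConfig, InfeasibleSampleError, fit_fluxes
from .network import BIOSYNTHESIS, ReactionNetwork

__all__ = [
    "ScoringConfig",
    "SelectionResult",
    "model_linkage_flux",
    "gene_linkage_score",
    "gls_matrix",
    "model_scores",
    "select_high_performing",
    "overlap_enrichment",
    "linkage_candidates",
]

log = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    z_threshold: float = 1.646  # upper 5% of a standard normal
    threshold_scan: tuple[float, float] = (0.04, 0.08)  # robustness range
    min_samples: int = 4  # minimum paired observations for a correlation
    linkage_aggregation: str = "sum"  # sum | mean | max over a linkage's reactions

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.linkage_aggregation not in ("sum", "mean", "max"):
            raise ValueError("linkage_aggregation must be sum, mean or max")


def model_linkage_flux(
    net: ReactionNetwork,
    model: CandidateModel,
    profile: pd.DataFrame,
    cfg: Optional[ScoringConfig] = None,
    enum_cfg: Optional[EnumConfig] = None,
) -> pd.DataFrame:
    """Per-sample normalised flux through each linkage of a model.

    ``profile`` is samples x observed-HMO relative abundances.  Samples whose
    profile is infeasible under the model are dropped (logged); linkages with
    no included reaction are absent from the columns.
    """
    cfg = cfg or ScoringConfig()
    agg = {"sum": np.sum, "mean": np.mean, "max": np.max}[cfg.linkage_aggregation]
    groups: dict[str, list[str]] = {}
    for r in net.reactions_of_kind(BIOSYNTHESIS):
        if r.id in model.reaction_ids:
            groups.setdefault(r.rule_id, []).append(r.id)
    rows = {}
    for sample, ab in profile.iterrows():
        try:
            sol = fit_fluxes(net, model, ab.to_dict(), enum_cfg)
        except InfeasibleSampleError:
            log.warning("sample %s infeasible under model; dropped", sample)
            continue
        rows[sample] = {
            lk: float(agg([sol.normalized[rid] for rid in rids]))
            for lk, rids in groups.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sorted(groups, key=_linkage_key)
    )


def _linkage_key(lk: str):
    return (len(lk), lk)  # L1..L10 in numeric order


def gene_linkage_score(
    flux: pd.Series, expression: pd.Series, min_samples: int = 4
) -> float:
    """Spearman correlation between linkage flux and one gene's expression.

    Pairs with a missing value on either side are dropped; returns NaN when
    fewer than ``min_samples`` pairs remain or either vector is constant.
    """
    joined = pd.concat([flux, expression], axis=1, join="inner").dropna()
    if len(joined) < min_samples:
        log.debug("fewer than %d paired samples; GLS missing", min_samples)
        return float("nan")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def linkage_candidates(
    net: ReactionNetwork, genes: Optional[Iterable[str]] = None
) -> dict[str, list[str]]:
    """Linkage -> candidate genes, optionally restricted to a retained set."""
    allowed = set(genes) if genes is not None else None
    out = {}
    for rule in net.rules:
        cands = [
            g for g in rule.candidate_genes if allowed is None or g in allowed
        ]
        out[rule.id] = cands
    return out


def gls_matrix(
    linkage_flux_by_model: Mapping[object, pd.DataFrame],
    expression: pd.DataFrame,
    candidates: Mapping[str, Sequence[str]],
    min_samples: int = 4,
) -> pd.DataFrame:
    """Models x (linkage, gene) Spearman-correlation matrix for one cohort.

    ``expression`` is samples x genes; only (linkage, gene) pairs where the
    gene is a candidate for a linkage present in the model are computed.
    """
    records = {}
    for mid, lf in linkage_flux_by_model.items():
        row = {}
        for lk in lf.columns:
            for gene in candidates.get(lk, ()):
                if gene not in expression.columns:
                    continue
                row[(lk, gene)] = gene_linkage_score(
                    lf[lk], expression[gene], min_samples
                )
        records[mid] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["linkage", "gene"])
    return df.sort_index(axis=1)


def model_scores(gls: pd.DataFrame) -> pd.Series:
    """Mean over linkages of the per-linkage maximum GLS (missing excluded)."""
    per_linkage_max = gls.T.groupby(level="linkage").max(min_count=1).T
    return per_linkage_max.mean(axis=1)


@dataclass
class SelectionResult:
    selected: list
    z: pd.Series
    qq_correlation: float  # normality diagnostic: r of the Q-Q plot

    def __iter__(self):  # convenience: `ids, z, qq = select_high_performing(...)`
        return iter((self.selected, self.z, self.qq_correlation))


def select_high_performing(
    scores: pd.Series, cfg: Optional[ScoringConfig] = None
) -> SelectionResult:
    """Models whose z-scored model score exceeds the threshold (default 1.646).

    The z-score uses the empirical mean/sd over all models; a Q-Q normality
    diagnostic (correlation of sorted scores vs normal quantiles) is
    reported alongside.  Zero variance yields an empty selection.
    """
    cfg = cfg or ScoringConfig()
    vals = scores.dropna()
    if len(vals) < 2:
        raise ValueError("need at least two model scores for selection")
    sd = vals.std(ddof=1)
    if sd == 0:
        log.warning("all model scores identical; empty selection")
        return SelectionResult([], pd.Series(0.0, index=vals.index), 1.0)
    z = (vals - vals.mean()) / sd
    order = np.sort(vals.to_numpy())
    theo = stats.norm.ppf((np.arange(1, len(order) + 1) - 0.5) / len(order))
    qq = float(np.corrcoef(order, theo)[0, 1]) if len(order) > 2 else 1.0
    selected = list(z.index[z > cfg.z_threshold])
    return SelectionResult(selected, z, qq)


def threshold_scan(
    scores: pd.Series, cfg: Optional[ScoringConfig] = None
) -> pd.DataFrame:
    """Robustness scan of the selection threshold over a top-fraction range.

    For each selection fraction in ``cfg.threshold_scan`` (default 4-8%, in
    1% steps) the z-threshold is the corresponding upper-tail normal
    quantile; reports the selected count and the Jaccard similarity with the
    default selection.
    """
    cfg = cfg or ScoringConfig()
    lo, hi = cfg.threshold_scan
    base = set(select_high_performing(scores, cfg).selected)
    rows = []
    for frac in np.arange(lo, hi + 1e-9, 0.01):
        z = float(stats.norm.isf(frac))
        sel = set(
            select_high_performing(scores, ScoringConfig(z_threshold=z)).selected
        )
        union = len(base | sel)
        rows.append(
            {
                "fraction": round(float(frac), 4),
                "z_threshold": z,
                "n_selected": len(sel),
                "jaccard_vs_default": (len(base & sel) / union) if union else 1.0,
            }
        )
    return pd.DataFrame(rows)


def overlap_enrichment(
    set_a: Iterable, set_b: Iterable, universe: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of the observed intersection.

    Returns ``(intersection size, P(overlap >= observed))`` for two subsets
    drawn from a universe of ``universe`` models.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe or len(b) > universe:
        raise ValueError("set larger than universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    return k, min(p, 1.0)
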