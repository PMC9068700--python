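"""Gene-to-linkage assignment: expression filtering, PROP/GLS/MSC, support.

Which isozyme of a glycosyltransferase family carries each linkage is
resolved in two stages.  First, candidate genes that are essentially
unexpressed in lactating mammary epithelium are excluded: a gene is
dropped when it is undetected in at least 75% of a cohort's microarray
samples and an independent RNA-Seq reference also measures low expression
(75th-percentile TPM <= 2 and below the reference-tissue median); a
linkage left with a single retained candidate is assigned by default.

Second, for the remaining ambiguous linkages three metrics are computed
over the high-performing model set of each cohort:

* **PROP** — the fraction of models in which the gene attains the
  linkage's maximum GLS (ties split equally);
* **GLS mean** — the gene's average Spearman flux-expression correlation;
* **MSC** — the Pearson correlation between model score and the gene's
  GLS, an estimate of the gene's influence on model ranking.

Each metric is z-scored against a permutation background obtained by
randomly remapping all entries of the GLS matrix (n = 27 shuffles) and
rerunning the scoring, selection and metric computation on each shuffle.
Per cohort, the three z-scores are summed and converted to an upper-tail
normal p-value (z_sum / sqrt(3)); cohorts are pooled with Fisher's method
and corrected across genes with Benjamini-Hochberg.  The reported support
is -log10(q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ScoringConfig, model_scores, select_high_performing

__all__ = [
    "PermConfig",
    "FilterResult",
    "filter_candidates",
    "compute_prop",
    "compute_gls_mean",
    "compute_msc",
    "metric_table",
    "permutation_background",
    "support_table",
    "support_analysis",
]

log = logging.getLogger(__name__)

METRICS = ("prop", "gls_mean", "msc")


@dataclass
class PermConfig:
    n_perm: int = 27
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")


# ---------------------------------------------------------------------------
# expression-based candidate filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    retained: list[str]
    excluded: list[str]
    default_selected: dict[str, str]  # linkage -> sole retained candidate
    table: pd.DataFrame


def filter_candidates(
    detection: Mapping[str, pd.DataFrame],
    tpm_q75: pd.Series,
    reference_median_tpm: pd.Series,
    candidates: Mapping[str, Sequence[str]],
    undetected_frac: float = 0.75,
    tpm_min: float = 2.0,
) -> FilterResult:
    """Low-expression filtering of candidate genes.

    ``detection`` maps cohort -> samples x genes boolean (or truthy) detection
    matrix.  A gene is excluded iff it is undetected in at least
    ``undetected_frac`` of some cohort's samples AND neither RNA-Seq rescue
    criterion holds (``tpm_q75 > tpm_min`` or ``tpm_q75 >`` the
    reference-tissue median TPM).  Genes absent from a matrix are treated as
    undetected; missing TPM entries as zero.
    """
    universe = sorted({g for gs in candidates.values() for g in gs})
    rows = []
    for gene in universe:
        worst = 0.0
        for cohort, det in detection.items():
            if gene in det.columns:
                frac = 1.0 - det[gene].astype(bool).mean()
            else:
                frac = 1.0
            worst = max(worst, frac)
        tpm = float(tpm_q75.get(gene, 0.0))
        ref = float(reference_median_tpm.get(gene, np.inf))
        rescued = (tpm > tpm_min) or (tpm > ref)
        excluded = (worst >= undetected_frac) and not rescued
        rows.append(
            {
                "gene": gene,
                "max_undetected_frac": worst,
                "tpm_q75": tpm,
                "reference_median_tpm": ref,
                "rescued": rescued,
                "excluded": excluded,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    retained = sorted(table.index[~table.excluded])
    defaults = {}
    for lk, genes in candidates.items():
        kept = [g for g in genes if g in retained]
        if len(kept) == 1:
            defaults[lk] = kept[0]
    return FilterResult(
        retained=retained,
        excluded=sorted(table.index[table.excluded]),
        default_selected=defaults,
        table=table,
    )


# ---------------------------------------------------------------------------
# per-(linkage, gene) metrics over a high-performing model set
# ---------------------------------------------------------------------------


def compute_prop(gls_high: pd.DataFrame) -> pd.Series:
    """Fraction of models where each gene attains its linkage's maximum GLS.

    Exact ties split equally among tied genes; the denominator is the full
    model set, so within a linkage the PROP values sum to at most 1 (below 1
    when some models lack the linkage).
    """
    n_models = len(gls_high)
    out = {}
    for lk in gls_high.columns.get_level_values("linkage").unique():
        sub = gls_high[lk]
        winners = sub.eq(sub.max(axis=1), axis=0) & sub.notna()
        n_tied = winners.sum(axis=1)
        share = winners.div(n_tied.where(n_tied > 0, 1), axis=0)
        for gene in sub.columns:
            out[(lk, gene)] = float(share[gene].sum() / n_models) if n_models else np.nan
    s = pd.Series(out)
    s.index.names = ["linkage", "gene"]
    return s.sort_index()


def compute_gls_mean(gls_high: pd.DataFrame) -> pd.Series:
    s = gls_high.mean(axis=0)
    s.index.names = ["linkage", "gene"]
    return s.sort_index()


def compute_msc(scores_high: pd.Series, gls_high: pd.DataFrame, min_models: int = 3) -> pd.Series:
    """Pearson correlation of (model score, gene GLS) across high models.

    A gene whose GLS is constant across models (e.g. its linkage has a
    single route shared by every model) exerts no detectable influence on
    the model score: MSC is defined as 0 in that degenerate case.  Missing
    (NaN) is reserved for insufficient data (< ``min_models`` pairs).
    """
    out = {}
    for col in gls_high.columns:
        joined = pd.concat([scores_high, gls_high[col]], axis=1).dropna()
        if len(joined) < min_models:
            out[col] = np.nan
            continue
        x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[col] = 0.0
            continue
        out[col] = float(stats.pearsonr(x, y).statistic)
    s = pd.Series(out)
    s.index.names = ["linkage", "gene"]
    return s.sort_index()


def metric_table(gls: pd.DataFrame, scores: pd.Series, high_ids: Sequence) -> pd.DataFrame:
    """PROP / GLS-mean / MSC for one cohort's high-performing model set."""
    gls_high = gls.loc[list(high_ids)]
    scores_high = scores.loc[list(high_ids)]
    return pd.DataFrame(
        {
            "prop": compute_prop(gls_high),
            "gls_mean": compute_gls_mean(gls_high),
            "msc": compute_msc(scores_high, gls_high),
        }
    )


# ---------------------------------------------------------------------------
# permutation background
# ---------------------------------------------------------------------------


def _select_for_metrics(scores: pd.Series, cfg: ScoringConfig) -> list:
    """High-performing set, falling back to the full ensemble when the
    selection is too small to support the metrics (MSC needs >= 3 models)."""
    sel = select_high_performing(scores, cfg)
    if len(sel.selected) >= 3:
        return sel.selected
    return list(scores.dropna().index)


def _one_pass(gls: pd.DataFrame, cfg: ScoringConfig) -> pd.DataFrame:
    scores = model_scores(gls)
    return metric_table(gls, scores, _select_for_metrics(scores, cfg))


def permutation_background(
    gls: pd.DataFrame,
    cfg: Optional[ScoringConfig] = None,
    perm: Optional[PermConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background mean and sd of each metric under GLS-matrix shuffling.

    Each replicate applies one uniformly random bijective remapping of all
    GLS entries onto the matrix positions (the value multiset is preserved
    exactly) and reruns scoring, selection and the three metrics.
    Returns ``(mean, sd)`` DataFrames indexed by (linkage, gene) with one
    column per metric; sd uses ddof=1.
    """
    cfg = cfg or ScoringConfig()
    perm = perm or PermConfig()
    rng = rng if rng is not None else np.random.default_rng(perm.seed)
    # canonical layout: the background is invariant to caller row/column order
    gls = gls.sort_index(axis=0).sort_index(axis=1)
    flat = gls.to_numpy().ravel()
    acc: list[pd.DataFrame] = []
    for _ in range(perm.n_perm):
        shuffled = pd.DataFrame(
            rng.permutation(flat).reshape(gls.shape),
            index=gls.index,
            columns=gls.columns,
        )
        acc.append(_one_pass(shuffled, cfg))
    stacked = pd.concat(acc, keys=range(len(acc)))
    grouped = stacked.groupby(level=["linkage", "gene"])
    return grouped.mean(), grouped.std(ddof=1)


# ---------------------------------------------------------------------------
# pooled support score
# ---------------------------------------------------------------------------


def _fisher_pool(pvals: Sequence[float]) -> float:
    ps = [p for p in pvals if np.isfinite(p)]
    if not ps:
        return np.nan
    ps = [min(max(p, 1e-300), 1.0) for p in ps]
    x = -2.0 * sum(np.log(ps))
    return float(stats.chi2.sf(x, 2 * len(ps)))


def support_table(
    metrics: Mapping[str, pd.DataFrame],
    backgrounds: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    fdr_q: float = 0.1,
    global_fdr: bool = False,
    default_selected: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Combine per-cohort metrics and permutation backgrounds into support.

    z = (observed - background mean) / background sd per metric; z_sum is
    their sum and the cohort p-value is the upper-tail normal probability of
    z_sum / sqrt(3).  Cohorts with a missing metric are omitted from Fisher
    pooling (the chi-square df adjusts).  q is Benjamini-Hochberg across
    genes within each linkage (or across all pairs with ``global_fdr``);
    support = -log10(q), flagged significant at q < ``fdr_q``.
    """
    cohorts = list(metrics)
    index = metrics[cohorts[0]].index
    out = pd.DataFrame(index=index)
    for cohort in cohorts:
        obs = metrics[cohort]
        mean, sd = backgrounds[cohort]
        z = (obs - mean.reindex(obs.index)) / sd.reindex(obs.index)
        z = z.replace([np.inf, -np.inf], np.nan)
        for m in METRICS:
            out[f"z_{m}_{cohort}"] = z[m]
        z_sum = z[list(METRICS)].sum(axis=1, min_count=len(METRICS))
        out[f"z_sum_{cohort}"] = z_sum
        out[f"p_{cohort}"] = stats.norm.sf(z_sum / np.sqrt(len(METRICS)))
        missing = z_sum.isna()
        if missing.any():
            log.info(
                "%s: %d (linkage, gene) pairs lack a metric; omitted from pooling",
                cohort, int(missing.sum()),
            )
    pcols = [f"p_{c}" for c in cohorts]
    out["p_pooled"] = out[pcols].apply(lambda row: _fisher_pool(row.to_list()), axis=1)
    out["q"] = np.nan
    if global_fdr:
        groups = [out.index]
    else:
        groups = [
            out.index[out.index.get_level_values("linkage") == lk]
            for lk in out.index.get_level_values("linkage").unique()
        ]
    for idx in groups:
        p = out.loc[idx, "p_pooled"]
        ok = p.notna()
        if ok.sum():
            q = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
            out.loc[p.index[ok], "q"] = q
    with np.errstate(divide="ignore"):
        out["support"] = -np.log10(out["q"])
    out["selected"] = out["q"] < fdr_q
    defaults = default_selected or {}
    out["default_selected"] = [
        defaults.get(lk) == gene for lk, gene in out.index
    ]
    return out


def support_analysis(
    gls_by_cohort: Mapping[str, pd.DataFrame],
    cfg: Optional[ScoringConfig] = None,
    perm: Optional[PermConfig] = None,
    fdr_q: float = 0.1,
    global_fdr: bool = False,
    default_selected: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Full support pipeline from per-cohort GLS matrices.

    Per cohort: model scores -> high-performing selection -> metrics ->
    permutation background; then pooled support across cohorts.
    """
    cfg = cfg or ScoringConfig()
    perm = perm or PermConfig()
    metrics, backgrounds = {}, {}
    for cohort, gls in gls_by_cohort.items():
        scores = model_scores(gls)
        metrics[cohort] = metric_table(gls, scores, _select_for_metrics(scores, cfg))
        # fresh generator per cohort from the same seed: swapping cohort
        # labels then swaps outputs exactly (label symmetry)
        rng = np.random.default_rng(perm.seed)
        backgrounds[cohort] = permutation_background(gls, cfg, perm, rng)
    return support_table(metrics, backgrounds, fdr_q, global_fdr, default_selected)
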