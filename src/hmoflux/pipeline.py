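"""Resumable pipeline: build -> reduce -> enumerate -> fit -> score -> support.

The pipeline is a thin orchestration over the library modules.  Each stage
writes plain-text artifacts (JSON / TSV) into the output directory and
records input hashes, counts and timing in ``manifest.json``; a stage is
skipped on re-run when its recorded input hashes match (resumability).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .datasets import load_hmo_structures
from .models import CandidateModel, EnumConfig, enumerate_models, validate_profile
from .network import (
    BIOSYNTHESIS,
    POOLING,
    BuilderConfig,
    ReactionNetwork,
    attach_observations,
    build_complete_network,
    reduce_network,
)
from .rules import load_rules
from .scoring import (
    ScoringConfig,
    gls_matrix,
    linkage_candidates,
    model_linkage_flux,
    model_scores,
    overlap_enrichment,
    select_high_performing,
)
from .summary import SummaryConfig, extract_summary, reaction_importance, summary_to_sif
from .support import PermConfig, support_analysis

__all__ = ["PipelineConfig", "CohortInput", "load_config", "validate_inputs", "run"]

log = logging.getLogger(__name__)


@dataclass
class CohortInput:
    profile: str  # TSV: samples x observed-HMO relative abundances
    expression: str  # TSV: samples x genes
    secretor: Optional[str] = None  # optional TSV: sample, secretor (0/1)


@dataclass
class PipelineConfig:
    outdir: str
    cohorts: dict[str, CohortInput] = field(default_factory=dict)
    rules_path: Optional[str] = None  # None -> packaged table
    structures_path: Optional[str] = None  # None -> packaged fixture
    max_size: int = 9
    enum: EnumConfig = field(default_factory=lambda: EnumConfig(cap=100))
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    summary: SummaryConfig = field(default_factory=SummaryConfig)
    fdr_q: float = 0.1
    seed: int = 0


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cohorts = {
        name: CohortInput(**spec) for name, spec in doc.pop("cohorts", {}).items()
    }
    for key, cls in (
        ("enum", EnumConfig),
        ("scoring", ScoringConfig),
        ("perm", PermConfig),
        ("summary", SummaryConfig),
    ):
        if key in doc and isinstance(doc[key], dict):
            sub = doc[key]
            if key == "scoring" and "threshold_scan" in sub:
                sub["threshold_scan"] = tuple(sub["threshold_scan"])
            doc[key] = cls(**sub)
    return PipelineConfig(cohorts=cohorts, **doc)


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def validate_inputs(config: PipelineConfig) -> dict:
    """Check profiles, sample matching and secretor plausibility.

    Errors (raised): malformed profile rows, misaligned sample ids.
    Warnings (returned): secretor-flagged samples without alpha-1,2-fucosylated
    HMOs and vice versa.
    """
    report: dict = {"cohorts": {}, "warnings": []}
    structures = load_hmo_structures(config.structures_path)
    a2 = [
        n for n, gs in structures.items()
        if all(g.contains_linkage("F", "a", 2) for g in gs)
    ]
    for name, cohort in config.cohorts.items():
        prof = _read_tsv(cohort.profile)
        validate_profile(prof)
        expr = _read_tsv(cohort.expression)
        missing = sorted(set(prof.index) - set(expr.index))
        extra = sorted(set(expr.index) - set(prof.index))
        if missing or extra:
            raise ValueError(
                f"cohort {name!r}: expression and glycoprofile samples are not "
                f"matched (missing from expression: {missing}; "
                f"unmatched expression samples: {extra})"
            )
        info = {"n_samples": len(prof), "n_hmos": prof.shape[1], "n_genes": expr.shape[1]}
        if cohort.secretor:
            sec = _read_tsv(cohort.secretor).iloc[:, 0].astype(bool)
            a2_present = [n for n in a2 if n in prof.columns]
            if a2_present:
                a2_total = prof[a2_present].sum(axis=1)
                for sample in prof.index:
                    if sec.get(sample, True) and a2_total[sample] < 1e-3:
                        report["warnings"].append(
                            f"{name}/{sample}: flagged secretor but no "
                            "alpha-1,2-fucosylated HMOs"
                        )
                    if not sec.get(sample, True) and a2_total[sample] > 0.05:
                        report["warnings"].append(
                            f"{name}/{sample}: flagged non-secretor with "
                            "substantial alpha-1,2-fucosylated HMOs"
                        )
        report["cohorts"][name] = info
    return report


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, bytes)):
            h.update(p.encode() if isinstance(p, str) else p)
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _file_hash(path: str) -> str:
    return _hash(Path(path).read_bytes())


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.doc = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, key: str) -> bool:
        return self.doc.get(stage, {}).get("input_hash") == key

    def record(self, stage: str, key: str, counts: dict, t0: float):
        self.doc[stage] = {
            "input_hash": key,
            "counts": counts,
            "seconds": round(time.time() - t0, 2),
        }
        self.path.write_text(json.dumps(self.doc, indent=1))


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest document."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    rules = load_rules(config.rules_path)
    structures = load_hmo_structures(config.structures_path)

    # -- stage: network -----------------------------------------------------
    net_key = _hash(
        config.rules_path and _file_hash(config.rules_path) or "packaged-rules",
        config.structures_path and _file_hash(config.structures_path)
        or "packaged-structures",
        config.max_size,
    )
    reduced_path = out / "reduced_network.json"
    if manifest.fresh("network", net_key) and reduced_path.exists():
        log.info("network: unchanged inputs; skipping")
        reduced = ReactionNetwork.from_json(reduced_path.read_text(), rules)
    else:
        t0 = time.time()
        complete = build_complete_network(BuilderConfig(max_size=config.max_size, rules=rules))
        attached = attach_observations(complete, structures)
        reduced = reduce_network(attached)
        reduced_path.write_text(reduced.to_json())
        (out / "reduced_network.sif").write_text(reduced.to_sif())
        manifest.record(
            "network",
            net_key,
            {
                "complete_species": len(complete.species),
                "complete_reactions": len(complete.reactions),
                "reduced_species": len(reduced.species),
                "reduced_biosynthetic": len(reduced.reactions_of_kind(BIOSYNTHESIS)),
                "reduced_pooling": len(reduced.reactions_of_kind(POOLING)),
            },
            t0,
        )

    # -- stage: enumerate ---------------------------------------------------
    enum_key = _hash(net_key, asdict(config.enum))
    models_path = out / "models.json"
    if manifest.fresh("enumerate", enum_key) and models_path.exists():
        log.info("enumerate: unchanged inputs; skipping")
        models = [
            CandidateModel(frozenset(ids)) for ids in json.loads(models_path.read_text())
        ]
    else:
        t0 = time.time()
        models = enumerate_models(reduced, config.enum)
        models_path.write_text(json.dumps([sorted(m.reaction_ids) for m in models]))
        sizes = [m.n_reactions for m in models]
        manifest.record(
            "enumerate",
            enum_key,
            {"models": len(models), "min_size": min(sizes), "max_size": max(sizes)},
            t0,
        )
    model_ids = {i: m for i, m in enumerate(models)}

    if not config.cohorts:
        return manifest.doc

    # -- stage: score per cohort -------------------------------------------
    validate_inputs(config)
    gls_by_cohort: dict[str, pd.DataFrame] = {}
    selected: dict[str, set] = {}
    for name, cohort in config.cohorts.items():
        key = _hash(enum_key, _file_hash(cohort.profile), _file_hash(cohort.expression),
                    asdict(config.scoring))
        gls_path = out / f"gls_{name}.tsv"
        scores_path = out / f"scores_{name}.tsv"
        if manifest.fresh(f"score:{name}", key) and gls_path.exists():
            log.info("score %s: unchanged inputs; skipping", name)
            gls = pd.read_csv(gls_path, sep="\t", header=[0, 1], index_col=0)
            gls.index = gls.index.astype(int)
            scores_df = pd.read_csv(scores_path, sep="\t", index_col=0)
            selected[name] = set(scores_df.index[scores_df.selected])
        else:
            t0 = time.time()
            prof = _read_tsv(cohort.profile)
            expr = _read_tsv(cohort.expression)
            cands = linkage_candidates(reduced, expr.columns)
            lfs = {
                i: model_linkage_flux(reduced, m, prof, config.scoring, config.enum)
                for i, m in model_ids.items()
            }
            gls = gls_matrix(lfs, expr, cands, config.scoring.min_samples)
            scores = model_scores(gls)
            sel = select_high_performing(scores, config.scoring)
            selected[name] = set(sel.selected)
            gls.to_csv(gls_path, sep="\t")
            pd.DataFrame(
                {
                    "score": scores,
                    "z": sel.z,
                    "selected": [i in selected[name] for i in scores.index],
                }
            ).to_csv(scores_path, sep="\t")
            manifest.record(
                f"score:{name}",
                key,
                {"models": len(gls), "high_performing": len(selected[name]),
                 "qq_correlation": round(sel.qq_correlation, 4)},
                t0,
            )
        gls_by_cohort[name] = gls

    # -- stage: overlap + support ------------------------------------------
    t0 = time.time()
    names = list(config.cohorts)
    common = set.intersection(*(selected[n] for n in names)) if names else set()
    overlap = {}
    if len(names) == 2:
        k, p = overlap_enrichment(selected[names[0]], selected[names[1]], len(models))
        overlap = {"common": k, "hypergeom_p": p}
    sup = support_analysis(
        gls_by_cohort, config.scoring, config.perm, config.fdr_q
    )
    sup.to_csv(out / "support.tsv", sep="\t")
    manifest.record(
        "support",
        _hash(enum_key, names, asdict(config.perm), config.fdr_q),
        {"common_high_performing": len(common), **overlap},
        t0,
    )

    # -- stage: summary network --------------------------------------------
    t0 = time.time()
    high = [model_ids[i] for i in sorted(common)] or models
    imp = reaction_importance(models, high, reduced)
    summary = extract_summary(reduced, imp.importance.to_dict(), config.summary)
    imp.to_csv(out / "reaction_importance.tsv", sep="\t")
    (out / "summary_network.sif").write_text(summary_to_sif(reduced, summary))
    manifest.record(
        "summary",
        _hash(enum_key, asdict(config.summary)),
        {"summary_reactions": len(summary["reactions"])},
        t0,
    )
    return manifest.doc
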