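"""Elementary glycosyltransferase linkage rules (L1-L10) and their application.

Each rule adds exactly one monosaccharide (the donor) through a fixed
anomer/position linkage to a matched acceptor site.  The acceptor is a
:class:`~hmoflux.glycans.GlycanPattern`; an optional negated constraint
pattern vetoes sites (e.g. alpha-1,3-fucosylation is blocked on a GlcNAc
already carrying a beta-1,3-galactose, where the alpha-1,4 rule acts
instead).  The ten rules shipped in ``data/rules.tsv`` cover chain
initiation/elongation (b3GnT, b3GalT, b4GalT), branching (b6GnT),
fucosylation (a2/a3/a4FucT) and sialylation (ST3GalT, ST6GalT, ST6GnT),
each with its candidate isozyme gene family.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .glycans import (
    Glycan,
    GlycanNode,
    GlycanPattern,
    PatternNode,
    _pattern_code,
    embed_pattern_in_pattern,
    match_sites,
    parse_pattern,
)

__all__ = ["LinkageRule", "load_rules", "apply_rule", "lactose", "LINKAGE_LABELS"]

LINKAGE_LABELS = {
    "L1": "b3GnT",
    "L2": "a2FucT",
    "L3": "a3FucT",
    "L4": "ST3GalT",
    "L5": "ST6GalT",
    "L6": "b3GalT",
    "L7": "b4GalT",
    "L8": "b6GnT",
    "L9": "a4FucT",
    "L10": "ST6GnT",
}


@dataclass(frozen=True)
class LinkageRule:
    id: str
    label: str
    donor: str
    anomer: str
    position: int
    acceptor: GlycanPattern
    constraint: Optional[GlycanPattern]
    product_code: str
    candidate_genes: tuple[str, ...]

    def __post_init__(self):
        if not self.candidate_genes:
            raise ValueError(f"{self.id}: candidate gene list must be non-empty")


def lactose() -> Glycan:
    """The root acceptor of all HMOs: Gal-b1,4-Glc."""
    from .glycans import parse_glycan

    return parse_glycan("Ab4G")


# ---------------------------------------------------------------------------
# anchor derivation
# ---------------------------------------------------------------------------


def _pattern_equal(a: PatternNode, b: PatternNode) -> bool:
    """Structural equality ignoring terminal flags."""
    if a.symbols != b.symbols or len(a.children) != len(b.children):
        return False
    for ca in a.children:
        cb = b.child_at(ca.position)
        if cb is None or cb.anomer != ca.anomer or not _pattern_equal(ca, cb):
            return False
    return True


def _derive_acceptor_anchor(
    acceptor: GlycanPattern, product: GlycanPattern, donor: str, anomer: str, position: int
) -> PatternNode:
    """Find the acceptor residue whose extension by the donor yields the product."""
    candidates = []
    for node in acceptor.root.nodes():
        if node.child_at(position) is not None:
            continue
        node.children.append(PatternNode(frozenset({donor}), anomer, position))
        if _pattern_equal(acceptor.root, product.root):
            candidates.append(node)
        node.children.pop()
    if len(candidates) != 1:
        raise ValueError(
            f"cannot derive a unique attachment site: acceptor {acceptor.code!r} "
            f"+ {donor}{anomer}{position} vs product {product.code!r} "
            f"({len(candidates)} candidates)"
        )
    return candidates[0]


def _derive_constraint_anchor(
    acceptor: GlycanPattern, constraint: GlycanPattern
) -> PatternNode:
    """The constraint extends the acceptor; map the acceptor anchor into it."""
    images = embed_pattern_in_pattern(acceptor, constraint)
    if len(images) != 1:
        raise ValueError(
            f"constraint {constraint.code!r} does not embed the acceptor "
            f"{acceptor.code!r} uniquely ({len(images)} embeddings)"
        )
    return images[0]


def make_rule(
    rule_id: str,
    label: str,
    donor: str,
    anomer: str,
    position: int,
    acceptor_code: str,
    product_code: str,
    constraint_code: str = "",
    candidate_genes: Sequence[str] = (),
) -> LinkageRule:
    acceptor = parse_pattern(acceptor_code)
    product = parse_pattern(product_code)
    anchor = _derive_acceptor_anchor(acceptor, product, donor, anomer, position)
    acceptor = acceptor.with_anchor(anchor)
    constraint = None
    if constraint_code.strip():
        constraint = parse_pattern(constraint_code)
        constraint = constraint.with_anchor(
            _derive_constraint_anchor(acceptor, constraint)
        )
    return LinkageRule(
        id=rule_id,
        label=label,
        donor=donor,
        anomer=anomer,
        position=position,
        acceptor=acceptor,
        constraint=constraint,
        product_code=_pattern_code(product.root),
        candidate_genes=tuple(candidate_genes),
    )


def load_rules(path=None) -> list[LinkageRule]:
    """Load linkage rules from a TSV (default: the packaged 10-rule table).

    Columns: id, label, donor, anomer, position, acceptor, constraint,
    product, candidate_genes (comma-separated).
    """
    if path is None:
        src = resources.files("hmoflux.data").joinpath("rules.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        rules.append(
            make_rule(
                row["id"].strip(),
                row["label"].strip(),
                row["donor"].strip(),
                row["anomer"].strip(),
                int(row["position"]),
                row["acceptor"].strip(),
                row["product"].strip(),
                row.get("constraint", "").strip(),
                tuple(g.strip() for g in row["candidate_genes"].split(",") if g.strip()),
            )
        )
    ids = [r.id for r in rules]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rule ids in rules table")
    return rules


def apply_rule(rule: LinkageRule, g: Glycan) -> list[tuple[Glycan, tuple[int, ...]]]:
    """All distinct products of applying ``rule`` to ``g``.

    Returns ``(product, site_path)`` pairs, one per attachment site from
    pattern matching; a site whose linkage position is already occupied is
    skipped, and duplicate products (same canonical code) are merged keeping
    the first site in canonical order.
    """
    out: list[tuple[Glycan, tuple[int, ...]]] = []
    seen: set[str] = set()
    for site in match_sites(g, rule.acceptor, rule.constraint):
        if site.child_at(rule.position) is not None:
            continue
        path = g.node_path(site)
        root = g.root.copy()
        cur = root
        for p in path:
            cur = cur.child_at(p)
        cur.children.append(GlycanNode(rule.donor, rule.anomer, rule.position))
        prod = Glycan(root)
        if prod.code not in seen:
            seen.add(prod.code)
            out.append((prod, path))
    return out
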