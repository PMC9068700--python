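"""Rooted-tree glycans and the compact linear code used to write them.

Free oligosaccharides of milk are built from five monosaccharides —
glucose (``G``), galactose (``A``), N-acetylglucosamine (``GN``),
fucose (``F``) and N-acetylneuraminic acid (``NN``) — attached through
anomer/position-labelled glycosidic bonds.  A glycan is a rooted tree:
the reducing-end glucose of the lactose core is the root, and every
other residue points to its parent through a linkage such as ``b4``
(beta 1→4) or ``a3`` (alpha 2→3 for sialic acid; the code only records
the anomer letter and the acceptor position).

The linear code writes the tree from the non-reducing end (left) to the
reducing end (right): ``Fa2Ab4G`` is 2'-fucosyllactose, and
parenthesised segments are branches of the residue they precede, e.g.
``Ab3(Fa4)GNb3Ab4G`` (LNFP II).  Patterns used by reaction rules extend
the grammar with

* a leading unmatched ``(`` marking the following residue as *terminal*
  (it must have no children when matched),
* ``[X/Y]`` (or bare ``X/Y``) meaning "either residue", and
* ``~`` marking a pattern as a negated constraint.

Canonical serialisation: among a node's children the backbone is
continued by the first child under the ordering (backbone sugars
A/GN/G before decorations F/NN, then ascending position, anomer,
subtree code); the remaining children are parenthesised in that same
order.  This reproduces the conventional printed forms, e.g.
``GNb3(GNb6)Ab4G`` and ``Ab4(Fa3)G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "MONOSACCHARIDES",
    "ANOMERS",
    "POSITIONS",
    "BACKBONE_RESIDUES",
    "GlycanNode",
    "Glycan",
    "PatternNode",
    "GlycanPattern",
    "GlycanParseError",
    "parse_glycan",
    "parse_pattern",
    "canonical_code",
    "match_sites",
    "embed_pattern_in_pattern",
]

#: Closed residue alphabet (symbol -> common name).
MONOSACCHARIDES = {
    "G": "Glc",
    "A": "Gal",
    "GN": "GlcNAc",
    "F": "Fuc",
    "NN": "Neu5Ac",
}

ANOMERS = frozenset("ab")
POSITIONS = frozenset({2, 3, 4, 6})

#: Residues that can themselves be extended; they continue the printed
#: backbone in preference to the terminal decorations F / NN.
BACKBONE_RESIDUES = frozenset({"G", "A", "GN"})


class GlycanParseError(ValueError):
    """Raised for malformed linear-code strings; carries the offending text."""

    def __init__(self, message: str, fragment: str = ""):
        self.fragment = fragment
        super().__init__(f"{message}" + (f" (at {fragment!r})" if fragment else ""))


@dataclass(eq=False)
class GlycanNode:
    """One residue in a glycan tree.

    ``anomer``/``position`` describe the linkage to the parent and are
    ``None`` for the root (reducing end).
    """

    symbol: str
    anomer: Optional[str] = None
    position: Optional[int] = None
    children: list["GlycanNode"] = field(default_factory=list)

    def child_at(self, position: int) -> Optional["GlycanNode"]:
        for c in self.children:
            if c.position == position:
                return c
        return None

    def copy(self) -> "GlycanNode":
        return GlycanNode(
            self.symbol, self.anomer, self.position, [c.copy() for c in self.children]
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanNode({canonical_code(self)})"


def _child_sort_key(node: GlycanNode):
    return (
        0 if node.symbol in BACKBONE_RESIDUES else 1,
        node.position,
        node.anomer,
        canonical_code(node),
    )


def canonical_code(node: GlycanNode) -> str:
    """Serialise the subtree rooted at ``node`` (linkage of ``node`` excluded)."""
    if not node.children:
        return node.symbol
    kids = sorted(node.children, key=_child_sort_key)
    backbone, branches = kids[0], kids[1:]
    parts = [canonical_code(backbone), backbone.anomer, str(backbone.position)]
    for b in branches:
        parts.append(f"({canonical_code(b)}{b.anomer}{b.position})")
    parts.append(node.symbol)
    return "".join(parts)


class Glycan:
    """Immutable rooted glycan; equality and hashing by canonical code."""

    __slots__ = ("root", "code")

    def __init__(self, root: GlycanNode):
        self.root = root
        self.code = canonical_code(root)

    @property
    def size(self) -> int:
        return sum(1 for _ in self.nodes())

    def nodes(self) -> Iterator[GlycanNode]:
        """Depth-first traversal in canonical child order, root first."""
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(sorted(n.children, key=_child_sort_key)))

    def node_path(self, node: GlycanNode) -> tuple[int, ...]:
        """Positions along the unique root-to-node path ('' for the root)."""

        def walk(cur: GlycanNode, path: tuple[int, ...]):
            if cur is node:
                return path
            for c in cur.children:
                got = walk(c, path + (c.position,))
                if got is not None:
                    return got
            return None

        got = walk(self.root, ())
        if got is None:
            raise ValueError("node not part of this glycan")
        return got

    def node_at(self, path: Sequence[int]) -> GlycanNode:
        cur = self.root
        for p in path:
            nxt = cur.child_at(p)
            if nxt is None:
                raise ValueError(f"no child at position {p}")
            cur = nxt
        return cur

    def composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for n in self.nodes():
            comp[n.symbol] = comp.get(n.symbol, 0) + 1
        return comp

    def contains_linkage(self, symbol: str, anomer: str, position: int) -> bool:
        return any(
            n.symbol == symbol and n.anomer == anomer and n.position == position
            for n in self.nodes()
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, Glycan) and self.code == other.code

    def __hash__(self) -> int:
        return hash(self.code)

    def __repr__(self) -> str:
        return f"Glycan({self.code!r})"


# ---------------------------------------------------------------------------
# tokenizer / parser
# ---------------------------------------------------------------------------

_SYMBOLS = ("GN", "NN", "G", "A", "F")  # two-letter symbols first (greedy)


def _tokenize(code: str, allow_pattern: bool):
    """Yield (kind, value, pos) tokens.

    kinds: 'lpar', 'rpar', 'term' (unmatched '(' terminal marker),
    'residue' (frozenset of symbols), 'linkage' ((anomer, position)).
    """
    # classify parentheses: unmatched '(' are terminal markers (pattern mode)
    stack: list[int] = []
    paired: set[int] = set()
    for i, ch in enumerate(code):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise GlycanParseError("unbalanced ')'", code[max(0, i - 3) : i + 1])
            paired.add(stack.pop())
            paired.add(i)
    unmatched = set(stack)
    if unmatched and not allow_pattern:
        j = min(unmatched)
        raise GlycanParseError("unbalanced '('", code[j : j + 4])

    tokens = []
    i = 0
    n = len(code)
    while i < n:
        ch = code[i]
        if ch == "(":
            tokens.append(("lpar", None, i) if i in paired else ("term", None, i))
            i += 1
        elif ch == ")":
            tokens.append(("rpar", None, i))
            i += 1
        elif ch == "[":
            if not allow_pattern:
                raise GlycanParseError("'[' only allowed in patterns", code[i : i + 6])
            j = code.find("]", i)
            if j < 0:
                raise GlycanParseError("unterminated '['", code[i : i + 6])
            syms = frozenset(code[i + 1 : j].split("/"))
            bad = syms - set(MONOSACCHARIDES)
            if bad:
                raise GlycanParseError("unknown residue symbol", code[i : j + 1])
            tokens.append(("residue", syms, i))
            i = j + 1
        elif ch in "ab" and i + 1 < n and code[i + 1].isdigit():
            pos = int(code[i + 1])
            if pos not in POSITIONS:
                raise GlycanParseError("invalid linkage position", code[i : i + 2])
            tokens.append(("linkage", (ch, pos), i))
            i += 2
        else:
            for sym in _SYMBOLS:
                if code.startswith(sym, i):
                    syms = {sym}
                    i += len(sym)
                    # bare alternative form "G/GN"
                    while allow_pattern and i < n and code[i] == "/":
                        i += 1
                        for sym2 in _SYMBOLS:
                            if code.startswith(sym2, i):
                                syms.add(sym2)
                                i += len(sym2)
                                break
                        else:
                            raise GlycanParseError(
                                "unknown residue symbol", code[i : i + 3]
                            )
                    tokens.append(("residue", frozenset(syms), i))
                    break
            else:
                raise GlycanParseError("unknown residue symbol", code[i : i + 3])
    return tokens


@dataclass(eq=False)
class PatternNode:
    """Residue of a pattern: a set of allowed symbols, optional terminal flag."""

    symbols: frozenset
    anomer: Optional[str] = None
    position: Optional[int] = None
    children: list["PatternNode"] = field(default_factory=list)
    terminal: bool = False

    def child_at(self, position: int) -> Optional["PatternNode"]:
        for c in self.children:
            if c.position == position:
                return c
        return None

    def nodes(self) -> Iterator["PatternNode"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)


def _pattern_code(node: PatternNode) -> str:
    sym = "/".join(sorted(node.symbols))
    if not node.children:
        return sym
    kids = sorted(node.children, key=lambda c: (c.position, c.anomer, _pattern_code(c)))
    parts = [_pattern_code(kids[0]), kids[0].anomer, str(kids[0].position)]
    for b in kids[1:]:
        parts.append(f"({_pattern_code(b)}{b.anomer}{b.position})")
    parts.append(sym)
    return "".join(parts)


class GlycanPattern:
    """A subtree pattern with an *anchor* residue (attachment site).

    The anchor defaults to the pattern root; reaction rules override it
    (derived from the acceptor/product difference).
    """

    def __init__(self, root: PatternNode, code: str, anchor: Optional[PatternNode] = None,
                 negated: bool = False):
        self.root = root
        self.code = code
        self.anchor = anchor if anchor is not None else root
        self.negated = negated
        if not any(n is self.anchor for n in root.nodes()):
            raise ValueError("anchor is not a residue of the pattern")

    def anchor_path(self) -> tuple[int, ...]:
        def walk(cur: PatternNode, path):
            if cur is self.anchor:
                return path
            for c in cur.children:
                got = walk(c, path + (c.position,))
                if got is not None:
                    return got
            return None

        return walk(self.root, ())

    def with_anchor(self, anchor: PatternNode) -> "GlycanPattern":
        return GlycanPattern(self.root, self.code, anchor, self.negated)

    def __repr__(self) -> str:
        return f"GlycanPattern({self.code!r})"


def _parse_tokens(tokens, i, pattern: bool, code: str):
    """Parse one chain; returns (root_node, root_linkage_or_None, next_index)."""
    make = PatternNode if pattern else GlycanNode
    pending = []  # (node, (anomer, pos)) awaiting a parent
    terminal_next = False
    while i < len(tokens):
        kind, val, pos = tokens[i]
        if kind == "rpar":
            break
        if kind == "term":
            terminal_next = True
            i += 1
            continue
        if kind == "lpar":
            node, link, i = _parse_tokens(tokens, i + 1, pattern, code)
            if i >= len(tokens) or tokens[i][0] != "rpar":
                raise GlycanParseError("unbalanced '('", code)
            i += 1
            if link is None:
                raise GlycanParseError("branch lacks a linkage", code[: tokens[i - 1][2]])
            pending.append((node, link))
            continue
        if kind == "linkage":
            raise GlycanParseError("linkage without residue", code[pos : pos + 2])
        # residue
        syms = val
        if not pattern:
            (sym,) = syms
            node = make(sym)
        else:
            node = make(frozenset(syms))
            node.terminal = terminal_next
        terminal_next = False
        seen_positions = set()
        for child, (anomer, cpos) in pending:
            if cpos in seen_positions or any(c.position == cpos for c in node.children):
                raise GlycanParseError("duplicate position on one residue",
                                       code[: pos + 2])
            seen_positions.add(cpos)
            child.anomer, child.position = anomer, cpos
            node.children.append(child)
        pending = []
        i += 1
        if i < len(tokens) and tokens[i][0] == "linkage":
            link = tokens[i][1]
            i += 1
            pending = [(node, link)]
        else:
            return node, None, i
    # chain ended at ')' or EOF with a pending linked node (branch case)
    if len(pending) == 1:
        node, link = pending[0]
        return node, link, i
    raise GlycanParseError("chain must end in a residue", code)


def parse_glycan(code: str) -> Glycan:
    """Parse a plain linear-code string into a :class:`Glycan`."""
    if not code:
        raise GlycanParseError("empty code")
    tokens = _tokenize(code, allow_pattern=False)
    root, link, i = _parse_tokens(tokens, 0, pattern=False, code=code)
    if link is not None or i != len(tokens):
        raise GlycanParseError("trailing input after root residue", code)
    return Glycan(root)


def parse_pattern(code: str) -> GlycanPattern:
    """Parse a pattern (extended grammar); a leading ``~`` marks negation."""
    raw = code.strip()
    negated = False
    body = raw
    if body.startswith("~") or body.startswith("∼"):
        negated = True
        body = body[1:]
    if body.startswith("{") and body.endswith("}"):
        body = body[1:-1]
        if body.startswith("~") or body.startswith("∼"):
            negated = True
            body = body[1:]
    if not body:
        raise GlycanParseError("empty pattern")
    tokens = _tokenize(body, allow_pattern=True)
    root, link, i = _parse_tokens(tokens, 0, pattern=True, code=body)
    if link is not None or i != len(tokens):
        raise GlycanParseError("trailing input after root residue", body)
    return GlycanPattern(root, body, negated=negated)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _match_at(pnode: PatternNode, gnode: GlycanNode) -> bool:
    if gnode.symbol not in pnode.symbols:
        return False
    if pnode.terminal and gnode.children:
        return False
    for pc in pnode.children:
        gc = gnode.child_at(pc.position)
        if gc is None or gc.anomer != pc.anomer or not _match_at(pc, gc):
            return False
    return True


def _anchor_images(g: Glycan, pattern: GlycanPattern) -> list[GlycanNode]:
    path = pattern.anchor_path()
    images = []
    for gnode in g.nodes():
        if _match_at(pattern.root, gnode):
            cur = gnode
            for p in path:
                cur = cur.child_at(p)
            images.append(cur)
    # dedup (a node could be the anchor image of several root placements)
    seen: list[GlycanNode] = []
    for n in images:
        if not any(n is s for s in seen):
            seen.append(n)
    return seen


def match_sites(
    g: Glycan,
    pattern: GlycanPattern,
    constraint: Optional[GlycanPattern] = None,
) -> list[GlycanNode]:
    """All nodes of ``g`` where the pattern anchor maps under subtree matching.

    The constraint pattern, when given, is interpreted as negated: a site is
    dropped whenever the constraint matches with its anchor at that site.
    Sites are returned in canonical depth-first order.
    """
    sites = _anchor_images(g, pattern)
    if constraint is not None:
        bad = _anchor_images(g, constraint)
        sites = [s for s in sites if not any(s is b for b in bad)]
    order = {id(n): i for i, n in enumerate(g.nodes())}
    return sorted(sites, key=lambda n: order[id(n)])


def embed_pattern_in_pattern(
    inner: GlycanPattern, outer: GlycanPattern
) -> list[PatternNode]:
    """Images of ``inner``'s anchor under embeddings of ``inner`` in ``outer``.

    Terminal flags on ``inner`` are ignored (the outer pattern may extend a
    residue the inner pattern considers terminal); used to locate a rule's
    attachment site inside its constraint pattern.
    """

    def ok(pn: PatternNode, hn: PatternNode) -> bool:
        if not (pn.symbols & hn.symbols):
            return False
        for pc in pn.children:
            hc = hn.child_at(pc.position)
            if hc is None or hc.anomer != pc.anomer or not ok(pc, hc):
                return False
        return True

    path = inner.anchor_path()
    images = []
    for hnode in outer.root.nodes():
        if ok(inner.root, hnode):
            cur = hnode
            for p in path:
                cur = cur.child_at(p)
            if not any(cur is s for s in images):
                images.append(cur)
    return images
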