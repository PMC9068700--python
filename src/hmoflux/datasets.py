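"""Packaged data: measured-HMO structure fixture and helpers.

Sixteen HMOs are measured by HPLC; eleven have fully determined structures
and five (DFLNT, FLNH, DFLNH, DSLNH, FDSLNH) are peaks with several
candidate isomers.  The fixture ``data/hmo_structures.tsv`` lists one row
per structure; candidate isomers of an ambiguous HMO carry a numeric
suffix (``DFLNT1`` ... ``DFLNT6``).  The candidate sets enumerate the
rule-reachable decorations of the backbone implied by the peak name
(LNT/LNnT tetraose cores for DFLNT, the lacto-N-hexaose core for the
hexaose family); the file is a plain TSV and is meant to be editable as
structure assignments improve.
"""

from __future__ import annotations

import re
from importlib import resources

from .glycans import Glycan, parse_glycan

__all__ = ["load_hmo_structures", "observed_names", "requires_a2_fucose", "HMO_ORDER"]

#: canonical display order of the 16 measured HMOs
HMO_ORDER = [
    "2'FL", "3FL", "3'SL", "LNT", "LNnT", "LNFPI", "LNFPII", "LNFPIII",
    "LSTb", "LSTc", "DFLNT", "DSLNT", "FLNH", "DFLNH", "FDSLNH", "DSLNH",
]

_SUFFIX = re.compile(r"^(.*?)(\d+)$")


def _strip_isomer_suffix(name: str) -> str:
    m = _SUFFIX.match(name)
    return m.group(1) if m else name


def load_hmo_structures(path=None) -> dict[str, list[Glycan]]:
    """HMO name -> candidate structures (isomer suffixes pooled per name)."""
    if path is None:
        text = resources.files("hmoflux.data").joinpath("hmo_structures.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out: dict[str, list[Glycan]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        name, code = ln.split("\t")
        out.setdefault(_strip_isomer_suffix(name), []).append(parse_glycan(code))
    return out


def observed_names(structures: dict[str, list[Glycan]] | None = None) -> list[str]:
    structures = structures if structures is not None else load_hmo_structures()
    return [n for n in HMO_ORDER if n in structures] + sorted(
        set(structures) - set(HMO_ORDER)
    )


def requires_a2_fucose(name: str, structures: dict[str, list[Glycan]] | None = None) -> bool:
    """True when *every* candidate structure carries an alpha-1,2 fucose.

    Such HMOs (2'FL, LNFPI) are near-absent in milk of non-secretor mothers,
    who lack functional FUT2.
    """
    structures = structures if structures is not None else load_hmo_structures()
    return all(g.contains_linkage("F", "a", 2) for g in structures[name])
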