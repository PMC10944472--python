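"""IUPAC degenerate-base utilities shared across the design modules."""

from __future__ import annotations

import re

from Bio.Seq import Seq

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Degenerate codes allowed in mixed-base synthesis designs.
MIXED_CODES = {"K": ("G", "T"), "M": ("A", "C")}


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a regex over plain ACGT text."""
    parts = []
    for ch in motif.upper():
        bases = IUPAC_SETS.get(ch)
        if bases is None:
            raise ValueError(f"illegal IUPAC character {ch!r} in motif {motif!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def scan_motif(sequence: str, motif: str, both_strands: bool = True) -> int:
    """Number of IUPAC matches of ``motif`` in ``sequence`` (overlapping).

    TFBSs are double-stranded entities, so by default the reverse
    complement strand is scanned too.
    """
    pat = iupac_regex(motif)
    n = _count_overlapping(pat, sequence.upper())
    if both_strands:
        n += _count_overlapping(pat, revcomp(sequence.upper()))
    return n


def _count_overlapping(pat: re.Pattern, text: str) -> int:
    count, pos = 0, 0
    while True:
        m = pat.search(text, pos)
        if m is None:
            return count
        count += 1
        pos = m.start() + 1


def matches_with_mixed(read_region: str, design_region: str) -> bool:
    """Exact match outside mixed positions; K/M positions accept their pair."""
    if len(read_region) != len(design_region):
        return False
    for r, d in zip(read_region, design_region):
        if d in MIXED_CODES:
            if r not in MIXED_CODES[d]:
                return False
        elif r != d:
            return False
    return True
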