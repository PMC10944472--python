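"""Synthetic stand-in motif catalogs.

The original 41-motif catalog is distributed as supplementary material and
is not bundled here; :func:`example_catalog` builds a synthetic catalog with
the same composition — 41 motifs of length 10-13, of which 20 carry 1-4
K/M mixed bases (so 2-16 sub-motifs each) and 21 are plain — seeded and
deterministic.  The handful of motif sequences that are public (printed in
the study's text) are included verbatim; the remainder are synthetic.
"""

from __future__ import annotations

import numpy as np

from .motif_catalog import MixedBaseMotif, MotifCatalog

__all__ = ["example_catalog", "PUBLISHED_MOTIFS"]

#: Motif sequences printed in the study's text, with their reported roles.
PUBLISHED_MOTIFS: list[tuple[str, str, str, str]] = [
    # (motif_id, sequence, organism, known_function)
    ("Rap1", "AMACCCACACMCC", "S. cerevisiae", "dual"),
    ("Zic3", "CCCCCCGCTG", "mouse", "activating"),
    ("CTCF", "ACGCCCCCTA", "mouse", "repressing"),
    ("Stp", "CGGCGCTAGC", "S. cerevisiae", "activating"),
    ("unk_GAGGCGCAGC", "GAGGCGCAGC", "S. cerevisiae", "unknown"),
    ("unk_GCTGCGCCAC", "GCTGCGCCAC", "S. cerevisiae", "unknown"),
]

_ORGANISMS = ("S. cerevisiae", "S. pombe", "D. melanogaster", "mouse")


def example_catalog(
    n_motifs: int = 41,
    n_mixed: int = 20,
    seed: int = 2024,
) -> MotifCatalog:
    """Deterministic synthetic catalog of ``n_motifs`` mixed/plain motifs.

    Defaults reproduce the reference composition: 41 motifs, 20 mixed-base
    (1-4 K/M positions) and 21 plain, lengths 10-13, function annotations
    split across activating/repressing/dual/unknown.
    """
    if n_mixed > n_motifs:
        raise ValueError("n_mixed cannot exceed n_motifs")
    rng = np.random.default_rng(seed)
    motifs: list[MixedBaseMotif] = []
    seen: set[str] = set()
    for mid, seq, org, fn in PUBLISHED_MOTIFS[:n_motifs]:
        motifs.append(MixedBaseMotif(mid, seq, fn, org))
        seen.add(seq)
    # published set contributes 1 mixed (Rap1) and 5 plain motifs
    made_mixed = sum(1 for m in motifs if m.is_mixed)
    functions = ["activating", "repressing", "dual", "unknown"]
    i = 0
    while len(motifs) < n_motifs:
        i += 1
        length = int(rng.integers(10, 14))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if made_mixed < n_mixed:
            k = int(rng.integers(1, 5))
            pos = rng.choice(length, size=k, replace=False)
            seq = list(seq)
            for p in pos:
                seq[p] = rng.choice(["K", "M"])
            seq = "".join(seq)
        if seq in seen:
            continue
        seen.add(seq)
        if made_mixed < n_mixed:
            made_mixed += 1
        fn = functions[int(rng.integers(0, 4))]
        org = _ORGANISMS[int(rng.integers(0, 4))]
        motifs.append(MixedBaseMotif(f"syn{i:02d}", seq, fn, org))
    return MotifCatalog(motifs=motifs)
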