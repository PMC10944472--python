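import numpy as np
import pytest

from unilib.library_designer import (
    allocate_barcodes,
    design_desert,
    enumerate_variants,
    generate_barcodes,
)
from unilib.motif_catalog import MixedBaseMotif, MotifCatalog

PLAIN_SEQS = [
    "GCTGCGCCAC",
    "ACGCCCCCTA",
    "CGGCGCTAGC",
    "GAGGCGCAGC",
    "CCCCCCGCTG",
    "TTGACGTCAT",
]


@pytest.fixture(scope="session")
def small_catalog():
    """Six plain motifs: enough for arity-3 enumeration (259 variants)."""
    return MotifCatalog(
        [MixedBaseMotif(f"m{i}", s) for i, s in enumerate(PLAIN_SEQS)]
    )


@pytest.fixture(scope="session")
def mixed_catalog():
    """Four motifs, two carrying K/M mixed bases."""
    return MotifCatalog(
        [
            MixedBaseMotif("mx1", "AMACCCACACMCC", "dual"),
            MixedBaseMotif("mx2", "GCKGCGCCAC", "unknown"),
            MixedBaseMotif("p1", "ACGCCCCCTA", "repressing"),
            MixedBaseMotif("p2", "GAGGCGCAGC", "unknown"),
        ]
    )


@pytest.fixture(scope="session")
def chassis(small_catalog):
    return design_desert(
        101, [m.sequence for m in small_catalog], seed=11
    )


@pytest.fixture(scope="session")
def small_manifest(small_catalog, chassis):
    """Arity-2 manifest (43 variants x 2 barcodes) used across modules."""
    variants = enumerate_variants(small_catalog, max_arity=2, chassis=chassis)
    barcodes = generate_barcodes(2 * len(variants), seed=13)
    return allocate_barcodes(variants, barcodes, n_default=2, n_deep=2,
                             deep_count=0, seed=17, chassis=chassis)


@pytest.fixture(scope="session")
def mixed_manifest(mixed_catalog):
    chassis = design_desert(101, [], seed=19)
    variants = enumerate_variants(mixed_catalog, max_arity=2, chassis=chassis)
    barcodes = generate_barcodes(2 * len(variants), seed=23)
    return allocate_barcodes(variants, barcodes, n_default=2, n_deep=2,
                             deep_count=0, seed=29, chassis=chassis)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
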