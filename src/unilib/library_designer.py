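"""Design of motif-based sURS oligo libraries.

The library is built around a neutral "desert" chassis: a synthetic
sequence scrubbed of all known TF binding sites, into which 0-3 catalog
motifs are embedded at fixed positions.  Each variant is tagged with one or
more 15 nt barcodes under synthesis-grade constraints (pairwise edit
distance >= 3, GC 35-65%, homopolymer runs <= 3), flanked with restriction
sites and amplification primers, and written out as a design manifest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._edit import levenshtein
from .iupac import iupac_regex, revcomp, scan_motif
from .motif_catalog import DESERT_MOTIF_ID, MotifCatalog

__all__ = [
    "DesertChassis",
    "OligoVariant",
    "BarcodeSet",
    "FlankConfig",
    "DesignManifest",
    "MOTIF_STARTS",
    "filter_exclusion_database",
    "design_desert",
    "enumerate_variants",
    "generate_barcodes",
    "allocate_barcodes",
    "assemble_oligo",
    "load_manifest",
]

#: 1-based motif start positions in the 101 nt variable region, per arity.
MOTIF_STARTS: dict[int, tuple[int, ...]] = {
    0: (),
    1: (46,),
    2: (28, 66),
    3: (18, 46, 74),
}

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DesertChassis:
    sequence: str
    exclusion_list_id: str = ""
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OligoVariant:
    variant_id: str
    motif_ids: tuple[str, ...]
    starts: tuple[int, ...]  # 1-based starts within the variable region
    variable_region: str

    @property
    def arity(self) -> int:
        return len(self.motif_ids)


@dataclass(frozen=True)
class BarcodeSet:
    barcodes: tuple[str, ...]
    min_pairwise_edit: int = 3
    gc_bounds: tuple[float, float] = (0.35, 0.65)
    max_homopolymer: int = 3
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class FlankConfig:
    """Constant oligo parts: amplification primers and cloning sites."""

    primer_5: str = "CTTGCATACGAGCTCGCACTACGTA"
    primer_3: str = "TCGACGTCTAGCATGCTAGTCGAGC"
    spe1: str = "ACTAGT"
    eag1: str = "CGGCCG"


@dataclass
class DesignManifest:
    table: pd.DataFrame  # oligo_id, variant_id, barcode, motif_ids, starts, variable_region, full_sequence
    flanks: FlankConfig = field(default_factory=FlankConfig)
    chassis: DesertChassis | None = None

    def __post_init__(self):
        if self.table["oligo_id"].duplicated().any():
            raise ValueError("duplicate oligo_ids in manifest")
        if self.table["barcode"].duplicated().any():
            raise ValueError("barcode must uniquely identify an oligo")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_variants(self) -> int:
        return self.table["variant_id"].nunique()

    def barcode_to_variant(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["variant_id"]))

    def variant_regions(self) -> dict[str, str]:
        sub = self.table.drop_duplicates("variant_id")
        return dict(zip(sub["variant_id"], sub["variable_region"]))

    def variant_motifs(self) -> dict[str, tuple[str, ...]]:
        sub = self.table.drop_duplicates("variant_id")
        return {
            v: tuple(m.split(",")) if m else ()
            for v, m in zip(sub["variant_id"], sub["motif_ids"])
        }

    def deep_variants(self) -> list[str]:
        """Variant ids in the deeply-barcoded subset."""
        if "deep" in self.table.columns:
            mask = self.table["deep"].astype(str).str.lower().isin(["true", "1"])
            return sorted(self.table.loc[mask, "variant_id"].unique())
        counts = self.table.groupby("variant_id")["barcode"].count()
        default = counts.mode().iat[0]
        return sorted(counts.index[counts > default])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path, flanks: FlankConfig | None = None) -> DesignManifest:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return DesignManifest(table=table, flanks=flanks or FlankConfig())


# ---------------------------------------------------------------------------
# exclusion database filtering and desert design
# ---------------------------------------------------------------------------

def filter_exclusion_database(iupac_motifs: list[str]) -> list[str]:
    """Reduce a consensus-TFBS exclusion list to scannable motifs.

    Drops motifs shorter than 5 nt, motifs that are entirely lower-case
    (low-frequency consensus calls), and motifs with 5 or fewer upper-case
    characters regardless of length.  Retained motifs are returned
    upper-cased with their lower-case positions degraded to N wildcards.
    """
    out = []
    for motif in iupac_motifs:
        if len(motif) < 5:
            continue
        n_upper = sum(ch.isupper() for ch in motif)
        if n_upper == 0 or n_upper <= 5:
            continue
        out.append("".join(ch if ch.isupper() else "N" for ch in motif))
    return out


def count_exclusion_hits(sequence: str, exclusion: list[str]) -> dict[str, int]:
    """IUPAC hits of each exclusion motif on both strands of ``sequence``."""
    return {m: scan_motif(sequence, m, both_strands=True) for m in exclusion}


def design_desert(
    length: int = 101,
    exclusion: list[str] | None = None,
    seed: int = 0,
    max_attempts: int = 2000,
    forbidden_sites: tuple[str, ...] = ("ACTAGT", "CGGCCG"),
) -> DesertChassis:
    """Generate a binding-site desert of ``length`` bases.

    Seeded rejection sampling with local repair: starting from a uniform
    random sequence, every exclusion-motif hit (either strand) is destroyed
    by resampling the bases under its footprint, until an independent scan
    of both strands finds zero hits.  The cloning restriction sites are
    excluded alongside the TFBS list so the chassis is always clonable.
    """
    exclusion = list(exclusion or []) + [
        s for s in forbidden_sites if s not in (exclusion or [])]
    if exclusion and length < max(len(m) for m in exclusion):
        raise ValueError("desert shorter than the longest exclusion motif")
    rng = np.random.default_rng(seed)
    patterns = [iupac_regex(m) for m in exclusion]
    seq = rng.choice(BASES, size=length)
    for _ in range(max_attempts):
        text = "".join(seq)
        rc = revcomp(text)
        hit = None
        for pat in patterns:
            m = pat.search(text)
            if m is not None:
                hit = (m.start(), m.end())
                break
            m = pat.search(rc)
            if m is not None:
                hit = (length - m.end(), length - m.start())
                break
        if hit is None:
            return DesertChassis(
                sequence=text,
                exclusion_list_id=f"{len(exclusion)} motifs",
                rng_seed=seed,
            )
        lo, hi = hit
        seq[lo:hi] = rng.choice(BASES, size=hi - lo)
    blocking = [m for m, n in count_exclusion_hits("".join(seq), exclusion).items() if n]
    raise RuntimeError(
        f"desert design failed after {max_attempts} attempts; "
        f"blocking motifs: {blocking[:10]}"
    )


# ---------------------------------------------------------------------------
# variant enumeration
# ---------------------------------------------------------------------------

def embed_motifs(
    chassis: str,
    motif_seqs: list[str],
    starts: tuple[int, ...],
) -> str:
    """Overwrite chassis bases with motif sequences at 1-based ``starts``."""
    region = list(chassis)
    prev_end = 0
    for seq, start in zip(motif_seqs, starts):
        i = start - 1
        if i < prev_end:
            raise ValueError(
                f"motif placement overlap: start {start} inside previous footprint"
            )
        if i + len(seq) > len(region):
            raise ValueError(
                f"motif of length {len(seq)} at start {start} exceeds the "
                f"{len(region)} nt variable region"
            )
        region[i:i + len(seq)] = list(seq)
        prev_end = i + len(seq)
    return "".join(region)


def enumerate_variants(
    catalog: MotifCatalog,
    max_arity: int = 3,
    chassis: DesertChassis | None = None,
    starts: dict[int, tuple[int, ...]] | None = None,
) -> list[OligoVariant]:
    """All ordered 0..max_arity motif arrangements with repetition.

    The count is the closed form sum over k of m**k for an m-motif catalog;
    the empty arrangement is the desert variant.  When a chassis is given,
    each arrangement is embedded at the fixed per-arity positions.
    """
    if max_arity < 0:
        raise ValueError("max_arity must be >= 0")
    starts = starts or MOTIF_STARTS
    seqs = {m.motif_id: m.sequence for m in catalog}
    chassis_seq = chassis.sequence if chassis is not None else None
    variants = []
    for arity in range(max_arity + 1):
        if arity not in starts:
            raise ValueError(f"no fixed motif positions configured for arity {arity}")
        pos = starts[arity]
        for combo in itertools.product(catalog.motif_ids, repeat=arity):
            if chassis_seq is None:
                region = ""
            else:
                region = embed_motifs(chassis_seq, [seqs[m] for m in combo], pos)
            vid = DESERT_MOTIF_ID if arity == 0 else "v_" + "+".join(combo)
            variants.append(
                OligoVariant(
                    variant_id=vid,
                    motif_ids=combo,
                    starts=pos,
                    variable_region=region,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def generate_barcodes(
    n: int,
    length: int = 15,
    min_edit: int = 3,
    gc_bounds: tuple[float, float] = (0.35, 0.65),
    max_run: int = 3,
    seed: int = 0,
    forbidden: tuple[str, ...] = ("ACTAGT", "CGGCCG"),
    max_attempts_per_barcode: int = 2000,
) -> BarcodeSet:
    """Greedy seeded rejection sampling of a constrained barcode code.

    Every accepted barcode satisfies the GC and homopolymer bounds, avoids
    the cloning restriction sites, and sits at Levenshtein distance
    >= ``min_edit`` from every previously accepted barcode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    budget = n * max_attempts_per_barcode
    while len(accepted) < n and budget > 0:
        budget -= 1
        cand = "".join(rng.choice(BASES, size=length))
        lo, hi = gc_bounds
        if not lo <= _gc_fraction(cand) <= hi:
            continue
        if _max_run(cand) > max_run:
            continue
        if any(site in cand for site in forbidden):
            continue
        if any(levenshtein(cand, b) < min_edit for b in accepted):
            continue
        accepted.append(cand)
    if len(accepted) < n:
        raise RuntimeError(
            f"barcode sampling budget exhausted: got {len(accepted)} of {n} "
            f"barcodes of length {length} at min edit distance {min_edit}"
        )
    return BarcodeSet(
        barcodes=tuple(accepted),
        min_pairwise_edit=min_edit,
        gc_bounds=gc_bounds,
        max_homopolymer=max_run,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# oligo assembly and barcode allocation
# ---------------------------------------------------------------------------

def assemble_oligo(
    variant: OligoVariant,
    barcode: str,
    flanks: FlankConfig | None = None,
) -> str:
    """5'primer + SpeI + barcode + variable region + EagI + 3'primer."""
    flanks = flanks or FlankConfig()
    if variant.starts != MOTIF_STARTS[variant.arity]:
        raise ValueError(
            f"variant {variant.variant_id}: starts {variant.starts} violate the "
            f"fixed positions {MOTIF_STARTS[variant.arity]} for arity {variant.arity}"
        )
    for part, name in ((barcode, "barcode"), (variant.variable_region, "variable region")):
        for site in (flanks.spe1, flanks.eag1):
            if site in part:
                raise ValueError(
                    f"restriction site {site} occurs inside the {name} of "
                    f"{variant.variant_id}"
                )
    return (
        flanks.primer_5 + flanks.spe1 + barcode
        + variant.variable_region + flanks.eag1 + flanks.primer_3
    )


def allocate_barcodes(
    variants: list[OligoVariant],
    barcodes: BarcodeSet | None = None,
    n_default: int = 2,
    n_deep: int = 22,
    deep_count: int = 2435,
    seed: int = 0,
    flanks: FlankConfig | None = None,
    chassis: DesertChassis | None = None,
) -> DesignManifest:
    """Assign barcodes to variants and assemble the design manifest.

    ``deep_count`` randomly chosen variants receive ``n_deep`` barcodes
    (the deeply-barcoded subset used for enrichment analysis); all others
    receive ``n_default``.
    """
    if deep_count > len(variants):
        raise ValueError("deep_count exceeds the number of variants")
    flanks = flanks or FlankConfig()
    rng = np.random.default_rng(seed)
    deep_idx = set(rng.choice(len(variants), size=deep_count, replace=False).tolist())
    need = n_default * len(variants) + (n_deep - n_default) * deep_count
    if barcodes is None:
        barcodes = generate_barcodes(need, seed=seed + 1)
    if len(barcodes) < need:
        raise ValueError(f"need {need} barcodes, only {len(barcodes)} provided")
    rows = []
    bc_iter = iter(barcodes.barcodes)
    for i, v in enumerate(variants):
        k = n_deep if i in deep_idx else n_default
        for j in range(k):
            bc = next(bc_iter)
            rows.append(
                {
                    "oligo_id": f"{v.variant_id}.bc{j + 1}",
                    "variant_id": v.variant_id,
                    "barcode": bc,
                    "motif_ids": ",".join(v.motif_ids),
                    "starts": ",".join(map(str, v.starts)),
                    "variable_region": v.variable_region,
                    "full_sequence": assemble_oligo(v, bc, flanks),
                    "deep": i in deep_idx,
                }
            )
    return DesignManifest(table=pd.DataFrame(rows), flanks=flanks, chassis=chassis)
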