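"""Demultiplexing and counting of per-bin SORT-seq reads.

Merged reads are assigned in a fixed pipeline: length filter, 5' primer
location, bin identity (per-bin input files, or a bin barcode when the bins
were PCR-barcoded into a single pool), variant barcode matching with a
bounded number of mismatches (undetermined N bases count as mismatches),
and finally strict verification of the variable region against the design
with K/M mixed positions wildcarded.  The first failing stage records the
rejection reason; nothing is silently dropped.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._edit import hamming_matrix
from .iupac import MIXED_CODES, matches_with_mixed
from .library_designer import DesignManifest

__all__ = [
    "DemuxConfig",
    "ReadAssignment",
    "BinReadTable",
    "assign_read",
    "annotate_subvariant",
    "tally",
    "parse_bins",
    "REJECT_REASONS",
]

BINS = (1, 2, 3, 4)
REJECT_REASONS = (
    "too-short",
    "no-primer",
    "no-bin-barcode",
    "no-variant-barcode",
    "body-mismatch",
)


@dataclass
class DemuxConfig:
    forward_primer: str = ""
    bin_barcode_table: dict[int, str] = field(default_factory=dict)
    min_read_length: int = 200
    barcode_max_errors: int = 2
    barcode_length: int = 15
    spe1: str = "ACTAGT"

    def __post_init__(self):
        if self.bin_barcode_table:
            bbs = list(self.bin_barcode_table.values())
            for i in range(len(bbs)):
                for j in range(i + 1, len(bbs)):
                    mismatches = sum(a != b for a, b in zip(bbs[i], bbs[j]))
                    if mismatches <= 2 * self.barcode_max_errors:
                        raise ValueError(
                            "bin barcodes not mutually distinguishable at the "
                            f"configured tolerance ({self.barcode_max_errors} errors)"
                        )


@dataclass(frozen=True)
class ReadAssignment:
    bin_id: int | None
    variant_id: str | None
    reason: str | None = None  # set iff unassigned
    subvariant: str = ""  # concrete bases at K/M design positions, in order

    @property
    def assigned(self) -> bool:
        return self.variant_id is not None


@dataclass
class BinReadTable:
    """Raw integer read counts per variant (and sub-variant) per bin."""

    counts: pd.DataFrame  # index variant_id, columns bin1..bin4
    subvariant_counts: pd.DataFrame  # index (variant_id, subvariant), columns bin1..bin4
    bin_totals: pd.Series

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    subvariant_counts: pd.DataFrame | None = None,
                    bin_totals: pd.Series | None = None) -> "BinReadTable":
        cols = [f"bin{b}" for b in BINS]
        counts = counts.reindex(columns=cols, fill_value=0).astype(int)
        if subvariant_counts is None:
            subvariant_counts = counts.copy()
            subvariant_counts.index = pd.MultiIndex.from_arrays(
                [counts.index, [""] * len(counts)], names=["variant_id", "subvariant"]
            )
        if bin_totals is None:
            bin_totals = counts.sum(axis=0)
        return cls(counts=counts, subvariant_counts=subvariant_counts,
                   bin_totals=bin_totals)

    def to_tsv(self, path: str | Path) -> None:
        self.subvariant_counts.reset_index().to_csv(path, sep="\t", index=False)


class _BarcodeIndex:
    """Vectorized Hamming matching of variant barcodes with N tolerance."""

    def __init__(self, manifest: DesignManifest, max_errors: int):
        self.max_errors = max_errors
        bcs = manifest.table["barcode"].tolist()
        self.barcodes = bcs
        self.exact = {bc: i for i, bc in enumerate(bcs)}
        self.pool = np.frombuffer(
            "".join(bcs).encode(), dtype=np.uint8
        ).reshape(len(bcs), -1)
        self.variant_ids = manifest.table["variant_id"].tolist()

    def match(self, observed: str) -> str | None:
        """Variant id for an observed barcode, or None (no match / ambiguous)."""
        hit = self.exact.get(observed)
        if hit is not None:
            return self.variant_ids[hit]
        if len(observed) != self.pool.shape[1]:
            return None
        d = hamming_matrix(observed, self.pool)
        best = int(d.min())
        if best > self.max_errors:
            return None
        idx = np.flatnonzero(d == best)
        if len(idx) > 1:
            return None  # ambiguous at equal distance -> rejected
        return self.variant_ids[int(idx[0])]


def _locate_primer(read: str, primer: str) -> int:
    """Index just past the 5' primer, or -1."""
    if not primer:
        return 0
    pos = read.find(primer)
    return -1 if pos < 0 else pos + len(primer)


def assign_read(
    read: str,
    manifest: DesignManifest,
    config: DemuxConfig,
    bin_id: int | None = None,
    _index: _BarcodeIndex | None = None,
    _regions: dict[str, str] | None = None,
) -> ReadAssignment:
    """Assign one merged read to a (bin, variant), or categorize the failure."""
    read = read.upper()
    if len(read) < config.min_read_length:
        return ReadAssignment(None, None, "too-short")
    primer = config.forward_primer or manifest.flanks.primer_5
    at = _locate_primer(read, primer)
    if at < 0:
        return ReadAssignment(None, None, "no-primer")
    if bin_id is None:
        if not config.bin_barcode_table:
            return ReadAssignment(None, None, "no-bin-barcode")
        for b, bb in config.bin_barcode_table.items():
            if read.startswith(bb):
                bin_id = b
                break
        else:
            return ReadAssignment(None, None, "no-bin-barcode")
    # layout after the primer: SpeI site, 15 nt variant barcode, variable region
    at += len(config.spe1)
    observed_bc = read[at:at + config.barcode_length]
    index = _index or _BarcodeIndex(manifest, config.barcode_max_errors)
    variant_id = index.match(observed_bc)
    if variant_id is None:
        return ReadAssignment(bin_id, None, "no-variant-barcode")
    regions = _regions if _regions is not None else manifest.variant_regions()
    design = regions[variant_id]
    body = read[at + config.barcode_length:at + config.barcode_length + len(design)]
    if not matches_with_mixed(body, design):
        return ReadAssignment(bin_id, None, "body-mismatch")
    sub = annotate_subvariant(body, design)
    if sub is None:
        return ReadAssignment(bin_id, None, "body-mismatch")
    return ReadAssignment(bin_id, variant_id, None, sub)


def annotate_subvariant(body: str, design_region: str) -> str | None:
    """Concrete bases observed at each K/M design position, in design order.

    Returns None when a mixed position carries a base outside its allowed
    pair (the read then counts as a body mismatch).
    """
    out = []
    for r, d in zip(body, design_region):
        if d in MIXED_CODES:
            if r not in MIXED_CODES[d]:
                return None
            out.append(r)
    return "".join(out)


def tally(assignments: list[ReadAssignment]) -> tuple[BinReadTable, dict[str, int]]:
    """Integer counts per (variant, bin) and (variant, subvariant, bin).

    Also returns the rejection summary; assigned + rejected = total input.
    """
    sub_counter: Counter = Counter()
    rejected: Counter = Counter()
    for a in assignments:
        if a.assigned:
            sub_counter[(a.variant_id, a.subvariant, a.bin_id)] += 1
        else:
            rejected[a.reason] += 1
    cols = [f"bin{b}" for b in BINS]
    if sub_counter:
        rows: dict[tuple[str, str], dict[str, int]] = {}
        for (vid, sub, b), n in sub_counter.items():
            rows.setdefault((vid, sub), {c: 0 for c in cols})[f"bin{b}"] = n
        sub_df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        sub_df.index = pd.MultiIndex.from_tuples(
            sub_df.index, names=["variant_id", "subvariant"]
        )
        sub_df = sub_df.reindex(columns=cols, fill_value=0).sort_index()
        counts = sub_df.groupby(level="variant_id").sum()
    else:
        sub_df = pd.DataFrame(
            columns=cols,
            index=pd.MultiIndex.from_arrays([[], []], names=["variant_id", "subvariant"]),
            dtype=int,
        )
        counts = pd.DataFrame(columns=cols, dtype=int)
        counts.index.name = "variant_id"
    table = BinReadTable.from_counts(counts, sub_df)
    summary = {reason: rejected.get(reason, 0) for reason in REJECT_REASONS}
    summary["assigned"] = sum(n for n in sub_counter.values())
    return table, summary


def parse_bins(
    fastq_by_bin: dict[int, str | Path],
    manifest: DesignManifest,
    config: DemuxConfig | None = None,
) -> tuple[BinReadTable, dict[str, int]]:
    """Parse one FASTQ file per bin and tally counts (simulator-mode demux)."""
    config = config or DemuxConfig()
    index = _BarcodeIndex(manifest, config.barcode_max_errors)
    regions = manifest.variant_regions()
    assignments = []
    for bin_id, path in fastq_by_bin.items():
        for rec in SeqIO.parse(str(path), "fastq"):
            assignments.append(
                assign_read(str(rec.seq), manifest, config, bin_id=bin_id,
                            _index=index, _regions=regions)
            )
    return tally(assignments)


def write_rejection_summary(summary: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
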