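"""Mixed-base TFBS motif catalog.

A motif library for mixed-base oligo synthesis encodes each transcription
factor binding site as a string over {A, C, G, T, K, M}, where K = G/T and
M = A/C are two-nucleotide synthesis mixtures.  A mixed-base motif with k
degenerate positions is physically realized as a pool of 2**k concrete
"sub-motifs", giving a first-order approximation of the underlying position
weight matrix (PWM) at low library complexity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .iupac import MIXED_CODES

__all__ = [
    "PWMatrix",
    "MixedBaseMotif",
    "SubMotif",
    "MotifCatalog",
    "encode_pwm_to_mixed",
    "expand_mixed_motif",
    "load_motif_catalog",
    "write_motif_catalog",
    "DESERT_MOTIF_ID",
]

BASES = ("A", "C", "G", "T")
KNOWN_FUNCTIONS = ("activating", "repressing", "dual", "unknown")

#: Sentinel id for the motif-free "desert" slot.
DESERT_MOTIF_ID = "desert"


@dataclass(frozen=True)
class PWMatrix:
    """Position weight matrix: per-column base frequencies (A, C, G, T)."""

    motif_id: str
    columns: tuple[tuple[float, float, float, float], ...]
    source_organism: str = ""

    def __post_init__(self):
        if len(self.columns) < 5:
            raise ValueError(f"{self.motif_id}: PWM must have length >= 5")
        for i, col in enumerate(self.columns):
            if len(col) != 4:
                raise ValueError(f"{self.motif_id}: column {i} must have 4 entries")
            if any(f < 0 or f > 1 for f in col):
                raise ValueError(f"{self.motif_id}: column {i} frequency outside [0,1]")
            if abs(sum(col) - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.motif_id}: column {i} sums to {sum(col):.8f}, not 1"
                )

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class MixedBaseMotif:
    """A TFBS motif over {A,C,G,T,K,M}; K and M mark synthesis mixtures."""

    motif_id: str
    sequence: str
    known_function: str = "unknown"
    source_organism: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - {"A", "C", "G", "T", "K", "M"}
        if bad:
            raise ValueError(
                f"{self.motif_id}: illegal characters {sorted(bad)} "
                "(only A/C/G/T and the K/M degenerate codes are supported)"
            )
        if self.known_function not in KNOWN_FUNCTIONS:
            raise ValueError(f"{self.motif_id}: unknown function {self.known_function!r}")
        if len(self.mixed_positions) > 4:
            raise ValueError(
                f"{self.motif_id}: {len(self.mixed_positions)} mixed positions, max 4"
            )

    @property
    def mixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, ch in enumerate(self.sequence) if ch in MIXED_CODES)

    @property
    def is_mixed(self) -> bool:
        return bool(self.mixed_positions)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SubMotif:
    """One concrete ACGT realization of a mixed-base motif."""

    parent_id: str
    sequence: str
    assignment: str  # concrete base chosen at each mixed position, in order

    @property
    def submotif_id(self) -> str:
        return f"{self.parent_id}|{self.assignment}" if self.assignment else self.parent_id


@dataclass
class MotifCatalog:
    motifs: list[MixedBaseMotif] = field(default_factory=list)

    def __post_init__(self):
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate motif ids: {dup}")
        if DESERT_MOTIF_ID in ids:
            raise ValueError(f"{DESERT_MOTIF_ID!r} is a reserved sentinel id")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, motif_id: str) -> MixedBaseMotif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    @property
    def mixed_motifs(self) -> list[MixedBaseMotif]:
        return [m for m in self.motifs if m.is_mixed]

    @property
    def plain_motifs(self) -> list[MixedBaseMotif]:
        return [m for m in self.motifs if not m.is_mixed]

    def function_counts(self) -> dict[str, int]:
        out = {f: 0 for f in KNOWN_FUNCTIONS}
        for m in self.motifs:
            out[m.known_function] += 1
        return out


def encode_pwm_to_mixed(
    pwm: PWMatrix,
    pair_threshold: float = 0.70,
    known_function: str = "unknown",
) -> MixedBaseMotif:
    """Collapse a PWM into a mixed-base motif.

    Per column, in order of precedence:

    1. a single base with frequency >= ``pair_threshold`` emits that base
       (a dominated column is not a mixture);
    2. freq(G) + freq(T) >= threshold emits K;
    3. freq(A) + freq(C) >= threshold emits M;
    4. otherwise the single most probable base (ties broken alphabetically).

    ``pair_threshold`` defaults to the 0.70 design threshold; it is a free
    parameter of the encoding, not a property of any particular PWM set.
    """
    if not 0.5 < pair_threshold <= 1.0:
        raise ValueError("pair_threshold must lie in (0.5, 1]")
    out = []
    for col in pwm.columns:
        freqs = dict(zip(BASES, col))
        best = max(BASES, key=lambda b: (freqs[b], -BASES.index(b)))
        if freqs[best] >= pair_threshold:
            out.append(best)
        elif freqs["G"] + freqs["T"] >= pair_threshold:
            out.append("K")
        elif freqs["A"] + freqs["C"] >= pair_threshold:
            out.append("M")
        else:
            out.append(best)
    return MixedBaseMotif(
        motif_id=pwm.motif_id,
        sequence="".join(out),
        known_function=known_function,
        source_organism=pwm.source_organism,
    )


def expand_mixed_motif(motif: MixedBaseMotif) -> list[SubMotif]:
    """All 2**k concrete sub-motifs, in lexicographic assignment order.

    A motif without mixed bases expands to itself (k = 0, one sub-motif).
    """
    positions = motif.mixed_positions
    pairs = [MIXED_CODES[motif.sequence[p]] for p in positions]
    out = []
    for assignment in itertools.product(*pairs):
        seq = list(motif.sequence)
        for pos, base in zip(positions, assignment):
            seq[pos] = base
        out.append(
            SubMotif(parent_id=motif.motif_id, sequence="".join(seq),
                     assignment="".join(assignment))
        )
    return out


def load_motif_catalog(table_path: str | Path) -> MotifCatalog:
    """Read a motif catalog TSV (motif_id, sequence, organism, known_function)."""
    path = Path(table_path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"motif_id", "sequence"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty motif catalog")
    motifs = []
    for idx, row in df.iterrows():
        try:
            motifs.append(
                MixedBaseMotif(
                    motif_id=str(row["motif_id"]),
                    sequence=str(row["sequence"]).upper() if pd.notna(row["sequence"]) else "",
                    known_function=str(row.get("known_function", "unknown"))
                    if pd.notna(row.get("known_function")) else "unknown",
                    source_organism=str(row.get("organism", ""))
                    if pd.notna(row.get("organism")) else "",
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {idx + 1}: {e}") from e
    return MotifCatalog(motifs=motifs)


def write_motif_catalog(catalog: MotifCatalog, table_path: str | Path) -> None:
    pd.DataFrame(
        {
            "motif_id": [m.motif_id for m in catalog],
            "sequence": [m.sequence for m in catalog],
            "organism": [m.source_organism for m in catalog],
            "known_function": [m.known_function for m in catalog],
        }
    ).to_csv(table_path, sep="\t", index=False)
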