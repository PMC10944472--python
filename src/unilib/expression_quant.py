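"""Per-variant expression from FACS-bin read counts.

A sorted library distributes each variant's cells across four fluorescence
bins.  Raw per-bin read counts are corrected for sequencing depth and for
the relative size of each sort gate, normalized to a per-variant bin
distribution (x, y, z, w), and summarized as a bin-weighted mean
fluorescent expression:

    Expression (A.U.) = MeanBin1*x + MeanBin2*y + MeanBin3*z + MeanBin4*w

where MeanBin_b is the mean fluorescence measured for bin b during the
sort.  The default calibration uses the measured bin means 607, 1364,
2596 and 7541 A.U.

Normalization steps, per variant v and bin b with raw counts r_vb:

1. per-bin totals T_b;
2. depth-corrected fraction r_vb / T_b;
3-4. gate-size adjustment a_vb = (r_vb / T_b) * %Bin_b;
5. S_v = sum_b a_vb;
6. normalized n_vb = a_vb / S_v.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motif_catalog import DESERT_MOTIF_ID

__all__ = [
    "BinCalibration",
    "ExpressionTable",
    "normalize_reads",
    "compute_expression",
    "quantify",
    "classify_group",
    "per_motif_distributions",
    "rank_shift_test",
    "barcode_pair_correlation",
    "median_vs_count_correlation",
]

BIN_COLS = ["bin1", "bin2", "bin3", "bin4"]
NORM_COLS = ["x", "y", "z", "w"]


@dataclass(frozen=True)
class BinCalibration:
    """FACS calibration: per-bin mean fluorescence and gate histogram areas."""

    bin_means: tuple[float, float, float, float] = (607.0, 1364.0, 2596.0, 7541.0)
    bin_areas: tuple[float, float, float, float] = (25.0, 25.0, 25.0, 25.0)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.bin_means, self.bin_means[1:])):
            raise ValueError("bin_means must be strictly increasing")
        if any(a < 0 for a in self.bin_areas):
            raise ValueError("bin_areas must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"bin_means": list(self.bin_means), "bin_areas": list(self.bin_areas)},
            indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BinCalibration":
        d = json.loads(Path(path).read_text())
        return cls(bin_means=tuple(d["bin_means"]), bin_areas=tuple(d["bin_areas"]))


@dataclass
class ExpressionTable:
    """Per-record normalized bin vectors, expression and quality group."""

    table: pd.DataFrame  # index-level keys + x..w, expression, total_reads, group
    calibration: BinCalibration = field(default_factory=BinCalibration)

    def group(self, g: int) -> pd.DataFrame:
        return self.table[self.table["group"] == g]

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def normalize_reads(
    counts: pd.DataFrame,
    cal: BinCalibration,
    bin_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalized per-bin read vectors (rows summing to 1).

    ``counts`` has one row per record (variant, barcode, or sub-variant)
    and columns bin1..bin4.  Records with zero total reads are dropped
    (they carry no bin information).
    """
    counts = counts.reindex(columns=BIN_COLS).astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    if bin_totals is None:
        bin_totals = counts.sum(axis=0)
    totals = bin_totals.reindex(BIN_COLS).to_numpy(dtype=float)
    frac = counts.to_numpy() / np.where(totals > 0, totals, np.nan)
    adjusted = np.nan_to_num(frac) * np.asarray(cal.bin_areas, dtype=float)
    s = adjusted.sum(axis=1)
    keep = s > 0
    normalized = adjusted[keep] / s[keep, None]
    out = pd.DataFrame(normalized, columns=NORM_COLS, index=counts.index[keep])
    return out


def compute_expression(normalized: pd.DataFrame | np.ndarray,
                       cal: BinCalibration) -> pd.Series | float:
    """Bin-weighted mean fluorescent expression (A.U.)."""
    arr = np.asarray(normalized, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("normalized vectors must sum to 1")
    expr = arr @ np.asarray(cal.bin_means, dtype=float)
    if single:
        return float(expr[0])
    return pd.Series(expr, index=normalized.index, name="expression")


def classify_group(total_reads: pd.Series | int,
                   top_bin_share: pd.Series | float,
                   min_reads: int = 40,
                   saturation_frac: float = 0.90):
    """Quality group: 3 = under-sampled (< ``min_reads`` total reads),
    2 = saturated (> ``saturation_frac`` of normalized mass in the top bin),
    1 = well-sampled dynamic range."""
    reads = pd.Series(np.atleast_1d(total_reads))
    share = pd.Series(np.atleast_1d(top_bin_share))
    group = pd.Series(1, index=reads.index)
    group[share.to_numpy() > saturation_frac] = 2
    group[reads.to_numpy() < min_reads] = 3
    if np.isscalar(total_reads) or isinstance(total_reads, (int, float)):
        return int(group.iloc[0])
    group.index = total_reads.index
    return group


def quantify(
    counts: pd.DataFrame,
    cal: BinCalibration | None = None,
    bin_totals: pd.Series | None = None,
    min_reads: int = 40,
    saturation_frac: float = 0.90,
) -> ExpressionTable:
    """Full quantification: normalize, score expression, classify groups."""
    cal = cal or BinCalibration()
    counts = counts.reindex(columns=BIN_COLS)
    total_reads = counts.sum(axis=1).astype(int)
    norm = normalize_reads(counts, cal, bin_totals)
    expr = compute_expression(norm, cal)
    out = norm.copy()
    out["expression"] = expr
    out["total_reads"] = total_reads.reindex(out.index)
    out["group"] = classify_group(out["total_reads"], out["w"],
                                  min_reads, saturation_frac)
    return ExpressionTable(table=out, calibration=cal)


def aggregate_barcodes(expr: ExpressionTable,
                       barcode_to_variant: dict[str, str]) -> ExpressionTable:
    """Pool per-barcode records to per-variant records.

    Normalized vectors are combined by read-weighted averaging across a
    variant's barcodes, which reproduces the pooled-bin estimate; groups
    are re-derived from the pooled vector and total.
    """
    t = expr.table.copy()
    t["variant_id"] = [barcode_to_variant[b] for b in t.index]
    w = t[NORM_COLS].to_numpy() * t["total_reads"].to_numpy()[:, None]
    t[NORM_COLS] = w
    agg = t.groupby("variant_id").agg(
        {**{c: "sum" for c in NORM_COLS}, "total_reads": "sum"}
    )
    agg[NORM_COLS] = agg[NORM_COLS].to_numpy() / agg[NORM_COLS].sum(axis=1).to_numpy()[:, None]
    agg["expression"] = compute_expression(agg[NORM_COLS], expr.calibration)
    agg["group"] = classify_group(agg["total_reads"], agg["w"])
    return ExpressionTable(table=agg, calibration=expr.calibration)


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def per_motif_distributions(
    records: pd.DataFrame,
    variant_motifs: dict[str, tuple[str, ...]],
    motif_ids: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Expression values of all records containing each motif at least once.

    ``records`` is indexed by variant_id with an ``expression`` column
    (typically group-1 records only).  A variant carrying a motif twice
    contributes once to that motif's distribution.  The desert entry
    collects motif-free variants.
    """
    if motif_ids is None:
        motif_ids = sorted({m for ms in variant_motifs.values() for m in ms})
    out: dict[str, list[float]] = {m: [] for m in motif_ids}
    out[DESERT_MOTIF_ID] = []
    expr = records["expression"]
    for vid, e in expr.items():
        motifs = variant_motifs.get(vid)
        if motifs is None:
            continue
        if not motifs:
            out[DESERT_MOTIF_ID].append(e)
        for m in set(motifs):
            if m in out:
                out[m].append(e)
    return {m: np.asarray(v, dtype=float) for m, v in out.items()}


def distribution_summary(distributions: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for m, v in distributions.items():
        if len(v) == 0:
            rows.append({"motif_id": m, "n": 0, "median": np.nan,
                         "q25": np.nan, "q75": np.nan})
        else:
            rows.append({"motif_id": m, "n": len(v), "median": float(np.median(v)),
                         "q25": float(np.percentile(v, 25)),
                         "q75": float(np.percentile(v, 75))})
    return pd.DataFrame(rows).set_index("motif_id")


def rank_shift_test(
    distributions: dict[str, np.ndarray],
    rank_offset: int = 5,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of each motif group against distant-ranked groups.

    Groups are ranked by median expression; each group is compared against
    the pooled values of groups ranked at least ``rank_offset`` positions
    away, two-sided, then Benjamini-Hochberg corrected at ``fdr``.
    """
    named = [(m, v) for m, v in distributions.items() if len(v) >= 2]
    named.sort(key=lambda mv: -float(np.median(mv[1])))
    rows = []
    pvals = []
    for i, (m, v) in enumerate(named):
        ref_parts = [v2 for j, (_, v2) in enumerate(named)
                     if abs(j - i) >= rank_offset]
        if not ref_parts:
            continue
        ref = np.concatenate(ref_parts)
        stat = stats.ranksums(v, ref)
        rows.append({"motif_id": m, "rank": i, "n": len(v),
                     "median": float(np.median(v)), "p_value": stat.pvalue})
        pvals.append(stat.pvalue)
    df = pd.DataFrame(rows)
    if len(df):
        reject, p_adj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
    return df.set_index("motif_id") if len(df) else df


def barcode_pair_correlation(
    expr: ExpressionTable,
    barcode_to_variant: dict[str, str],
) -> pd.DataFrame:
    """Pearson r of the normalized 4-bin vectors of same-variant barcode pairs.

    Pairs where either vector has zero variance are flagged undefined
    (r = NaN) rather than dropped.
    """
    t = expr.table
    by_variant: dict[str, list[str]] = {}
    for bc in t.index:
        v = barcode_to_variant.get(bc)
        if v is not None:
            by_variant.setdefault(v, []).append(bc)
    rows = []
    for v, bcs in by_variant.items():
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                a = t.loc[bcs[i], NORM_COLS].to_numpy(dtype=float)
                b = t.loc[bcs[j], NORM_COLS].to_numpy(dtype=float)
                if np.std(a) == 0 or np.std(b) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append({
                    "variant_id": v, "barcode_1": bcs[i], "barcode_2": bcs[j],
                    "r": r,
                    "expression_1": float(t.loc[bcs[i], "expression"]),
                    "expression_2": float(t.loc[bcs[j], "expression"]),
                })
    return pd.DataFrame(rows)


def median_vs_count_correlation(distributions: dict[str, np.ndarray]) -> float:
    """Pearson r between per-motif median expression and group size."""
    named = [(float(np.median(v)), len(v)) for v in distributions.values() if len(v)]
    if len(named) < 3:
        raise ValueError("need at least 3 nonempty motif groups")
    med, n = map(np.asarray, zip(*named))
    if np.std(med) == 0 or np.std(n) == 0:
        return float("nan")
    return float(stats.pearsonr(med, n).statistic)
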