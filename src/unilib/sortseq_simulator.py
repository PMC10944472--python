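"""Synthetic SORT-seq experiments with known ground truth.

The generative model mirrors the measurement process of a FACS-binned
reporter library:

* each variant has a latent log-expression mu0 + sum(beta_m * count_m)
  + Normal(0, sigma_v) — multiplicative motif effects on the fluorescence
  scale, matching billboard-style additive regulation in log space;
* single cells fluoresce log-normally around the variant latent with
  spread sigma_c, and are gated into 4 bins at fixed log-fluorescence
  boundaries (defaulting to quartiles of the pooled distribution, the way
  sort gates are placed in practice);
* per-bin read counts are multinomial across variants with probabilities
  proportional to abundance x bin-occupancy, at a configured depth;
* optionally, full per-bin FASTQ reads are emitted (primer + barcode +
  variable region + downstream context) with independent substitution
  errors and uniform realization of K/M mixed positions.

Everything is deterministic given the seed.  Not modeled: PCR bias, sort
impurity, growth effects between sort and sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression_quant import BIN_COLS, BinCalibration
from .iupac import MIXED_CODES
from .library_designer import DesignManifest
from .sortseq_reader import BinReadTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_truth",
    "simulate_counts",
    "simulate_reads",
    "recovery_report",
]

#: Downstream core-promoter context appended to simulated reads so that
#: standard-design reads clear the 200-base merged-read length filter.
#: Synthetic sequence (stand-in for the real downstream minimal promoter).
DOWNSTREAM_CONTEXT = "GATCCGTACGCTAGCTTGACGGTATCGCATCACGATTTGAGC"


@dataclass
class SimulationConfig:
    motif_effects: dict[str, float] = field(default_factory=dict)
    core_log_level: float = float(np.log(1000.0))  # weak-promoter baseline, ~1000 A.U.
    variant_noise: float = 0.1   # sigma_v, log-scale variant-to-variant noise
    cell_noise: float = 0.6      # sigma_c, log-scale single-cell fluorescence spread
    bin_boundaries: tuple[float, float, float] | None = None  # log-fluorescence gates
    reads_per_variant: float = 50.0
    per_bin_depth: int | None = None  # overrides reads_per_variant when set
    barcode_error_rate: float = 0.0
    abundance_skew: float = 0.0  # log-normal sd of per-variant abundance
    rng_seed: int = 0

    def __post_init__(self):
        if self.variant_noise < 0 or self.cell_noise < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.bin_boundaries is not None:
            b = self.bin_boundaries
            if not (b[0] < b[1] < b[2]):
                raise ValueError("bin boundaries must be strictly increasing")


@dataclass
class GroundTruth:
    latent: pd.Series                 # per-variant latent log-expression
    bin_probs: pd.DataFrame           # per-variant 4-vector, rows sum to 1
    true_expression: pd.Series        # A.U. under the derived calibration
    calibration: BinCalibration
    boundaries: tuple[float, float, float]
    abundance: pd.Series              # relative variant abundance (sums to 1)


def _pooled_quartile_boundaries(latent: np.ndarray, sigma_c: float,
                                rng: np.random.Generator) -> tuple[float, ...]:
    """Quartile gates of the pooled cell fluorescence distribution."""
    draws = rng.normal(
        loc=np.repeat(latent, 64), scale=max(sigma_c, 1e-9)
    )
    return tuple(np.quantile(draws, [0.25, 0.5, 0.75]))


def _truncated_lognormal_mass_mean(mu: np.ndarray, sigma: float,
                                   lo: float, hi: float):
    """(P(lo < f <= hi), E[e^f ; lo < f <= hi]) for f ~ N(mu, sigma)."""
    sigma = max(sigma, 1e-9)
    mass = norm.cdf((hi - mu) / sigma) - norm.cdf((lo - mu) / sigma)
    mgf = np.exp(mu + sigma**2 / 2)
    weighted = mgf * (norm.cdf((hi - mu - sigma**2) / sigma)
                      - norm.cdf((lo - mu - sigma**2) / sigma))
    return mass, weighted


def simulate_truth(manifest: DesignManifest, config: SimulationConfig) -> GroundTruth:
    """Latent expression, bin occupancies and derived calibration."""
    rng = np.random.default_rng(config.rng_seed)
    variant_motifs = manifest.variant_motifs()
    vids = sorted(variant_motifs)
    beta = config.motif_effects
    latent = np.array([
        config.core_log_level + sum(beta.get(m, 0.0) for m in variant_motifs[v])
        for v in vids
    ])
    if config.variant_noise > 0:
        latent = latent + rng.normal(0, config.variant_noise, size=len(vids))
    if config.bin_boundaries is None:
        bounds = _pooled_quartile_boundaries(latent, config.cell_noise, rng)
    else:
        bounds = config.bin_boundaries
    edges = np.array([-np.inf, *bounds, np.inf])
    sigma = config.cell_noise
    mass = np.empty((len(vids), 4))
    weighted = np.empty((len(vids), 4))
    for b in range(4):
        mass[:, b], weighted[:, b] = _truncated_lognormal_mass_mean(
            latent, sigma, edges[b], edges[b + 1]
        )
    mass = np.clip(mass, 0.0, None)
    mass /= mass.sum(axis=1, keepdims=True)

    if config.abundance_skew > 0:
        ab = np.exp(rng.normal(0, config.abundance_skew, size=len(vids)))
    else:
        ab = np.ones(len(vids))
    ab /= ab.sum()

    # calibration from the pooled (abundance-weighted) cell distribution
    pooled_mass = ab @ mass
    pooled_weighted = ab @ weighted
    bin_means = pooled_weighted / np.where(pooled_mass > 0, pooled_mass, np.nan)
    bin_means = np.maximum.accumulate(np.nan_to_num(bin_means, nan=1.0))
    # guarantee strict increase for degenerate pools
    for i in range(1, 4):
        if bin_means[i] <= bin_means[i - 1]:
            bin_means[i] = bin_means[i - 1] * (1 + 1e-6)
    cal = BinCalibration(bin_means=tuple(bin_means),
                         bin_areas=tuple(100.0 * pooled_mass))
    true_expr = mass @ np.asarray(cal.bin_means)
    return GroundTruth(
        latent=pd.Series(latent, index=vids, name="latent"),
        bin_probs=pd.DataFrame(mass, index=vids, columns=BIN_COLS),
        true_expression=pd.Series(true_expr, index=vids, name="true_expression"),
        calibration=cal,
        boundaries=tuple(bounds),
        abundance=pd.Series(ab, index=vids, name="abundance"),
    )


def _bin_depths(truth: GroundTruth, config: SimulationConfig) -> np.ndarray:
    n = len(truth.latent)
    if config.per_bin_depth is not None:
        return np.full(4, int(config.per_bin_depth))
    total = config.reads_per_variant * n
    pooled = truth.abundance.to_numpy() @ truth.bin_probs.to_numpy()
    return np.round(total * pooled).astype(int)


def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> BinReadTable:
    """Multinomial per-bin read counts across variants."""
    rng = np.random.default_rng(config.rng_seed + 1)
    probs = truth.bin_probs.to_numpy() * truth.abundance.to_numpy()[:, None]
    depths = _bin_depths(truth, config)
    cols = {}
    for b in range(4):
        p = probs[:, b]
        total = p.sum()
        if total <= 0 or depths[b] <= 0:
            cols[BIN_COLS[b]] = np.zeros(len(p), dtype=int)
        else:
            cols[BIN_COLS[b]] = rng.multinomial(int(depths[b]), p / total)
    counts = pd.DataFrame(cols, index=truth.bin_probs.index)
    return BinReadTable.from_counts(counts)


def _realize_mixed(seq: str, rng: np.random.Generator) -> str:
    if not any(ch in MIXED_CODES for ch in seq):
        return seq
    out = []
    for ch in seq:
        if ch in MIXED_CODES:
            out.append(MIXED_CODES[ch][rng.integers(0, 2)])
        else:
            out.append(ch)
    return "".join(out)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    truth: GroundTruth,
    manifest: DesignManifest,
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[int, Path]:
    """Emit per-bin FASTQ files of full oligo reads.

    Read counts are drawn per oligo (a variant's reads split uniformly
    across its barcodes); each read is the oligo's full sequence with K/M
    positions realized uniformly, plus downstream context, with
    independent substitution errors at ``barcode_error_rate``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed + 2)
    t = manifest.table
    variant_of = t["variant_id"].to_numpy()
    full_seqs = t["full_sequence"].to_numpy()
    vids = truth.bin_probs.index
    vid_pos = {v: i for i, v in enumerate(vids)}
    oligo_rows = np.array([vid_pos[v] for v in variant_of])
    n_bc = t.groupby("variant_id")["barcode"].count()
    oligo_weight = (truth.abundance.to_numpy()[oligo_rows]
                    / n_bc.loc[variant_of].to_numpy())
    probs = truth.bin_probs.to_numpy()[oligo_rows] * oligo_weight[:, None]
    depths = _bin_depths(truth, config)
    paths = {}
    for b in range(4):
        path = out_dir / f"bin{b + 1}.fastq"
        p = probs[:, b]
        total = p.sum()
        with open(path, "w") as fh:
            if total > 0 and depths[b] > 0:
                counts = rng.multinomial(int(depths[b]), p / total)
                serial = 0
                for oligo_idx in np.flatnonzero(counts):
                    base = full_seqs[oligo_idx] + DOWNSTREAM_CONTEXT
                    for _ in range(counts[oligo_idx]):
                        serial += 1
                        read = _mutate(_realize_mixed(base, rng),
                                       config.barcode_error_rate, rng)
                        fh.write(f"@bin{b + 1}_read{serial}\n{read}\n+\n"
                                 f"{'I' * len(read)}\n")
        paths[b + 1] = path
    return paths


def recovery_report(
    estimated_expression: pd.Series,
    truth: GroundTruth,
    classification: pd.DataFrame | None = None,
    planted: dict[str, str] | None = None,
    predictions: pd.Series | None = None,
) -> dict[str, float]:
    """Ground-truth recovery metrics for a pipeline run on simulated data.

    Reports the Pearson correlation between estimated expression and the
    ground truth, sensitivity/specificity of the motif classification
    against the planted effect signs, and (optionally) the correlation of
    model predictions with the truth.

    Two truth scales are reported: ``expression_vs_true_r`` compares the
    estimate with the per-variant true binned expression (the estimator's
    infinite-depth target, on the same A.U. scale), while
    ``expression_vs_latent_r`` compares against exp(latent); the latter is
    additionally limited by gate saturation of the 4-bin readout, not only
    by estimation error.
    """
    common = estimated_expression.index.intersection(truth.latent.index)
    est = estimated_expression.loc[common].to_numpy()
    lat = truth.latent.loc[common].to_numpy()
    true_au = truth.true_expression.loc[common].to_numpy()
    report: dict[str, float] = {
        "n_variants": float(len(common)),
        "expression_vs_true_r": float(np.corrcoef(est, true_au)[0, 1]),
        "expression_vs_latent_r": float(np.corrcoef(est, np.exp(lat))[0, 1]),
    }
    if classification is not None and planted is not None:
        calls = classification["classification"]
        tp = fn = fp = tn = 0
        for mid, true_sign in planted.items():
            call = calls.get(mid, "undetermined")
            if true_sign in ("activating", "repressing"):
                if call == true_sign:
                    tp += 1
                else:
                    fn += 1
            else:
                if call == "undetermined":
                    tn += 1
                else:
                    fp += 1
        report["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        report["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        report["false_positive_rate"] = fp / (fp + tn) if fp + tn else float("nan")
    if predictions is not None:
        common = predictions.index.intersection(truth.latent.index)
        report["prediction_vs_latent_r"] = float(np.corrcoef(
            predictions.loc[common].to_numpy(),
            np.exp(truth.latent.loc[common].to_numpy()))[0, 1])
    return report
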