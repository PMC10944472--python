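"""Sequence-to-expression models for sURS variants.

Two complementary predictors:

* the motif-additive model (MAM), a mechanistic billboard-grammar model in
  which expression = core promoter level x linear boost in the summed
  activating-motif weights (weight = -log10 of the motif's enrichment
  p-value) x a single constant attenuation factor (~x2 down) when one or
  more repressing motifs is present, regardless of their number; and

* a small 1D convolutional network (conv -> ReLU -> global max pool ->
  dense -> linear or softmax head) trained on one-hot encoded variable
  regions, optionally concatenating a per-sequence motif-count vector
  after the pooling layer so that sequences longer than the training
  length can be scored (the hybrid "MLAM" configuration).  Ensembles of
  independently initialized members are averaged.

No deep-learning framework is assumed: the network is implemented directly
in numpy (im2col convolution, Adam optimizer, backprop by hand), which is
ample for the desk-scale configurations used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .library_designer import DesignManifest
from .motif_catalog import MotifCatalog

__all__ = [
    "MAMParams",
    "mam_predict",
    "mam_from_enrichment",
    "fit_mam_calibration",
    "CNNConfig",
    "TrainingSet",
    "one_hot_encode",
    "encode_design_sequence",
    "train_cnn",
    "predict",
    "evaluate",
    "EvalResult",
    "select_training_set",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_MIXED_CHANNELS = {"K": (2, 3), "M": (0, 1)}  # K = G/T, M = A/C


# ---------------------------------------------------------------------------
# motif-additive model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAMParams:
    """Billboard-model parameters.

    ``boost_weights`` maps each activating motif to a nonnegative weight
    (by construction -log10 of its enrichment p-value); ``repressors`` is
    the set of attenuating motifs; ``calibration`` = (slope, intercept)
    maps the summed weight W to fold = intercept + slope * W, with
    intercept 1 so a motif-free cassette gives fold exactly 1.
    """

    boost_weights: dict[str, float] = field(default_factory=dict)
    repressors: frozenset[str] = frozenset()
    attenuation_factor: float = 0.5
    core_levels: dict[str, float] = field(
        default_factory=lambda: {"weak": 1000.0, "strong": 4000.0}
    )
    calibration: tuple[float, float] = (0.25, 1.0)  # (slope, intercept)

    def __post_init__(self):
        if not 0 < self.attenuation_factor <= 1:
            raise ValueError("attenuation_factor must lie in (0, 1]")
        if any(w < 0 for w in self.boost_weights.values()):
            raise ValueError("boost weights must be nonnegative")


def mam_predict(
    motif_ids: tuple[str, ...] | list[str],
    params: MAMParams,
    core_promoter: str = "weak",
) -> tuple[float, float]:
    """Predicted (expression, fold-vs-core) for a motif cassette.

    fold = calibration(sum of activating weights) x attenuation factor if
    any repressing motif is present (applied once, independent of the
    repressor count); expression = core level x fold.
    """
    if core_promoter not in params.core_levels:
        raise KeyError(f"unknown core promoter {core_promoter!r}")
    w = sum(params.boost_weights.get(m, 0.0) for m in motif_ids)
    slope, intercept = params.calibration
    fold = intercept + slope * w
    if any(m in params.repressors for m in motif_ids):
        fold *= params.attenuation_factor
    expression = params.core_levels[core_promoter] * fold
    return expression, fold


def mam_from_enrichment(classification: pd.DataFrame, **kwargs) -> MAMParams:
    """Build MAM parameters from a motif classification table
    (columns p_up, p_down, classification)."""
    boosts = {
        mid: float(-np.log10(max(row["p_up"], 1e-300)))
        for mid, row in classification.iterrows()
        if row["classification"] == "activating"
    }
    reps = frozenset(
        mid for mid, row in classification.iterrows()
        if row["classification"] == "repressing"
    )
    return MAMParams(boost_weights=boosts, repressors=reps, **kwargs)


def fit_mam_calibration(
    observed_folds: np.ndarray | list[float],
    mean_log10_pvalues: np.ndarray | list[float],
) -> dict[str, float]:
    """Least-squares line fold ~ mean(-log10 p) over measured cassettes."""
    x = np.asarray(mean_log10_pvalues, dtype=float)
    y = np.asarray(observed_folds, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 cassettes to calibrate")
    if np.std(x) == 0:
        raise ValueError("degenerate calibration: all weights identical")
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue)}


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def one_hot_encode(sequence: str, max_length: int | None = None,
                   pad_value: float = 0.25) -> np.ndarray:
    """One-hot encode an ACGT sequence as a 4 x max_length matrix.

    Positions beyond the sequence are uniform-padded with ``pad_value`` in
    every channel, so every column sums to 1 with the default 0.25.
    """
    max_length = max_length if max_length is not None else len(sequence)
    if len(sequence) > max_length:
        raise ValueError("sequence longer than max_length")
    out = np.full((4, max_length), pad_value, dtype=np.float64)
    for j, ch in enumerate(sequence):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"illegal character {ch!r} at position {j}")
        out[:, j] = 0.0
        out[idx, j] = 1.0
    return out


def encode_design_sequence(sequence: str, max_length: int | None = None,
                           pad_value: float = 0.25) -> np.ndarray:
    """Like :func:`one_hot_encode` but accepts K/M design symbols, encoded
    as an equal 0.5/0.5 split over their two channels (the synthesis
    mixture the symbol denotes)."""
    max_length = max_length if max_length is not None else len(sequence)
    out = np.full((4, max_length), pad_value, dtype=np.float64)
    for j, ch in enumerate(sequence):
        if ch in _BASE_INDEX:
            out[:, j] = 0.0
            out[_BASE_INDEX[ch], j] = 1.0
        elif ch in _MIXED_CHANNELS:
            out[:, j] = 0.0
            for idx in _MIXED_CHANNELS[ch]:
                out[idx, j] = 0.5
        else:
            raise ValueError(f"illegal character {ch!r} at position {j}")
    return out


def count_motifs(sequence_motifs: tuple[str, ...], motif_ids: list[str]) -> np.ndarray:
    """Per-catalog-motif occurrence counts of one designed cassette."""
    return np.array([sequence_motifs.count(m) for m in motif_ids], dtype=np.float64)


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNConfig:
    """Desk-scale defaults; :meth:`paper_config` restores the full-size
    architecture (1024 kernels, ensemble of 100)."""

    n_kernels: int = 64
    kernel_width: int = 6
    dense_units: int = 16
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    output_mode: str = "scalar"  # or "bins" (4-way softmax head)
    use_sample_weights: bool = True
    ensemble_size: int = 5
    include_motif_counts: bool = False  # MLAM hybrid input
    max_input_length: int = 101
    pad_value: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_kernels", "kernel_width", "dense_units", "epochs",
                     "batch_size", "ensemble_size", "max_input_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.output_mode not in ("scalar", "bins"):
            raise ValueError("output_mode must be 'scalar' or 'bins'")

    @classmethod
    def paper_config(cls, **overrides) -> "CNNConfig":
        return cls(n_kernels=1024, ensemble_size=100, **overrides)


@dataclass
class TrainingSet:
    sequences: list[str]
    targets: np.ndarray  # (n,) expression or (n, 4) normalized bin vectors
    sample_weights: np.ndarray | None = None
    motif_counts: np.ndarray | None = None  # (n, n_catalog_motifs)
    ids: list[str] | None = None

    def __post_init__(self):
        n = len(self.sequences)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if len(self.targets) != n:
            raise ValueError("targets/sequences length mismatch")
        if self.sample_weights is not None:
            self.sample_weights = np.asarray(self.sample_weights, dtype=np.float64)
            if len(self.sample_weights) != n:
                raise ValueError("sample_weights length mismatch")
            total = self.sample_weights.sum()
            if total <= 0:
                raise ValueError("sample weights must have positive mass")
            self.sample_weights = self.sample_weights / total
        if self.motif_counts is not None:
            self.motif_counts = np.asarray(self.motif_counts, dtype=np.float64)
            if self.motif_counts.shape[0] != n:
                raise ValueError("motif_counts length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _ConvNet:
    """conv1d -> ReLU -> global max pool -> [motif-count concat] ->
    dense ReLU -> linear or softmax head."""

    def __init__(self, config: CNNConfig, n_counts: int, rng: np.random.Generator):
        self.config = config
        kw, nk, du = config.kernel_width, config.n_kernels, config.dense_units
        n_out = 1 if config.output_mode == "scalar" else 4
        fan_conv = 4 * kw
        fan_d1 = nk + n_counts
        self.params = {
            "Wc": rng.normal(0, np.sqrt(2.0 / fan_conv), size=(fan_conv, nk)),
            "bc": np.zeros(nk),
            "W1": rng.normal(0, np.sqrt(2.0 / fan_d1), size=(fan_d1, du)),
            "b1": np.zeros(du),
            "W2": rng.normal(0, np.sqrt(1.0 / du), size=(du, n_out)),
            "b2": np.zeros(n_out),
        }
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X: np.ndarray, counts: np.ndarray | None):
        """X: (n, 4, L) encoded sequences."""
        kw = self.config.kernel_width
        n, _, L = X.shape
        # im2col: windows (n, P, 4*kw) in channel-major layout
        win = np.lib.stride_tricks.sliding_window_view(X, kw, axis=2)
        # win: (n, 4, P, kw) -> (n, P, 4*kw)
        win = win.transpose(0, 2, 1, 3).reshape(n, L - kw + 1, 4 * kw)
        conv = win @ self.params["Wc"] + self.params["bc"]
        relu_c = np.maximum(conv, 0.0)
        pool_idx = relu_c.argmax(axis=1)  # (n, nk)
        pooled = np.take_along_axis(relu_c, pool_idx[:, None, :], axis=1)[:, 0, :]
        h_in = pooled if counts is None else np.concatenate([pooled, counts], axis=1)
        z1 = h_in @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.params["W2"] + self.params["b2"]
        cache = (win, conv, pool_idx, h_in, z1, a1)
        return z2, cache

    def _backward(self, dz2: np.ndarray, cache) -> dict[str, np.ndarray]:
        win, conv, pool_idx, h_in, z1, a1 = cache
        p = self.params
        grads = {
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (z1 > 0)
        grads["W1"] = h_in.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dh = dz1 @ p["W1"].T
        nk = self.config.n_kernels
        dpool = dh[:, :nk]
        # route gradient back through the max pool to the argmax window
        dconv = np.zeros_like(conv)
        np.put_along_axis(dconv, pool_idx[:, None, :], dpool[:, None, :], axis=1)
        dconv *= conv > 0
        n, P, F = win.shape
        grads["Wc"] = win.reshape(n * P, F).T @ dconv.reshape(n * P, nk)
        grads["bc"] = dconv.sum(axis=(0, 1))
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, counts: np.ndarray | None,
            weights: np.ndarray | None, rng: np.random.Generator):
        cfg = self.config
        n = X.shape[0]
        scalar = cfg.output_mode == "scalar"
        if scalar:
            self.y_mean = float(y.mean())
            self.y_std = float(y.std()) or 1.0
            yt = (y - self.y_mean) / self.y_std
            yt = yt[:, None]
        else:
            yt = y
        if weights is None:
            weights = np.ones(n)
        w = weights * (n / weights.sum())  # mean-1 so loss scale is batch-invariant
        opt = _Adam(self.params, cfg.learning_rate)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = X[idx]
                cb = None if counts is None else counts[idx]
                yb, wb = yt[idx], w[idx]
                z2, cache = self._forward(xb, cb)
                m = len(idx)
                if scalar:
                    dz2 = (z2 - yb) * wb[:, None] * (2.0 / m)
                else:
                    # average-weighted cross-entropy against soft bin targets
                    zmax = z2.max(axis=1, keepdims=True)
                    ez = np.exp(z2 - zmax)
                    probs = ez / ez.sum(axis=1, keepdims=True)
                    dz2 = (probs - yb) * wb[:, None] / m
                grads = self._backward(dz2, cache)
                opt.step(self.params, grads)

    def predict(self, X: np.ndarray, counts: np.ndarray | None) -> np.ndarray:
        out = []
        for start in range(0, X.shape[0], 512):
            xb = X[start:start + 512]
            cb = None if counts is None else counts[start:start + 512]
            z2, _ = self._forward(xb, cb)
            out.append(z2)
        z2 = np.concatenate(out, axis=0)
        if self.config.output_mode == "scalar":
            return z2[:, 0] * self.y_std + self.y_mean
        zmax = z2.max(axis=1, keepdims=True)
        ez = np.exp(z2 - zmax)
        return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class CNNEnsemble:
    members: list[_ConvNet]
    config: CNNConfig
    n_counts: int


def _encode_batch(sequences: list[str], config: CNNConfig) -> np.ndarray:
    X = np.empty((len(sequences), 4, config.max_input_length))
    for i, s in enumerate(sequences):
        X[i] = encode_design_sequence(s, config.max_input_length, config.pad_value)
    return X


def train_cnn(training_set: TrainingSet, config: CNNConfig | None = None) -> CNNEnsemble:
    """Train an ensemble of independently initialized conv nets.

    Members differ in initial weights and batch order; their averaged
    prediction is the ensemble output.  Fully reproducible from
    ``config.rng_seed``.
    """
    config = config or CNNConfig()
    if len(training_set) == 0:
        raise ValueError("empty training set")
    if config.output_mode == "bins":
        if training_set.targets.ndim != 2 or training_set.targets.shape[1] != 4:
            raise ValueError("bins output mode needs (n, 4) targets")
    elif training_set.targets.ndim != 1:
        raise ValueError("scalar output mode needs 1-d targets")
    counts = None
    n_counts = 0
    if config.include_motif_counts:
        if training_set.motif_counts is None:
            raise ValueError("include_motif_counts requires motif_counts")
        counts = training_set.motif_counts
        n_counts = counts.shape[1]
    X = _encode_batch(training_set.sequences, config)
    weights = training_set.sample_weights if config.use_sample_weights else None
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.ensemble_size)
    members = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        net = _ConvNet(config, n_counts, rng)
        net.fit(X, training_set.targets, counts, weights, rng)
        members.append(net)
    return CNNEnsemble(members=members, config=config, n_counts=n_counts)


def predict(ensemble: CNNEnsemble, sequences: list[str],
            motif_counts: np.ndarray | None = None) -> np.ndarray:
    """Ensemble-mean prediction for new sequences (padded to the training
    input length; MLAM mode requires the motif-count matrix)."""
    cfg = ensemble.config
    if cfg.include_motif_counts:
        if motif_counts is None:
            raise ValueError("this ensemble requires motif_counts input")
        motif_counts = np.asarray(motif_counts, dtype=np.float64)
        if motif_counts.shape != (len(sequences), ensemble.n_counts):
            raise ValueError(
                f"motif_counts must have shape ({len(sequences)}, {ensemble.n_counts})"
            )
    else:
        motif_counts = None
    X = _encode_batch(sequences, cfg)
    preds = [m.predict(X, motif_counts) for m in ensemble.members]
    return np.mean(preds, axis=0)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalResult:
    pearson_r: float
    bootstrap_mean: float
    bootstrap_sd: float
    scheme: str
    n_subsets: int


def evaluate(
    predictions: np.ndarray | list[float],
    observations: np.ndarray | list[float],
    scheme: str = "all_subsets",
    subset_size: int | None = None,
    n_subsets: int = 100,
    seed: int = 0,
) -> EvalResult:
    """Pearson r with bootstrap over subsets.

    ``all_subsets``: every subset of size n-2 (default) — the scheme used
    for small validation panels, e.g. C(11, 9) = 55 subsets for n = 11.
    ``random_subsets``: ``n_subsets`` seeded random subsets of
    ``subset_size`` (30, or 16 for small mammalian panels).
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return EvalResult(float("nan"), float("nan"), float("nan"), scheme, 0)
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if scheme == "all_subsets":
        k = subset_size if subset_size is not None else n - 2
        idx_sets = [np.array(c) for c in combinations(range(n), k)]
    elif scheme == "random_subsets":
        k = subset_size if subset_size is not None else min(30, n)
        rng = np.random.default_rng(seed)
        idx_sets = [rng.choice(n, size=k, replace=False) for _ in range(n_subsets)]
    else:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    rs = []
    for idx in idx_sets:
        xs, ys = x[idx], y[idx]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        rs.append(stats.pearsonr(xs, ys).statistic)
    rs = np.asarray(rs)
    return EvalResult(pearson_r=r, bootstrap_mean=float(rs.mean()),
                      bootstrap_sd=float(rs.std()), scheme=scheme,
                      n_subsets=len(idx_sets))


# ---------------------------------------------------------------------------
# training-set selection
# ---------------------------------------------------------------------------

def select_training_set(
    records: pd.DataFrame,
    manifest: DesignManifest,
    catalog: MotifCatalog,
    mode: str = "AMM",
    read_cutoff: float | None = None,
    target: str = "expression",
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[TrainingSet, TrainingSet]:
    """Build (train, heldout) sets under the named selection scheme.

    ADM ("all data"): variants above a total-read-count cutoff;
    AMM ("all motif"): the deeply barcoded variant subset;
    MBO ("mixed-base only"): deep variants containing >= 1 mixed-base motif.
    """
    variant_motifs = manifest.variant_motifs()
    regions = manifest.variant_regions()
    mixed_ids = {m.motif_id for m in catalog.mixed_motifs}
    recs = records[records.index.isin(variant_motifs)]
    if mode == "ADM":
        if read_cutoff is None:
            raise ValueError("ADM mode requires a read_cutoff")
        sel = recs[recs["total_reads"] > read_cutoff]
    elif mode in ("AMM", "MBO"):
        deep = set(manifest.deep_variants())
        sel = recs[recs.index.isin(deep)]
        if mode == "MBO":
            keep = [vid for vid in sel.index
                    if any(m in mixed_ids for m in variant_motifs[vid])]
            sel = sel.loc[keep]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if sel.empty:
        raise ValueError(f"selection mode {mode} produced an empty training set")

    motif_ids = catalog.motif_ids

    def build(index) -> TrainingSet:
        sub = sel.loc[index]
        seqs = [regions[v] for v in sub.index]
        counts = np.stack([count_motifs(variant_motifs[v], motif_ids)
                           for v in sub.index])
        if target == "expression":
            targets = sub["expression"].to_numpy()
        else:
            targets = sub[["x", "y", "z", "w"]].to_numpy()
        return TrainingSet(sequences=seqs, targets=targets,
                           sample_weights=sub["total_reads"].to_numpy(),
                           motif_counts=counts, ids=list(sub.index))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sel))
    n_hold = int(round(holdout_fraction * len(sel)))
    hold_idx = sel.index[order[:n_hold]]
    train_idx = sel.index[order[n_hold:]]
    return build(train_idx), build(hold_idx)
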