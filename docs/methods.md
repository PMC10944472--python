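# Methods

`unilib` implements the design and in-silico characterization loop for
motif-based synthetic upstream regulatory sequence (sURS) oligo libraries
read out by SORT-seq: a pooled reporter library is FACS-sorted into four
fluorescence bins, each bin is sequenced, and per-variant expression is
inferred from the bin read distribution.

## Library design

**Motif encoding.** TFBS motifs are carried as strings over
{A, C, G, T, K, M}, where K = G/T and M = A/C are two-base synthesis
mixtures. A PWM column is collapsed to one symbol by precedence: a single
base at frequency ≥ the pair threshold emits that base (a dominated
column is not a mixture); otherwise a qualifying G+T pair emits K, then a
qualifying A+C pair emits M; otherwise the single most probable base
(alphabetical tie-break). The pair threshold defaults to 0.70 and is a
free parameter of the encoding — any higher empirical value is a property
of a particular PWM set, not of the rule. Only K and M are supported,
matching mixed-base synthesis chemistry; R/Y/S/W inputs are rejected. A
motif with k ≤ 4 mixed positions denotes a pool of 2^k concrete
"sub-motifs", enumerated in lexicographic assignment order.

**Desert chassis.** The neutral backbone is a 101 nt sequence (186 nt for
the long validation variant) scrubbed of every motif in an IUPAC
exclusion list. The list is first filtered: motifs shorter than 5 nt,
entirely lower-case motifs, and motifs with ≤ 5 upper-case characters are
dropped; retained lower-case positions become N wildcards. Generation is
seeded rejection sampling with local repair — any hit (scanned on both
strands, since TFBSs are double-stranded) has its footprint resampled —
and the result is re-verified by an independent scan. Chassis GC content
is unconstrained.

**Variant enumeration.** All ordered arrangements of 0–3 catalog motifs
with repetition are embedded at fixed 1-based starts: 46 (single), 28/66
(double), 18/46/74 (triple). For an m-motif catalog this gives
Σ_{k=0..3} m^k variants (70,644 at m = 41), including the motif-free
desert variant. Motifs longer than 10 nt keep the same fixed starts, so
inter-motif spacing shrinks below the nominal 17 bp; overlap is a
placement error.

**Barcodes and assembly.** 15 nt barcodes are greedily rejection-sampled
under: pairwise Levenshtein distance ≥ 3 (which implies Hamming ≥ 3, the
matching-side guarantee), GC ∈ [35%, 65%], homopolymer runs ≤ 3, and no
internal SpeI/EagI site. Oligos are assembled as
5′ primer + SpeI (ACTAGT) + barcode + variable region + EagI (CGGCCG) +
3′ primer. A configurable subset of variants ("deep" variants, default
2,435) receives 22 barcodes; the rest receive 2. Note 70,644·2 + 2,435·20
= 189,988 rows; the manifest reports its own count.

## Read processing

Merged reads pass a fixed pipeline — length ≥ 200 nt, 5′ primer located,
bin identity (per-bin files, or an exact bin-barcode prefix when the bins
were PCR-pooled), variant barcode, body verification — with the first
failing stage recorded as the rejection reason, so assigned + rejected
always equals total input. Variant barcodes match by Hamming distance ≤ 2
with undetermined N bases counting as mismatches; ties at equal distance
are rejected as ambiguous (impossible at ≤ 1 error given the distance-3
code, possible at 2). The variable region must match the design exactly
outside K/M positions; at each mixed position the observed base must be
one of the pair and is recorded, giving per-sub-variant counts that
marginalize exactly to the variant counts.

## Expression quantification

For variant v with raw counts r_vb in bins b = 1..4 with per-bin totals
T_b and sort-histogram gate areas %Bin_b: a_vb = (r_vb / T_b) · %Bin_b,
S_v = Σ_b a_vb, normalized n_vb = a_vb / S_v, and

    Expression (A.U.) = MeanBin1·x + MeanBin2·y + MeanBin3·z + MeanBin4·w

with (x, y, z, w) = n_v· and the measured bin means defaulting to
607 / 1364 / 2596 / 7541 A.U. Expression is therefore bounded by
[MeanBin1, MeanBin4] and invariant to per-bin sequencing depth. Gate
areas default to uniform (25, 25, 25, 25) in simulation; with real data
they are a required calibration input.

Quality groups: group 3 = total reads < 40 (40 itself is included in
groups 1/2, resolving the boundary ambiguity in one direction); group 2 =
saturated, > 90% of normalized mass in the top bin; group 1 = the
analyzable dynamic range. When a variant carries several barcodes, per-
barcode vectors are pooled by read-weighted averaging, which reproduces
the pooled-count estimate; per-barcode records are retained for the
barcode-pair Pearson diagnostics (computed on the normalized 4-vectors;
zero-variance vectors are flagged undefined, not dropped).

Cohort statistics: per-motif expression distributions use
contains-at-least-once membership (the desert entry collects motif-free
variants); each motif group is compared against the pooled groups ranked
≥ 5 median-positions away by a two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg correction at FDR 0.1.

## Minimum-hypergeometric enrichment

Variants are ranked by expression (descending for the activating screen,
ascending for the repressing screen; ties broken by a stable sort on the
record id, since the statistic is order-sensitive) and labeled 1 when they
contain the motif. The mHG score is min over prefixes n ∈ 1..N−1 of the
hypergeometric tail HGT(b(n); n, B, N); the full-list prefix is excluded
(its tail is 1). Because the cutoff is optimized, the score is not a
p-value; the exact p-value P(mHG ≤ score) over all C(N, B) equally likely
orderings is computed by a probability-space dynamic program on the
(n, b) lattice that tracks the mass of label paths avoiding the rejection
region. The rejection boundary is derived from a whole-lattice
log-gamma pmf with reversed cumulative sums (O(N·B)); the DP is verified
in tests against brute-force enumeration of all arrangements for every
N ≤ 12 and every B, and the invariants score ≤ p ≤ min(1, N·score) are
property-checked on random lists.

Motifs are called activating (up-significant only), repressing
(down-significant only), or undetermined, at a fixed α = 1e-4;
both-significant conflicts are flagged rather than silently assigned. The
sub-motif screen ranks observed (variant, sub-variant) records — reads
split by the concrete bases realized at K/M positions — and labels each
record for the exact sub-motif it realizes, so a mixed parent contributes
to each of its 2^k children separately while the parent-level screen
pools them.

## Expression models

**Motif-additive model (MAM).** fold = (1 + slope · Σ w_m) ×
attenuation^[any repressor], expression = core level × fold, with
w_m = −log10 of the motif's up-direction enrichment p-value. The
intercept is fixed at 1 so a motif-free cassette scores fold 1 exactly;
attenuation defaults to 0.5 (a single constant ×2 down-regulation,
independent of the repressor count); the default slope 0.25 is a
placeholder to be replaced by `fit_mam_calibration` (least squares of
measured folds on mean log10 p) on real cassette measurements. The linear
form of the calibration is a modeling choice: the data motivating it show
a linear fold-vs-log10(p) dependence, but no closed form is published.

**Convolutional models.** A 1D conv net (kernels → ReLU → global max
pool → dense ReLU → linear head, or 4-way softmax head for bin-
distribution targets) over one-hot sequences, uniform-padded with 0.25
per channel to the maximum input length; K/M design symbols may be
encoded as a 0.5/0.5 split over their pair channels. The hybrid "MLAM"
configuration concatenates a catalog-length motif-count vector after the
pooling layer, which also lets the model score sequences longer than the
training length. Training uses Adam (lr 1e-3, the framework-conventional
default, recorded in the frozen config), MSE on standardized scalar
targets or average-weighted cross-entropy on bin targets, and optional
sample weights proportional to read counts, normalized so the loss scale
is batch-invariant. Ensembles of independently seeded members are
averaged; everything is reproducible from one seed. Because no deep-
learning framework is assumed, the network is implemented directly in
numpy (im2col convolution, hand-written backprop); desk-scale defaults
are 64 kernels / ensemble 5, and `CNNConfig.paper_config()` restores the
full 1024-kernel / 100-member architecture. Training-set selectors: ADM
(total reads above a cutoff), AMM (deep-barcode variants), MBO (deep
variants containing ≥ 1 mixed-base motif; always a subset of AMM).

**Evaluation.** Pearson r with two bootstrap schemes: all subsets of size
n−2 for small validation panels (55 subsets at n = 11), or 100 seeded
random subsets of size 30 (16 for small panels).

## Simulator

The generator states a world and the tests measure against it; its
defaults are not tuned to outcomes. Per variant: latent log-expression
μ0 + Σ β_m·count_m + N(0, σ_v) with μ0 = log(1000) (a weak-promoter
baseline of ~1000 A.U.), σ_v = 0.1; single-cell log-fluorescence adds
N(0, σ_c) with σ_c = 0.6, a typical spread for single-cell reporter FACS.
Gates default to quartiles of the pooled distribution, emulating sort
gate placement; bin occupancies are Gaussian-tail differences. Per-bin
counts are multinomial across variants at the configured depth (default
50 reads/variant, matching the characterized deep subset); reads are
emitted as full oligos plus a fixed 42 nt synthetic downstream context
(so standard designs clear the 200 nt filter) with independent
substitution errors. The derived calibration uses exact truncated
log-normal bin means and pooled gate areas, closing the loop with the
quantifier.

What a green simulation test does establish: the pipeline recovers
planted effects of |β| = 1.5 σ_c at 50 reads/variant with correct sign at
p < 1e-4, calls nothing on null data, and the expression estimator
converges to its target. What it does not: real libraries add PCR bias,
sort impurity, growth between sort and sequencing, barcode-specific
effects and chromatin context, none of which are modeled.
`recovery_report` therefore distinguishes correlation with the binned
true expression (the estimator's infinite-depth target) from correlation
with exp(latent), which any 4-bin readout additionally compresses by gate
saturation.

## Numerical and degenerate-input choices

Zero-read variants are excluded from expression (flagged, not silently
dropped); zero-variance vectors give NaN correlations with a flag;
B = 0 lists score 1 with an undefined cutoff; rejection-region membership
uses a 1e-9 relative tolerance so the attained minimum is inside despite
float roundoff; barcode generation and desert design raise explicit
infeasibility errors when their seeded sampling budgets are exhausted.

## Known limitations

The bundled 41-motif catalog is a synthetic stand-in with the correct
composition (the published motif sequences are included verbatim; the
remainder are random), so catalog-dependent results are structural, not
biological. The paper-scale CNN configuration is exposed but not
exercised in tests. Bin-barcode demultiplexing uses exact prefix
matching; error tolerance is applied only to variant barcodes.
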