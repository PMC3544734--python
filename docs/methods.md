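# Methods

`csrnai` implements a compressed-sensing strategy for pooled RNAi screening:
instead of one siRNA per gene, a small panel of *group identifier* siRNAs —
19-bp motifs shared across several transcripts — interrogates a much larger
gene set, and the knockdown profile is recovered from the pooled readouts by
sparse optimization. The pipeline has four stages: motif ingest and consensus
extraction, effective-siRNA selection, sensing-matrix design, and signal
reconstruction.

## Sequence encodings

Three deterministic machine representations feed the feature extractors:

* **Binary indicator matrix (BIM).** An L×4 one-hot grid; positions index
  rows, channels index columns in the fixed order A, G, T, C.
* **Bit signal.** The codebook A→1000, G→0100, T→0010, C→0001 concatenated in
  sequence order: a 19-mer becomes a 76-sample binary signal.
* **Disk image.** The sequence wrapped around a disk of radius 4 fitted to a
  9×9 pixel grid centered at pixel (5,5): N equal angular sectors (N = length),
  the 4-bit code of each nucleotide laid radially, bit 1 innermost. Pixel
  membership uses polar coordinates about the central pixel; the sector index
  is floor(N·θ/2π) with θ counter-clockwise from the positive x-axis, radial
  bands are (0,1], (1,2], (2,3], (3,4] and the exact center belongs to
  (sector 0, band 1). Band tests use integer squared radii, so rasterization
  is platform-exact. The rounded shape is what makes cell-image texture and
  moment descriptors meaningful; sequences outside 15–25 bp rasterize poorly
  and trigger a warning.

RNA input (U) is normalized to T on ingest so one alphabet serves cDNA motifs
and siRNA sequences alike.

## Feature groups (combined dimension 1424)

| group  | dim | content |
|--------|----:|---------|
| PSF    |  20 | learned single-nucleotide position rules, signed match |
| SPSF   |  16 | learned dinucleotide position rules, signed match |
| TD     |  21 | nearest-neighbor thermodynamics |
| NGram  | 336 | contiguous 2/3/4-mer counts (16+64+256) |
| NGSK   | 336 | gap-weighted string-kernel 2/3/4-mer occurrences |
| PC     | 364 | position one-hot composition (19×4 + 18×16) |
| Image  | 132 | disk-image texture and moments (60+52+20) |
| Speech | 199 | cepstral/linear-prediction descriptors (91+84+24) |

**PSF/SPSF.** For every (position, pattern) pair a 2×2 presence table
(positive vs negative training siRNAs) is scored by the two-sided Fisher
exact test; the k smallest-p rules are kept (k = 20 single-nucleotide, 16
dinucleotide), each labeled *desired* (enriched among effective siRNAs) or
*undesired*. A rule evaluates to +1 on a desired match, −1 on an undesired
match, 0 otherwise — the signed encoding keeps both directions inside the
printed dimension. Ties break deterministically by (p, position, pattern).
The Fisher test is exact at the few-hundred-per-class sizes of siRNA
training sets.

**Thermodynamics.** The 18 positional stack ΔG°37 values of the duplex, the
whole-duplex ΔG (stack sum plus initiation), and the mean ΔG of the two
stacks at each end — low 5′-end stability of the guide strand is the classic
asymmetry signal of effective siRNAs. The default table is the Xia et al.
(1998) RNA nearest-neighbor set (kcal/mol), shipped as package data and
replaceable via TSV; no literature values are hard-coded in code paths.

**N-gram / N-GSK.** Words are enumerated lexicographically (A<C<G<T). The
gap-weighted variant credits every ordered, possibly non-contiguous match
with decay^gaps (default decay 0.5); decay 0 reduces exactly to the
contiguous counts, which the tests exploit as an oracle. Counting is by
exhaustive subsequence enumeration — exact and affordable at L = 19.

**Image.** On the disk image: a Gabor filter bank at 5 spatial frequencies
(0.1–0.5 cycles/pixel) × 6 orientations, mean and standard deviation of each
response magnitude (60); Haralick's 13 co-occurrence statistics at the 4
unit offsets of a 2-level GLCM (52); Zernike moment magnitudes through order
7 on the inscribed disk (20). Degenerate (constant) images yield zeros, never
NaN: entropies use 0·log 0 = 0 and correlation statistics fall back to 0 when
a marginal is deterministic.

**Speech.** The 76-sample bit signal is framed (length 16, hop 10 → 7
frames). Per frame: 13 mel-cepstral coefficients (20 triangular filters on
the half band at nominal sampling rate 1, DCT-II, log-energy coefficient
excluded) and 12 linear-prediction coefficients by Levinson–Durbin (84
total). On the whole signal: 12 perceptual linear-prediction cepstra
(Bark-warped critical-band integration, equal-loudness weighting, cube-root
compression, all-pole fit, LPC→cepstrum recursion) plus their first
differences between the two signal halves (24). All-zero frames fall back to
zero coefficients. At the nominal unit sampling rate the mel and Bark warps
are nearly linear; they are retained for structural fidelity to the
speech-processing pipeline, and every parameter above is pinned for
bitwise determinism. Filter counts, frame geometry and model orders were
chosen once to realize the published group sizes and are exposed as module
constants.

## Classification and feature selection

Activities in [0,1] are thresholded into +1 (≥ high) / −1 (≤ low) classes;
three default cutoff pairs (0.3, 0.7), (0.4, 0.6), (0.5, 0.5) span strict to
inclusive labelings. The margin classifier is a linear-kernel SVM (exact QP
via scikit-learn's SVC, C = 1) on per-column standardized features;
standardization is fit on training data only and folded back into the stored
weight vector. A margin of exactly 0 is called negative — the conservative
siRNA call.

SVM-RFE refits the classifier on the surviving features, ranks by squared
weight, and eliminates the lowest 10% per step (at least one feature). The
stratified-CV accuracy of every surviving set is recorded on folds fixed
once from the seed; the selected subset maximizes CV accuracy, ties going to
the smaller set. Per-fold models train only on their fold's training
indices, and SHA-256 digests of those index sets are kept in the result for
leakage auditing. The elimination ranking itself is computed from a fit on
the full training matrix, standard practice for this procedure.

## Network pruning and the sensing matrix

Each motif's **maximum consensus sequence** (MCS) is the per-position modal
nucleotide over its occurrence sites, ties to the alphabetically smallest.
Pruning iterates to a fixed point over three rules, each recorded in an
audit log:

1. motifs whose MCS is near-homopolymeric (modal nucleotide ≥ 80% of
   positions, configurable) are discarded — such probes match everywhere and
   identify nothing;
2. genes sharing an identical motif-membership signature are collapsed to
   one seeded-random survivor — identically covered genes are
   indistinguishable from any readout;
3. strict 1-to-1 motif–gene pairs are removed — a dedicated probe is
   conventional screening, not compressive.

The sensing matrix Φ (rows siRNAs, columns genes) holds the percent identity
between the motif's MCS and its occurrence site on that gene (best site if
several), zero where the motif does not hit the gene. Columns are then
scaled to unit Euclidean norm, the normalization the recovery guarantees
assume; pruning precedes normalization so no column is normalized against
entries that are later dropped. Occurrence coordinates are 0-based,
half-open, forward strand; a complement toggle serves motifs discovered in
mRNA space.

Diagnostics: the mutual coherence M_Φ (largest absolute inner product among
distinct columns, with the full pair histogram at bin width 0.1), and the
exhaustive restricted-isometry constant δ_S (worst eigenvalue deviation of
any ≤S-column Gram submatrix from 1, enumeration guarded by a 10⁶-subset
budget). For unit columns δ₂ equals M_Φ exactly — a cross-check the test
suite enforces to 1e−10.

## Sparse recovery

Given y = Φx + e with ‖e‖₂ ≤ ε, the profile is recovered by basis pursuit
denoising: minimize ‖x‖₁ subject to ‖Φx − y‖₂ ≤ ε. The solver minimizes the
penalized surrogate ½‖Φx − y‖² + λ‖x‖₁ by FISTA with monotone restart,
walking λ down from 0.9·‖Φᵀy‖∞ (halving, warm-started) until the residual
enters the discrepancy band ε ± 1%, with a log-scale bisection on λ to land
inside it; for ε = 0 the band is numerical zero (1e−9 relative). The inner
iteration stops on the subgradient optimality condition (violation ≤ 1e−8
relative to the penalty), not on iterate change: relative-change criteria
provably stall far from the minimizer when the penalty is tiny, which an LP
basis-pursuit cross-check exposed during development. Iteration cap 10⁴ per
inner solve; non-convergence is flagged on the result, never silent.

**Debiasing** (on by default for simulation reporting) refits least squares
on the detected support. Detection gates at max(1e−6·‖x‖∞, 3ε/√m): spurious
coefficients of the l1 solution at the discrepancy penalty sit at exactly
the per-component noise scale ε/√m, and refitting on them would fit noise.
The refit residual legitimately fluctuates around ε (it equals the
off-support noise component), so it is accepted whenever the support is
nonempty. Components below three noise standard deviations are statistically
undetectable and are the price of the gate. A `nonnegative` flag swaps in
the one-sided prox for users who want the physical constraint that knockdown
strengths are nonnegative; the generic solver does not impose it.

The exhaustive minimum-support program (P0) — least squares over every
support up to a size cap — serves as an oracle on small instances. The
recovery guarantee δ_3S + 3δ_4S < 2 (under which the l1 solution's error is
bounded by a constant times ε) is checked exhaustively. Note that for
matrices with m ≤ 6 rows this condition is only attainable near the simplex
equiangular frame (m+1 unit vectors at mutual inner product −1/m; at m = 6,
δ₃ = 1/3 and δ₄ = 1/2); random unit-column matrices at these sizes never
satisfy it, which is why the oracle-equivalence tests draw jittered,
randomly rotated simplex frames and filter on the verified condition.

## Simulation harness

Signals are K-sparse by construction: n components drawn U(0,1), all but the
K largest zeroed. Readout noise is i.i.d. Gaussian with standard deviation σ
(the conservative reading of the noise specification), the residual bound is
the expected noise norm ε = σ√m, and SNR is defined as
10·log₁₀(‖Φx₀‖²/(mσ²)). The low-coherence reference matrix concatenates
three random orthonormal bases of R⁴⁸ plus two unit-normalized Gaussian
columns to reach 48×146. The sparsity-from-coefficient rule K = c·m/ln n is
provided literally, with a base-10 variant and a c·√m/log₁₀ n variant (the
only one of the three that yields K = 3, 4, 5, 6 at c = 1, 1.2, 1.5, 2 for
this shape — an observation, not a claim about the rule's intent); sweep
drivers take K values directly. Every sweep cell derives its generator from
(seed, K, σ-index, rep), so tables are bit-reproducible and any cell can be
recomputed in isolation.

Reported problem sizes: the ideal-example experiment runs 50 repetitions at
K = 3, σ = 0.001; the MSE/SNR sweep in the acceptance suite runs
K ∈ {3,4,5,6} × 3 noise levels × 100 repetitions — adjacent sparsity levels
differ by ~25% in mean MSE, which smaller samples do not resolve against
repetition-level noise.

## Synthetic data

The generators make the pipeline testable without downloads and ship
machine-readable ground truth.

* **Motif planting** writes mutated motif copies (bounded substitution
  counts) at collision-free offsets into i.i.d. background genes at a
  requested GC content. Pseudo p-values (mismatches+1)/(width+1) order
  occurrences by match quality — the pipeline never consumes their
  magnitudes, only their order. The screening-scale fixture (48 motifs × 146
  genes, 6 perfect + 3 five-mismatch occurrences per motif, targets dealt
  least-covered-first so every gene is hit by 2–3 motifs) exercises the full
  pipeline in seconds.
* **Activity generation** scores random 19-mers by planted position terms
  plus a weighted duplex ΔG, adds Gaussian noise on the logit scale (no
  truncation artifacts), and maps through the logistic function centered at
  the rule's analytic expectation under uniform sequences.

What the generators do not emulate: real EST/motif-discovery statistics
(E-values, overlapping and palindromic motifs), position-dependent
mutational structure, off-target thermodynamics, and the correlated activity
noise of bench measurements. Passing tests therefore demonstrate that the
machinery is correct and that planted structure of realistic effect size is
recovered — not that the feature set predicts real siRNA efficacy at any
particular accuracy.

## Known limitations

* The supplementary parameterizations of the image/speech extractors are
  pinned to reproduce the published group sizes; their individual feature
  *values* are this package's convention.
* δ_S enumeration is exponential and guarded; large-matrix isometry can only
  be probed by subsampling columns.
* The end-to-end pipeline defaults to no RFE on the combined 1424-dim space
  (it is available but slow at full scale); rule learning and classification
  run on all features by default.
* Real screening data (the published 2431-siRNA activity set, EST libraries,
  discovered motif tables) are not bundled; the package ingests their
  formats and the synthetic generators emulate their structure.
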