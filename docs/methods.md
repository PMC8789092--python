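# Methods

## Model

`helixcycle` estimates cell-cycle pseudotime from a genes × cells expression
matrix by learning a constrained 3-dimensional linear embedding. Let
X ∈ R^{D×N} be the log-normalized matrix (genes centered), W ∈ R^{D×3} an
orthonormal basis (WᵀW = I) and Z = WᵀX the embedded cells. Each embedded
cell is attracted to a circular helix

    Ẑᵢ = (v·θᵢ, a·sin θᵢ, a·cos θᵢ),    a > 0, v > 0,

whose circular cross-section models the cyclic part of the transcriptional
program and whose axis carries progression; a soft-clustering term groups
cells of the same phase. The joint objective is

    min  Σᵢ ‖Xᵢ − WZᵢ‖² + λ Σᵢ ‖Zᵢ − Ẑᵢ‖²
         + γ [ Σₖ Σᵢ r_{ik} ‖Zᵢ − Yₖ‖² + σ Σᵢₖ r_{ik} log r_{ik} ]

subject to WᵀW = I, rows of R on the simplex. Pseudotime is the min–max
normalization of θ; discrete G1/S/G2M calls come from a univariate
3-component Gaussian mixture on pseudotime.

## Optimization

Alternating structure optimization, one cycle per iteration:

1. **Helix fit** (warm-started): block coordinate descent on (a, v, θ).
   Given θ, closed forms v = Σxᵢθᵢ/Σθᵢ² and a = Σ(yᵢ sin θᵢ + zᵢ cos θᵢ)/N,
   each clamped at ε = 1e-8 to keep a, v > 0; given (a, v), each θᵢ
   minimizes a smooth 1-D function via a 256-point grid on
   [xᵢ/v − 2π, xᵢ/v + 2π] followed by damped Newton steps. Rounds stop when
   the residual change drops below 1e-10 (max 50 rounds); every candidate is
   accepted only if it does not worsen the fit, so a warm start can never
   increase the residual.
2. **Responsibilities**: r_{ik} ∝ exp(−‖Zᵢ−Yₖ‖²/σ), computed with
   max-subtraction; underflowed entries are lifted to the smallest positive
   float and rows renormalized.
3. **Q solve**: Q = [(1+λ+γ)I − γRΓ⁻¹Rᵀ]⁻¹ with Γ = diag(1ᵀR). The matrix
   is symmetric positive definite (RΓ⁻¹Rᵀ is PSD with spectral norm ≤ 1, so
   the smallest eigenvalue is ≥ 1+λ); it is applied through a Cholesky
   solve, or through the N×K Woodbury factorization beyond 2000 cells
   (agreement with the dense solve is tested to 1e-8).
4. **Basis**: W = V_thin Uᵀ from the thin SVD of A = ẐQXᵀ — the orthogonal
   Procrustes maximizer of tr(AW) over the Stiefel manifold, attaining the
   nuclear norm of A. Under repeated singular values the maximizer is not
   unique; the factorization LAPACK returns is accepted as-is.
5. **Embedding**: Z = (WᵀX + λẐ)Q, the exact minimizer of the working
   objective over Z with Y eliminated.
6. **Centroids**: Y = ZRΓ⁻¹.

Each step exactly minimizes its block, so the objective trace is
non-increasing (tested with 1e-9 relative slack). Convergence: relative
objective change < 1e-6 (configurable), max 200 iterations.

## Initialization

The paper-facing updates above need a starting point; this package uses a
deterministic one:

- Genes are centered (the linear model WZ has no intercept) and W, Z are the
  top-3 principal axes/scores with a fixed sign convention (largest-magnitude
  loading positive).
- A PCA embedding is an arbitrarily rotated — possibly mirror-handed — copy
  of any helix structure in the data, and the model's helix is axis-aligned,
  origin-centered, phase-pinned and of fixed handedness. The initialization
  therefore searches 64 Fibonacci-sphere axis candidates (each also
  reflected) scored by a short free-center helix fit, polishes the winner by
  alternating helix fits with Procrustes re-rotation, and folds the fitted
  center into the centering vector (X is re-centered on means + Wt, which
  preserves Z = WᵀX and the exact reconstruction of low-rank data). This
  matters because the λ-dominated updates quickly snap Z onto the initial
  helix: θ errors present at initialization change only very slowly
  afterwards.
- During initialization, θ updates are Newton-only (no grid): free grid
  jumps across turns admit a degenerate near-circle fit (v → 0 with cells
  scattered over many turns) that can undercut the true helix residual.
- Cluster centroids Y come from seeded k-means on the embedded cells.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | 50 | helix-fidelity weight |
| γ (`gam`) | 50 | clustering weight |
| σ (`sigma`) | 0.001 | entropy temperature of soft assignments |
| K | 3 | clusters (one per phase) |
| d | 3 | embedding dimension (fixed by the helix) |
| `tol` / `max_iter` | 1e-6 / 200 | convergence criteria |

{50, 50, 0.001} is the operating point used when no ground truth is
available. With labeled data, `tune_parameters` performs the fix-two-tune-one
coordinate search with stage-call accuracy as the criterion.

With σ as small as 0.001 the responsibilities are effectively hard, and the
γ-weighted term deliberately contracts within-cluster spread in the
embedding (by roughly 1/(1+λ) at the defaults). That is what makes stage
calls crisp; it also quantizes fine within-cluster ordering, which is why
the pseudotime rank-recovery checks are run on data where the helix
geometry, not the clustering, is the binding constraint.

## Pre-processing

Values are transformed as log2(x + 1). Genes expressed (value > 0) in
strictly fewer than 5% of cells are removed; among the survivors the 2000
most dispersed genes (variance/mean on the unlogged scale) are kept.
Dispersion-based selection is a deterministic stand-in for a
differential-expression-driven gene selection step; the optimizer is
agnostic to how genes were chosen. Filtering runs after normalization; the
dispersion is computed on unlogged values.

## Stage assignment

The 3-component univariate Gaussian mixture is fit by EM with deterministic
initialization at the 1/6, 3/6, 5/6 quantiles of pseudotime, equal weights,
equal spreads; variance floor 1e-6, at most 500 iterations, log-likelihood
tolerance 1e-8. Components sorted by mean map to (G1, S, G2M) — phase order
along pseudotime is fixed by construction. A degenerate fit (a component
weight below 1/(10N)) triggers one jittered re-initialization before
erroring. EM is hand-rolled because this initialization/degeneracy contract
is part of the method's determinism guarantee; agreement with a standard GMM
implementation on separated data is covered by a test. Quantile
initialization makes the fit equivariant under positive affine maps of
pseudotime (up to the absolute variance floor, which essentially never
binds), so fitting on normalized pseudotime rather than raw θ is
inconsequential. Which end of the axis is G1 is not identifiable from
geometry; orientation defaults to as-fitted and can be set with G2/M marker
genes (the orientation in which mean marker expression rises with
pseudotime is kept).

## Synthetic data

`simulate_cycle` emulates a cyclic 3-phase process embedded linearly in gene
space: phase arcs split [0, 2π) proportionally to the phase fractions
(default 0.5/0.25/0.25, G1-dominant); θ is truncated-normal around each arc
midpoint with sd 0.3 × arc width (cells concentrate near
phase-characteristic states; `None` gives uniform arcs); the helix point
(default a = 1, v = 0.5) maps to log2 expression through a random
orthonormal D×3 basis scaled by √D so a typical gene swings ~1 log2 unit
over the cycle (`gene_amplitude`); per-gene baselines are Uniform(3, 8) in
log2 (counts roughly 8–256, mid-depth scRNA-seq); Gaussian noise
(default sd 0.1) is added before exponentiation and Poisson sampling.
Features of real data it does not emulate: library-size variation,
batch effects, gene–gene correlation beyond the helix, and
expression-dependent overdispersion — passing recovery tests show the
estimator handles the geometry, dropout and counting noise, not those
nuisances.

`simulate_cidr_like` generates three discrete cell groups (150 cells ×
20,180 genes by default), each up-regulating its own 50 marker genes by a
lognormal fold change (meanlog 1.0, sdlog 0.4) over a shared lognormal
baseline (meanlog 2.0, sdlog 1.5), with Gamma–Poisson counts (size 2.0,
giving ~13% intrinsic zeros at this design). Dropout zeroes an entry with
log1p-expression u with probability sigmoid(s·(u0(v) − u)), s = 1; the
midpoint u0(v) is a monotone piecewise-linear curve through three knots
calibrated once (scripts/calibrate_dropout.py) so v ∈ {6.5, 9, 12} yields
overall zero fractions of 25.6%, 51.1% and 68.8% at the default design.
v = 0 is dropout-free by convention. Group index stands in for phase in the
ground truth.

## Cell-cycle effect removal

Per gene, r² = SS_between/SS_total of the one-way decomposition of log2
expression over stage groups (constant genes: r² = 0; empty stages
ignored). Genes at or above a threshold (default 0.05, deliberately
conservative and exposed on the CLI) are removed. Under random labels
E[r²] = (K−1)/(N−1), which the tests use as a null check.

## Evaluation

Seven multiclass metrics: accuracy and macro precision/recall/F1 are
computed after a Hungarian matching of predicted to true labels (stages are
unsupervised clusters; classes absent from the matched prediction
contribute 0 to macro averages); Rand index, adjusted Rand index and NMI
(arithmetic-mean normalization) are computed on raw partitions. Gene–
pseudotime association uses Pearson correlation with the two-sided t-test
p-value; pseudotime-by-phase separation uses one-way ANOVA.

## Problem sizes and determinism

Recovery and monotonicity checks run at D = 30–200 genes and N = 40–150
cells, the scale at which the properties they probe are already binding;
the dropout-calibration checks run the full 150 × 20,180 design. Every
stochastic component (generators, k-means, GMM jitter) takes an explicit
seed and is bit-reproducible under it.

## Known limitations

- The helix fit is non-convex; the θ grid makes each 1-D update reliable,
  but the global axis alignment is found only at initialization. Data whose
  cyclic signal is not approximately linearly embedded (deep nonlinear
  manifolds) will not be recovered.
- With the default near-hard clustering, pseudotime is locally quantized
  around cluster centroids; fine ordering within a phase is better probed
  with a small γ.
- Orientation (which end is G1) and the zero-point of the cycle are not
  identifiable without markers.
- The dropout calibration constants are specific to the default CIDR-like
  design; other designs should use `dropout_level_for_rate` to pick levels
  by target rate.
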