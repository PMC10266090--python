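# Methods

This note records the models, conventions, and numerical choices behind
`rmtfc`, in the spirit of a statistics package's model documentation: what
is computed, under which assumptions, which knobs matter, and what the
synthetic-data experiments do and do not demonstrate.

## Correlation spectra via the dual problem

For a scan matrix `M` (`N` voxels x `t` volumes, rows non-constant), the
Pearson correlation matrix of the rows is `C = Z Zᵀ/(t−1)` with `Z` the
row-centered, row-scaled data.  `rmtfc` never forms `C`: the nonzero
eigenvalues of `Z Zᵀ` equal those of the `t x t` Gram matrix `Zᵀ Z`, so
`correlation_eigenvalues` diagonalizes `Zᵀ Z/(t−1)` (cost `O(N t²)`,
memory `O(t²)`) and returns its `t` eigenvalues sorted ascending.  The
omitted `N − t` eigenvalues of `C` are exactly zero and carry no
information.  Row standardization removes one degree of freedom, so
generic data has exactly `t − 1` levels above numerical precision — a
property the test suite checks against a brute-force `N x N`
eigendecomposition.  When `t ≥ N` the direct eigenproblem is solved
instead (same nonzero spectrum), with a warning.

## Trimming

Four variants operate on the sorted spectrum:

- `none` — identity.
- `precision` — removes eigenvalues at or below
  `max(n·ε·max|λ|, ε·‖λ‖₂)` (the matrix-rank convention and the
  symmetric-eigenproblem error bound; the larger of the two per matrix),
  i.e. values indistinguishable from zero in floating point.
- `largest` — correlation spectra of `t << N` data grow roughly
  exponentially, so 2-means clustering is run on the *logs* of the
  precision-trimmed eigenvalues (10 restarts, seed derived from a CRC of
  the input bytes so results are reproducible without global state) and
  the cluster with the larger mean — the few dominant modes — is removed.
  If the logs are all equal, or the rule would remove more than half the
  spectrum, the trim degenerates to no-op with a warning: destroying the
  bulk is never the intent of outlier trimming.
- `middle` — mirrors the `largest` count at the lower end, removing the
  same number of smallest surviving eigenvalues.

Trimming always returns a contiguous subsequence of its input (a tested
invariant).

## Unfolding

Fluctuation observables are only meaningful after the system-specific mean
level density is removed.  `unfold` fits a polynomial `p` of degree
`d ∈ {3, 5, 7, 9}` (other odd degrees accepted) to the empirical staircase
points `(λ_i, i)`, `i = 1…n`, and maps `e_i = p(λ_i)`.  Because
`p(λ_1) ≈ 1` and `p(λ_n) ≈ n`, the unfolded mean spacing is ~1; the test
suite enforces `[0.9, 1.1]` for every spectrum with `n ≥ 50`.  The fit
target is the cumulative level count — the standard smoothing of the
spectral staircase — rather than any parametric density.  The fit runs in
numpy's rescaled polynomial domain, which keeps the Vandermonde system
well conditioned even for exponentially growing spectra.  A fitted
polynomial that is non-monotone over the data range (possible for
degree ≥ 5 on spectra with dense bulks) does not fail: outputs are
re-sorted and the result carries a `monotone=False` flag.  Only
polynomial unfolding is implemented; exponential-family fits are out of
scope.

## Spectral rigidity and level number variance

Both observables average a window statistic over starts `c` drawn
uniformly from `[e_1, e_n − L]`:

- `Δ₃(L)`: within `[c, c+L]`, the staircase `η(λ)` (number of levels
  ≤ λ) is fit with a straight line in the *continuous* least-squares
  sense, and `(1/L)∫(η − Aλ − B)²` is evaluated **exactly** by piecewise
  integration over the step intervals.  There is no quadrature grid and
  hence no discretization knob.  Per window, coordinates are shifted to
  `[0, L]` so every moment is `O(L)` and no cancellation occurs for large
  level indices; across windows the segment sums reduce to prefix-sum
  differences, so a block of window starts is evaluated with a handful of
  vectorized operations.
- `Σ²(L)`: the variance over `c` of the number of levels in the
  *half-open* window `[c, c+L)`.  Half-open counting makes the
  picket-fence case exactly zero for integer `L` and avoids double
  counting at window edges.

**Convergence.**  Window starts are sampled in blocks of 128 until the
estimator's own standard error falls below the requested relative
tolerance (`tol`, default 0.01): for the rigidity this is the standard
error of the running mean; for the level variance, the asymptotic
standard error of the sample variance, `sqrt((μ₄ − σ⁴)/k)`, computed from
running power sums up to the fourth moment.  Sampling stops when
`2·SEM ≤ tol·estimate` (or at `max_centers`, default 10⁵, in which case
the curve is flagged unconverged rather than failing).  A simpler
running-mean-change criterion was rejected: the trajectory of a running
variance estimator is strongly autocorrelated, and change-based rules
systematically stop early — in measurements, with 8% residual error at a
nominal 1% tolerance.  The standard-error rule keeps the converged
estimates within twice the tolerance of an exhaustive dense-grid
evaluation, which the test suite verifies against an independent
loop-based oracle on spectra of 500 levels.

Both observables use `L ∈ {1, …, 20}` on the analytic grid, take explicit
seeds, and record per-`L` center counts, convergence flags, and the
achieved standard-error bound.

**Reference ensembles.**  `simulate_goe(n)` diagonalizes `(G + Gᵀ)/2`
with `G` iid standard normal (off-diagonal variance ½, diagonal 1);
its scaled spectrum follows the Wigner semicircle on `[−√(2n), √(2n)]`
and its unfolded spacings the Wigner surmise
`p(s) = (πs/2)·exp(−πs²/4)`.  `simulate_poisson_levels(n)` cumulates
iid Exp(1) spacings and is unfolded by construction, with the closed
forms `Δ₃(L) = L/15`, `Σ²(L) = L` as `n → ∞`.  Both are validation
utilities, not analysis paths.

## Feature catalog

24 eigenfeatures + 10 baselines.  Eigenfeature components: `eigs` (the
trimmed spectrum), `eigs_smooth`/`eigs_savgol` (uniform / Savitzky-Golay
smoothed spectrum), `eigsminmaxF` (both F% tails, concatenated),
`eigsmiddleF` (central F%), `unfolded`, `rigidity`, `levelvar`.  A `+` in
a feature id means concatenation, and slicing is applied per component
before concatenation.  Conventions:

- **Slices** (10): full; first/last 5, 10, 20%; middle 10, 20, 40% — of
  the ascending-sorted feature.  Slice length is `ceil(f·n)` (never
  empty, even for 20-point observable curves at 5%), and middle slices
  start at `floor((n−k)/2)`.
- **Smoothing**: uniform smoothing is a centered moving average with
  truncated (shrinking) windows at the boundaries, preserving length;
  Savitzky-Golay uses polynomial order `min(2, w−1)` so the window-3
  variant remains valid; window 1 is the identity.
- **Degree sharing**: the analytic grid has a single degree axis with
  values {3, 5, 7, 9}; it is the unfolding polynomial degree for RMT
  components and the smoothing window for the smoothed-eigenvalue
  features.  Within a combined feature, one (trim, degree) pair applies
  to all components.
- **Baselines**: ten voxel-axis reductions per time point (mean, median,
  max, min, 5th/95th percentile, sample standard deviation, max−min,
  p95−p05, interquartile range), each a `t`-dimensional curve, uniformly
  smoothed with window ∈ {1, 2, 4, 8, 16}.  Percentiles interpolate
  linearly between order statistics.
- **Normalization**: eigenfeatures always receive a natural log (their
  distributions are close to exponential; the base is immaterial and
  recorded); values ≤ 0 — possible only under `trim="none"` — are
  clipped to the precision threshold first, with a warning.  Optional
  min-max maps each feature dimension to [0, 1] with statistics fit on
  the training fold only; constant dimensions map to 0.  Baselines skip
  the log.

## Multiverse evaluation

The eigenfeature grid is 4 preprocessing levels x 2 normalizations x
4 trims x 4 degrees x 10 slices = 1280 cells; baselines use
4 x 2 x 5 windows = 40.  With the catalog's 24 + 10 features, 11 binary
tasks, and 6 classifiers, the full design is 2,053,920 evaluations; the
package computes this accounting exactly and runs arbitrary sub-grids.

Each cell is scored by stratified fivefold cross-validation (stratified
because several tasks are imbalanced; single split, fixed seed; if a fold
ever lacks a class the split is retried with the next seed).  Classifiers
are scikit-learn defaults: gradient-boosted trees, random forest, RBF
support-vector classifier, and k-nearest-neighbours with k ∈ {3, 5, 9}.
AUROC uses continuous class-1 scores (probabilities or decision values —
k-NN contributes neighbour-vote fractions); accuracy, adjusted accuracy,
and F1 are collected alongside.  Adjusted accuracy is accuracy minus the
majority-class proportion, so positive values beat majority guessing.  A
constant feature matrix is flagged degenerate and scored mAUROC = 0.5.
Per-cell seeds derive from the root seed and the cell's provenance tuple,
so results are identical regardless of evaluation order.

Per-matrix trimming can leave scans with slightly different feature
lengths inside one cell; vectors are center-cropped to the common minimum
length before stacking, keeping the shared central region of the
spectrum.  Distribution summaries report mean/min/5%/50%/95%/max/std with
linear-interpolation percentiles.  The predictability screen declares a
task *not* solvable when the mAUROC distribution is roughly symmetric
about 0.5 (|mean − 0.5| and |median − 0.5| < 0.02, |skewness| < 0.2) or
has both median and KDE mode (Gaussian kernel, Silverman bandwidth) below
0.5; all thresholds are keyword-configurable, and fewer than 30 values
returns "insufficient evidence".

## Synthetic data generator

`SyntheticSpec` defines the study conditions: `n_per_group` scans per
group (default 20), spatial grid + volumes (default 8x8x8 voxels,
t = 48 — so `t << N` and scan spectra have `t − 1 = 47` levels, enough
for observables on `L ≤ 20`), `n_latent` shared signals (default 5),
`noise_sd` (default 1.0), and a planted `effect ≥ 0`.

Each scan is `x_v(t) = a_g · Σ_k w_{vk} s_k(t) + ε`, with smooth
unit-variance latent signals `s_k` (low-frequency random Fourier sums),
spatially blurred Gaussian loading maps `w` scaled to variance
`1/n_latent` (per-voxel signal variance ≈ noise variance — a deliberately
moderate signal-to-noise regime), and group strength `a = 1` or
`1 + effect`.  `effect = 0` makes the groups exchangeable (the null);
larger effects shift the dominant correlation eigenvalues up and — since
the correlation trace is fixed at `N` — press the noise bulk down, so
every region of the spectrum carries some group signal.  Four
"preprocessing levels" per scan are emitted as labelled variants (linear
drift shrinking with level, plus mild temporal smoothing), exercising the
grid axis without claiming to emulate a real fMRI pipeline.  Generation
is bit-reproducible from the spec's seed, in memory or as NIfTI files
plus a tab-delimited manifest.

**What passing tests show — and do not.**  The generator produces wide,
low-rank, noisy matrices with a controllable spectral group difference;
it does not reproduce BOLD autocorrelation, physiological confounds, head
motion, scanner drift structure, spatial non-stationarity, or realistic
anatomy.  End-to-end recovery results (planted effect → median mAUROC
above 0.9; null → mean mAUROC ≈ 0.5; performance monotone in effect
size) therefore validate the *pipeline's correctness and calibration*,
not any claim about real-data effect sizes.

## Problem sizes and runtime choices

The test suite and acceptance script use: 50 random instances (N ≤ 60,
t ≤ 12) for the transposition identity; 10 Poisson spectra of 10⁴ levels
for the closed-form limits; GOE spectra of 2000 (Wigner surmise) and 5000
(observable ordering) levels; 500-level spectra for the
Monte-Carlo-vs-oracle comparison; and synthetic datasets of 20 scans per
group (10 per group, 20 replicates per effect size, for the monotonicity
check).  These sizes put every stochastic check several standard errors
inside its tolerance while keeping the whole suite around a minute of
compute.

## Known limitations

- The `largest`-trim cluster split inherits k-means' behaviour on
  spectra without a clear bulk/outlier gap; the >50% safeguard bounds the
  damage but the split point itself is data-dependent.
- Polynomial unfolding of sharply bounded densities (e.g. the semicircle
  edge) distorts the extreme tails; observables on `L ≤ 20` windows are
  insensitive to this in practice, but tail-slice features of `unfolded`
  partly reflect fit behaviour rather than physics.
- Scan-level cross-validation is the default; for multi-run subjects the
  optional ``groups`` argument switches to stratified *group* folds so no
  subject straddles a train/validation boundary, but nothing detects the
  need automatically.
- The multiverse harness evaluates cells independently and is trivially
  parallel, but the implementation is serial; at desk scale (dozens of
  scans, hundreds of cells) this is seconds to minutes.
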