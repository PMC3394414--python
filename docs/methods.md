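# Methods

This note documents the models, the numerical choices, and what the test
fixtures do and do not establish about real molecular-dynamics data.

## Model and assumptions

All estimators model a covariate matrix `D` (t frames × n covariates) as
draws from multivariate Gaussians. The modelling assumptions are:

- **Harmonicity.** A single Gaussian describes fluctuations within one
  basin well; it cannot represent multi-modal (anharmonic) motion. The
  time-varying and Markov-chain estimators relax this by tiling the
  trajectory with locally Gaussian models, but each window model is still
  uni-modal.
- **Linearity.** Only linear correlations are captured; nonlinear couplings
  appear, at best, as weak linear shadows.
- **Covariate choice.** The default covariate is the per-residue C-α
  displacement magnitude relative to a reference frame after rigid-body
  superposition. Magnitudes give one variable per residue, matching
  residue-level network interpretation; signed x/y/z components (`xyz`
  mode) triple the dimension and retain directionality. Superposition
  defaults to on because without it global tumbling dominates and swamps
  internal motion; it can be disabled for pre-aligned trajectories.

## Sparse estimation

The penalized objective `log|P| − tr(SP) − λ‖P‖₁` penalizes **all** entries
of the precision `P`, diagonal included; this matches the dual
initialization `W⁰ = S + λI` and makes the diagonal of the solution exactly
`S_ii + λ`. The sample covariance uses `1/t` scaling, which makes `tr(SP)`
a per-frame average and keeps λ comparable across trajectory lengths; a λ
tuned against an unscaled covariance on another dataset will not transfer.

The solver maximizes the dual `log|W|` over the box `‖W − S‖∞ ≤ λ`. Each
column update solves `min_y { yᵀ(W_¬j¬j)⁻¹ y : ‖y − S_j‖∞ ≤ λ }`. Note the
**inverse** of the retained block: that is the form consistent with the
duality derivation (the Schur complement of `W` after replacing column j is
`W_jj − yᵀ(W_¬j¬j)⁻¹y`, so minimizing the quadratic maximizes `log|W|`).
The box-constrained quadratic is solved through its own dual, the lasso
`min_z zᵀBz − 2S_jᵀz + 2λ‖z‖₁` with `B = W_¬j¬j` and `y = Bz`, by cyclic
coordinate minimization (relative tolerance 1e-10). Convergence of the
outer loop is certified by the duality gap
`tr(W⁻¹S) − n + λ‖W⁻¹‖₁ ≤ ε`, default `ε = 1e-6·n`, sweep cap 200; budget
exhaustion is flagged on the result, never silent.

The returned precision is assembled from the converged lasso coefficients
(`P_jj = 1/(W_jj − y·z)`, `P_j = −zP_jj`) rather than by densely inverting
`W`: coordinates soft-thresholded to zero become exact zeros instead of
inversion noise at the gap level, so the edge set is well defined under the
default `1e-8` edge threshold.

Properties maintained and asserted in tests: every iterate is symmetric
positive-definite and dual-feasible; `log|W|` is non-decreasing sweep to
sweep; with `λ = 0` the feasible set collapses to `{S}`; larger λ never
produces more edges.

`default_lambda(t, n, α)` is the Student-t tail construction
`λ = max_{i<j} σᵢσⱼ · q / sqrt(t − 2 + q²)` with `q` the upper
`α/(2n²)` t-quantile on `t − 2` degrees of freedom: it bounds by α the
probability of introducing any edge between truly non-adjacent variables,
decreases in `t`, and increases as α tightens. Without supplied scales,
unit variances are assumed (standardized covariates).

## Time-varying estimation

Windows are non-overlapping and contiguous with stride = width; a trailing
partial window is dropped and logged. Kernel weights falling off the
trajectory edge are excluded and the remainder renormalized to sum 1, so
`S(τ)` is always a convex combination of window covariances (symmetric PSD
by construction). The per-window mean uses the same weights as `S(τ)` for
internal consistency. One λ is shared across windows. The `sawtooth_kernel`
family is one-sided and trailing: offsets `0, −1, …, −(depth−1)` with each
older window at half the weight of the one after it (depth 2 → 2/3, 1/3;
depth 3 → 4/7, 2/7, 1/7 ≈ 0.57/0.29/0.14). Consecutive window solves are
warm-started from the previous `W`; the dual optimum is unique (strictly
concave objective on a convex box), so warm starting affects only the path
taken, not the solution.

## Kinetics

The symmetric KL matrix is computed in closed form for all pairs at once
(the log-determinant terms cancel in the symmetrized divergence); entries
are clipped at 0 to remove negative round-off. Complete-linkage clustering
is delegated to scipy's agglomerative implementation and cluster ids are
relabelled by first temporal appearance, giving deterministic, order-stable
labels. `suggest_k = ceil(ln T)` encodes the assumption that sub-states are
separated by energy barriers crossed with exponentially small probability,
so the visited-state count grows logarithmically in the number of window
models; it is a heuristic and always user-overridable.

Transition probabilities are raw row-normalized counts of consecutive
window-cluster pairs — no smoothing, matching the counting definition. A
state with no outgoing transitions (possible only for the cluster of the
final window) becomes a self-loop with a warning; any smoothing prior would
invent kinetics the data does not contain. The representative model of a
state is the cluster **medoid** under symmetric KL (smallest summed
distance to members); refitting a pooled model per cluster would also be
defensible, but the medoid is guaranteed to be one of the actually fitted
models and keeps generation faithful to an observed sub-state.

## Synthetic fixtures: what they show and what they do not

`random_sparse_precision` draws the edge support uniformly at a requested
density, couplings uniform in magnitude [0.5, 1] with random sign, and
inflates the diagonal to strict diagonal dominance — positive-definiteness
is guaranteed, and partial correlations land in a detectable but not
trivial range. `ggm_dataset` and `switching_trajectory` draw frames
**independently**; real MD frames are autocorrelated, so the effective
sample size of a real trajectory is smaller than its frame count. Passing
recovery tests therefore demonstrates estimator correctness in the
idealized i.i.d. regime, not a guarantee at equal frame counts on real
trajectories — on real data, λ should be chosen as if `t` were the
effective (decorrelated) sample count, or adjusted for desired sparsity.

Problem sizes used in the validation suite: solver-vs-oracle agreement on
25 random instances at n ≤ 6, λ ∈ {0.01, 0.1, 0.5}; edge recovery over 20
replicates at n = 10, density 0.2, t = 5000 with the analytic λ; the
kinetics round trip on 3-state chains (self-probability 0.9) over T = 500
windows of 50 frames at n = 6, states sharing graph structure but differing
in covariance scale (×1/×3/×9); change-point localization on 50-window
two-state fixtures with a ×4 covariance contrast. These sizes exercise
every code path at full trajectory-shaped scale while keeping the whole
suite around a minute.

## Numerical choices and degenerate inputs

- Everything is in natural log (nats).
- Edge threshold `|P_ij| > 1e-8` (strict), user-overridable; exact zeros
  from the sparse assembly make the default threshold uncritical.
- Conditioning rejects empty clamped or free sets (a fully clamped model is
  a point mass, not a Gaussian); the conditional covariance is symmetrized
  and validated positive-definite on construction.
- Sampling uses the lower Cholesky factor of Σ; a seed fully determines
  output, and a `Generator` may be passed to chain draws.
- `threshold_baseline` breaks magnitude ties lexicographically by (i, j).
- Data log-likelihood exposes three normalizations (`total`, `per_frame`,
  `per_frame_per_dim`) because reported per-dataset likelihood magnitudes
  depend strongly on this convention; comparisons between models are
  invariant to the choice as long as it is held fixed.
- Model JSON stores mean, precision, labels and λ; covariance is
  recomputed from the precision on load rather than stored.

## Known limitations

- No autocorrelation modelling in fixtures or estimators (i.i.d. within
  windows).
- Gaussian nodes only: no discrete or angular (von Mises) variables, so
  dihedral-angle covariates near periodic boundaries are not handled.
- No overlapping/sliding windows and no fused penalty across windows;
  smoothness comes only from the covariance kernel.
- The chain over window-cluster states is estimated at a single lag (one
  window); no implied-timescale or lag-convergence analysis is provided.
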