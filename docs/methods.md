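# Methods

## The estimation problem

A collection Γ₁,…,Γ_N of P×P SPD matrices is summarized by its Fréchet mean
under the affine-invariant (Fisher information) metric,

G = argmin_G Σₙ ‖logm(G^{-1/2} Γₙ G^{-1/2})‖²_F ,

computed here in the congruence form (the textbook form
‖logm(G^{-1}Γₙ)‖_F applies logm to a non-symmetric product; the congruence
form is equal in norm, keeps every matrix function on a symmetric argument,
and avoids spurious complex eigenvalues). The objective is geodesically
convex and its unique stationary point solves the matrix-normal equation
Σₙ logm(G^{-1/2} Γₙ G^{-1/2}) = 0. All matrix functions go through a
symmetric eigendecomposition after explicit symmetrization (A + Aᵀ)/2,
which is deterministic and well conditioned at the dimensions involved
(P up to a few hundred).

## The bilinear network estimator (MSPDNN)

The network applies the tied-weight congruence Γₙ ↦ V Γₙ V with
V = W̃W̃ᵀ, W̃ = W + λI, so the output is symmetric positive semidefinite by
construction, and minimizes

𝓛(W) = (1/P²) ‖ (1/N) Σₙ logm(V Γₙ V) ‖²_F ,

which vanishes exactly at V = G^{-1/2}. The weighted variant replaces the
uniform average by Σₙ wₙ(·)/Σₙ wₙ. The mean is recovered from the
best-loss iterate as G = V⁻² (eigendecomposition of the symmetric V).

Training is full-batch Adam (β₁ = 0.9, β₂ = 0.999) on the analytic
gradient: the matrix-logarithm derivative is the Daleckii–Krein
divided-difference kernel K_ij = (log aᵢ − log aⱼ)/(aᵢ − aⱼ) (1/aᵢ on the
diagonal) applied in the eigenbasis of each transformed matrix, followed by
the chain rule through the congruence and the symmetric product. The
gradient was verified against central differences (relative error ~5e-9).

Defaults, and why:

- `lr = 0.01`, decayed by 0.8 every 50 epochs; `steps_per_epoch = max(N, 50)`
  full-batch Adam steps per epoch; `max_epochs = 300` with two early-stop
  rules — training loss below `tol = 1e-8`, or no 1% relative improvement of
  the best loss for 15 epochs. An epoch is a fixed-length optimization pass
  rather than a single full-batch step so that small collections still
  receive an adequate step budget; `batch_size` switches to per-sample
  stochastic steps for the conventional epoch semantics. These values were
  tuned on the synthetic generating process against the Riemannian
  gradient-descent solution as reference: with tight per-step budgets or
  learning rates much below 1e-2 the full-batch optimizer stalls far from
  stationarity on ill-conditioned collections, while the defaults reach a
  first-order residual of ~1e-8 (geodesic error ~1e-3) across all problem
  sizes exercised by the tests.
- `lam = 1e-4` keeps W̃ full rank at initialization without biasing the
  optimum materially.
- Weights initialize i.i.d. uniform on [−1/√P, +1/√P], the standard
  fully-connected-layer default, seeded by `random_state`.
- **Whitening preconditioner** (`precondition=True`): training runs on
  M^{-1/2} Γₙ M^{-1/2} with M the (weighted) arithmetic mean, and the
  result is mapped back as G = M^{1/2} G′ M^{1/2}. The Fréchet mean is
  exactly equivariant under congruence, so this changes conditioning only:
  the optimum moves near the identity, where the uniform initialization
  starts. Without it, collections whose scale or spectrum is far from unity
  converge orders of magnitude more slowly.
- Eigenvalues of V Γₙ V that round to tiny negatives (within −1e-10 of the
  spectral radius, relatively) are floored during training rather than
  aborting; a genuinely indefinite congruence raises with advice to
  increase λ.
- The reported `condition_fit_` is always recomputed on the raw data at
  λ = 0, so it is comparable across estimators.

## Baselines

**Riemannian gradient descent** iterates
G ← G^{1/2} expm(η R) G^{1/2}, R = Σₙ wₙ logm(G^{-1/2} Γₙ G^{-1/2}),
from the arithmetic mean, with default step η = 0.5 (η = 1 is the classical
fixed-point iteration, exact in one step for commuting data; η = 0.5 is a
conservative default for a method known to be step-size sensitive). It
stops when the intrinsic update norm η‖R‖_F falls below `tol = 1e-8`.

**ALE mean**: Pham's approximate joint diagonalization finds B with every
B Γₙ Bᵀ near diagonal by Jacobi-like 2×2 sweeps minimizing the
log-likelihood off-diagonality criterion; the mean is
B⁻¹ expm(meanₙ log ddiag(B Γₙ Bᵀ)) B⁻ᵀ. Oversized 2×2 updates are damped
(h₁₂h₂₁ clamped below 1) so the transform stays well conditioned. On exact
CPC data this estimator equals the process's closed-form geodesic mean,
which is the correctness anchor for both the sweeps and the composition.

## Benchmark harness

The sweeps compare estimators at a **shared first-order stationarity
tolerance** (condition-fit 1e-4, the network's training tolerance),
translated into each method's native stopping rule (network: loss
threshold; gradient descent: η‖R‖ < ηP√tol). An exactly converged
fixed-point solver reports a condition fit at numerical precision, so
without a common stopping point the comparison measures stopping rules
rather than estimation behavior. Pipeline stages, in contrast, use each
estimator's accurate defaults — there the mean itself is the product.

Scalability sweeps draw noiseless CPC data and score the normalized
recovery error d_mean = δ_R²(G_est, G*)/‖G*‖²_R against the closed-form
optimum; the noise sweep (σ from 0.2 to 1.0 in steps of 0.1) has no
closed-form optimum and records condition fits only. Replicates redraw
data, initialization, or both (`vary`, default both). Runtime is recorded
but hardware-dependent and never asserted on.

## Synthetic data

The CPC process draws components B with i.i.d. standard-normal columns
(resampled with an incremented sub-seed if the condition number exceeds
1e12) and loadings c_nk as squared standard normals clipped below at 0.001;
Γₙ = B diag(cₙ) Bᵀ. The clip keeps matrices full rank but makes them
deliberately ill-conditioned (condition numbers ~1e5–1e7), which is the
stress the estimators are tested under. Structured noise adds the rank-one
term (1/P)xₙxₙᵀ, xₙ ~ 𝒩(0, σ²I); the perturbation is PSD so samples stay
SPD, and its expected trace inflation is σ² (verified by Monte Carlo).
Noise vectors are redrawn per noise level with a recorded seed offset.

Clustered cohorts place one SPD centroid per group along mutually
orthogonal unit tangent directions at the identity (scaled so pairwise
geodesic separation ≈ the requested value) and scatter members by the
exponential map of random symmetric directions of fixed Frobenius norm
(`within_spread`). This emulates the between/within geodesic structure of
multi-cohort connectome studies — not the spectral shape, sampling noise,
or site effects of real correlation matrices, so pipeline tests establish
error control and power under controlled geometry, not clinical effect
sizes.

## Group pipeline

- Connectomes: Pearson correlation of T×P time series, shrunk as
  (1−s)C + sI with default s = 0.05 — the simplest full-rank guarantee
  (minimum eigenvalue ≥ s).
- Bootstrap separation: per trial, fixed-size subsamples of each group give
  a between-means distance; the matched within draw is the mean of the two
  groups' split-half distances in the same trial. A one-sided Wilcoxon
  signed-rank test (between > within) summarizes the paired distribution;
  with a single trial no test is reported.
- Edge selection: observed statistic |difference of group geodesic means|
  per edge; null from label permutations with both means re-estimated per
  shuffle; add-one p-values; Benjamini–Hochberg FDR over the strict upper
  triangle (default α = 0.001). With n permutations the smallest attainable
  p-value is 1/(n+1), which bounds the detectable-effect resolution after
  FDR ranking — power studies should size n accordingly.
- Classification: selected upper-triangle entries feed an off-the-shelf
  random forest (100 trees); accuracy and AUROC on held-out subjects.
- Geodesic EM: E-step assigns to the nearest centroid in geodesic distance
  (ties to the lowest cluster index); M-step re-estimates centroids with
  the network estimator by default. Initialization is explicit centroids or
  a seeded farthest-point heuristic; emptied clusters keep their previous
  centroid (logged). Purity is the majority-vote fraction per cluster,
  size-weighted overall; empty clusters are excluded with a warning.

## Problem sizes and reproducibility

Tests and the acceptance script run at desk scale — P up to 30, N up to 50,
10 replicates per condition, 100–500 permutations — chosen so the full
suite completes in minutes on one CPU while still exercising the
ill-conditioned regime; the sweep grids extend to P, N = 200 behind the
CLI's `--full` flag. Every stochastic operation takes an explicit seed, and
derived seeds are fixed offsets of it; CLI runs record all resolved
parameters and seeds in a JSON manifest.

## Known limitations

- The network estimator is first-order: its terminal accuracy is set by the
  optimizer tolerance (~1e-3 geodesic distance at default settings), versus
  numerical precision for the fixed-point baseline. Its value is
  composability (a differentiable mean layer), not raw accuracy.
- Pham's diagonalizer assumes a shared component basis; far from the CPC
  regime the ALE mean is a biased approximation of the Fréchet mean (its
  condition fit degrades measurably with structured noise, which the tests
  assert).
- Mini-batch training is exposed but not tuned; the deterministic
  full-batch mode is the supported path.
- The clustered-cohort generator controls geometry only; conclusions about
  real rs-fMRI cohorts require real data.
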