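# Methods

## The model

Single-cell qPCR reports expression as cycle thresholds (Ct): the fewer
cycles needed for detectable amplification, the more transcript the cell
contained. Reactions that never amplify within the instrument's limit of
detection (LOD) are *censored*, not missing — the true Ct is known only to
exceed the LOD. In typical panels this affects a large fraction of entries
for some genes, and the common work-around of substituting every non-detect
with the LOD (or with 40 Ct) feeds a fabricated constant into downstream
PCA.

`censorlvm` performs probabilistic (kernel) PCA that treats those entries
as what they are. The model is a Gaussian process latent variable model
(GPLVM): each cell has a latent coordinate `x_n ∈ R^Q` (Q = 2 by default,
for visualization) and each gene d an independent GP over those
coordinates,

    f_{:,d} | X ~ N(0, K_d),        y_{nd} | f_{nd} ~ p_noise(y | f),

with the kernel shared across genes except for a per-gene diagonal term
(below). A linear kernel `K = X Xᵀ` makes this dual probabilistic PCA —
with Gaussian noise and centered data its optimum spans exactly the
classical PCA subspace, which the test suite pins as the primary
correctness anchor. An RBF kernel
`k(x, x') = α exp(−γ/2 ||x − x'||²)` gives the nonlinear generalization.

### Noise models

Each matrix entry carries one likelihood factor:

- **gaussian** `N(y; f, 1/β)` for detected values (β learnt by default);
- **missing** — a constant factor; the entry's site precision is exactly
  zero, making a missing entry mathematically identical to deleting that
  point from that gene's GP (tested to 1e-6);
- **censored** — a probit: for an entry right-censored at bound `b` the
  observation event has probability `Φ(λ (f − b))`, with steepness λ.
  Left censoring mirrors this, and interval censoring between `b₁ < b₂`
  uses `Φ(λ(f − b₁)) − Φ(λ(f − b₂))`.

The probit slope is the censoring mechanism's own noise scale: if
censoring is decided by a noisy observation `f + ε ≥ b` with
`ε ~ N(0, σ²)`, the implied slope is `λ = 1/σ`. λ → ∞ recovers a hard
threshold (Tobit-style likelihood).

### Orientation

Raw Ct decreases with expression. `NormalizedExpression` stays in
normalized-Ct units (lower = more expression); the model layer works on
the sign-flipped values `f = −(Ct − hk_mean)`, under which a qPCR
non-detect is **left**-censored at `−(LOD − hk_mean)`. With the interval
noise model the maximal measurable 40 Ct supplies the other bound, which
prevents the optimizer from parking censored entries at absurdly high
expression on the wrong side of the latent space. All outputs can be
mapped back through `FittedModel.to_data_orientation`.

### Housekeeping normalization

Cell size and efficiency effects are removed by subtracting each cell's
mean housekeeping-gene Ct from all its Ct values. Because the LOD is an
instrument property in *raw* Ct, the censoring threshold after
normalization is per-cell: `b_nd = LOD_d − hk_mean(n)`, and likewise the
40-Ct ceiling. Cells whose housekeeping genes are partly unusable fall
back to the mean of the remaining ones (logged); cells with none are
dropped (logged). Housekeeping columns are excluded from the fit by
default — they are approximately constant after normalization.

## Inference: assumed density filtering

The probit factors make the posterior over latent function values
non-Gaussian. A single-sweep assumed-density filter produces a Gaussian
approximation per gene: starting from the prior `N(0, K_d)`, each factor
is absorbed by moment matching. For a running marginal `N(μ, v)` the
tilted normalizer is available in closed form,

    Z = Φ( ±(μ − b) / s ),    s = √(v + 1/λ²),

(differences of two such terms for intervals; a Gaussian convolution for
Gaussian factors), and with `g1 = ∂ log Z/∂μ`, `g2 = ∂² log Z/∂μ²` the
joint update is the rank-one

    μ ← μ + g1 Σ[:, n],    Σ ← Σ + g2 Σ[:, n] Σ[:, n]ᵀ.

Site pseudo-observations `(m̃, τ̃)` are back-derived from the matched
moments; negative site precisions (possible under moment matching) are
clipped to zero with a logged count. The accumulated `Σ log Z` is the
approximate log marginal likelihood. For Gaussian-only data the sweep is
exact; its agreement with brute-force numerical marginalization on small
censored fixtures is part of the acceptance suite (≤ 0.05 nats).

**Sweep order.** Gaussian (exact) and missing sites are folded in first,
then censored sites, each in ascending cell order. Exact sites commute, so
this ordering only improves the cavities the approximate sites are matched
against; on 6-cell fixtures it reduced the median error against brute
force from ~3e-2 to ~2e-4 nats. A custom order (including plain row-major)
can be passed to `adf_sweep_dim`.

All closed forms are validated against an independent quadrature oracle —
log partition values against 30-digit mpmath integration (double-precision
adaptive quadrature cannot certify 1e-8 agreement for deep-tail sites),
moment integrals against scipy's adaptive quadrature.

## Optimization

Fitting alternates:

1. **Assimilation** — one ADF sweep per gene with the current kernels,
   yielding sites and the approximate log marginal;
2. **SCG block** — holding non-Gaussian sites fixed, each gene's marginal
   is the closed-form Gaussian `N(m̃_d; 0, K_d + diag(1/τ̃_d))` over active
   entries (Gaussian entries always use the live β, for which the site is
   exact; zero-precision entries drop out). This surrogate is
   differentiable in X and all hyperparameters and is maximized jointly by
   scaled conjugate gradient (Møller's algorithm, implemented in
   `censorlvm._scg`; `optimizer="lbfgs"` switches to the scipy
   quasi-Newton fallback).

The loop stops when the relative change of the ADF objective falls below
`tol` (default 1e-5) or after `outer_max` iterations (default 100, with 50
SCG steps per block); the best-objective state is returned, so the final
reported objective is never below the initial one. Re-assimilation can
transiently lower the objective between blocks; only accepted (best)
states matter. Trial steps that overflow a hyperparameter or break a
Cholesky factorization are rejected by returning an infinite objective to
the optimizer rather than aborting the fit.

Hyperparameters are optimized in log space (positivity by construction):
RBF α, γ, bias/white variances, the Gaussian precision β and, when the
probit slope is learnt, the censor-white variance. A fixed relative jitter
of 1e-6 × mean diagonal is added before every factorization.

### Learning the probit slope

Rather than differentiating λ directly, the slope is learnt through the
kernel: the base slope is set steep (λ₀ = 100) and a white-noise term
`v_c · I_c^(d)` is added to the kernel diagonal — only at censored
entries, with a different 0/1 mask per gene, which is why each gene needs
its own kernel (all other terms are shared and computed once). Because

    Z = Φ((μ − b)/√(v + 1/λ²)),

adding `v_c` to the prior variance of a censored site is exactly
equivalent to flattening the slope to `λ_eff = 1/√(1/λ₀² + v_c)`; the
equivalence is asserted numerically to 1e-6. `v_c` is a smooth, positive,
jointly-optimized hyperparameter; `FittedModel.effective_lambda` reports
the implied slope. The censor-white term models an observation artifact at
training points and never contributes to test-point covariances.

Initialization: latent coordinates start from classical PCA of the
bound-substituted matrix, scaled to unit variance per dimension (a random
normal init is available); `substituted-pca` initialization aligns much
better with ground truth than random starts on synthetic data. β starts
at 1/(0.1 × data variance), RBF γ at the inverse median squared distance
of the initial latents, and λ_eff at 10 when learning.

## Posterior prediction and diagnostics

For any latent point the fitted model gives per-gene GP posterior moments
using the site pseudo-observations; cross-covariances exclude white and
censor-white terms (noise-free function prediction). Two diagnostics:

- **Censored residuals** — for each censored entry, the posterior mean at
  its cell's fitted coordinate minus the detection bound, signed so
  positive means "beyond the bound on the censored side" (past the
  normalized LOD). A censoring-aware fit maps a large fraction of
  non-detects beyond the bound; a substitution fit pins them at or below
  it. For interval entries the residual is measured from the
  detection-side bound.
- **Uncertainty map** — on a 2D lattice over the fitted latents (80×80,
  10% padding by default), the scalar per pixel is the log of the product
  of per-gene posterior variances — the model is a product of independent
  GPs, so the product is its joint predictive spread; the log compresses
  dynamic range. The map is min-max normalized to [0, 1] per image and
  rendered so that higher uncertainty is darker. Only the monotone
  "darker = more uncertain" contract is load-bearing; the normalization
  preserves pixel ranking by construction.

**Embedding quality** is scored by the leave-one-out nearest-neighbour
error: the count of cells whose Euclidean-nearest other cell carries a
different label, ties broken to the lowest index for determinism.

## Synthetic data

No real dataset ships with the package; two seeded generators provide
ground-truthed study material.

**Four-Gaussian toy** (`four_gaussian_toy`): a 2D mixture with component
means (0,0), (3,0), (0,3), (3,3), unit covariance, right-censored in
dimension 1 at 2.0, so one pair of components straddles the bound. The
layout is illustrative — chosen so censoring bites one component hard —
not a reproduction of any published parameterization.
`censor_noise_sd > 0` makes the censoring decision noisy (generative slope
1/sd), which is how the learnt-slope rank check is constructed: data
censored by a hard threshold yields a steeper learnt λ_eff than matched
data censored through noise (median over 10 seeds).

**qPCR simulator** (`qpcr_simulator`): populations are Gaussian clusters
in a Q=2 latent space (centers sd 1.0, within-population sd 0.7 — chosen
so populations overlap and the substitution baseline's nearest-neighbour
error rate falls in the tens of percent, the regime where visualization
quality is actually contested), mapped linearly to target genes (per-gene
effect sizes 1.5–3 Ct, observation noise 0.5 Ct), converted to cycles via
`Ct = 30 − expression`. Non-detects in real panels mix two regimes —
transcript levels trailing into the LOD and genes that are simply *off*
in some populations — so each censorable gene is additionally switched
off (5 Ct deeper than its detected range) in a random population subset
covering roughly its target censoring fraction, producing the
characteristic bimodal per-gene Ct distributions. Per-gene offsets are
then quantile-calibrated so realized censoring fractions land within 5
percentage points of the requested profile. A shared per-cell offset
(sd 1 Ct) on every gene, housekeeping included, emulates cell-size
variation and is removed by normalization. Housekeeping genes sit at
≈16 Ct, far from the 28-Ct LOD. Values are censored at the LOD and the
stored Ct capped at 40.

What the generators do *not* emulate: amplification stochasticity and PCR
efficiency curves, batch/array structure, gene–gene correlations beyond
the low-rank latent map, and gene-dependent LODs (supported by the data
structures, not exercised by the simulator). Passing the synthetic
comparisons therefore shows the machinery behaves as designed under the
stated generative assumptions, not that it will improve any particular
real dataset.

## Study configuration for the synthetic comparisons

The packaged comparison (tests and `scripts/acceptance.py`) fits the
linear-kernel, interval-censored model with λ fixed at 2 — the simulator's
generative steepness (censoring acts on the observation with 0.5 Ct noise,
slope 1/0.5) — on 120-cell, 24-gene panels (2 housekeeping) with moderate
censoring (none in half the target genes, 30–50% in the other half),
against classical PCA of the LOD-substituted matrix. Each comparison uses
20 seeded replicates; fits run 8 outer iterations × 50 SCG steps, sizes
chosen to keep a full comparison within minutes on one core. The toy
demonstration uses the learnt-λ model (Q = D = 2, where the slope is
identifiable).

## Known limitations

- Cubic cost in cells per gene-kernel factorization; no sparse/inducing
  approximations. Panels of a few hundred cells fit in seconds to minutes;
  thousands of cells will not.
- Single-sweep ADF is order-dependent and can err by more than 0.05 nats
  on badly misspecified fixtures (censored entries whose latent values sit
  far on the detected side); iterated EP refinement is not implemented.
- On rank-limited panels (Q far below the effective data rank), maximum
  likelihood drives the *learnt* slope shallow: flattening every censored
  factor costs at most log 2 per site while a steep misfit site is
  unboundedly expensive, so the learnt-λ mode under-weights censoring
  exactly when the latent space cannot accommodate every censored entry.
  The fixed-slope mode with λ matched to the observation noise is the
  recommended configuration for low-Q fits; the learnt mode shines when
  Q is generous (the toy, or exploratory fits with larger Q).
- The latent coordinates carry no prior; duplicate cells are handled only
  through kernel jitter, and the map is identified up to rotation/scale.
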