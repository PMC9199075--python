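# Methods

`pdestride` identifies the governing equation of a spatio-temporal dynamical
system from gridded observations by stability selection over sparse
regression. This note records the model, the algorithmic choices that were
genuinely open, the study conditions built into the benchmark generators,
and the known limits of the approach.

## Regression formulation

Observations `u(x, t)` on a regular grid are turned into a linear system
`Ut ≈ Θ ξ`. The response `Ut` is the first-order forward time difference of
the target variable; each column of the dictionary `Θ` is one candidate
model term — a polynomial monomial in the state variables, a spatial
derivative, or a product of both — evaluated at `N` sampled space-time
points. Spatial derivatives use second-order central stencils; third and
fourth orders are built by composing the first- and second-derivative
stencils, which keeps the whole dictionary on one stencil family. At
non-periodic boundaries, points whose stencil does not fit are excluded
from sampling rather than switched to one-sided formulas, so boundary
order-reduction never contaminates the regression.

A deliberate property of the benchmark pipeline is that data generation and
differentiation share the same stencils and time step: the stored frames of
every simulator are consecutive explicit-Euler states, so the forward time
difference of clean data reproduces the discrete right-hand side to
rounding. Clean-data recovery is therefore limited only by deliberate
discretization mismatches (see the Burgers flux form below), not by
integration error.

## Sparse solvers

Five sparsity-promoting solvers act on standardized systems (columns
centered to mean zero and unit mean square, response centered; an explicit
constant column is absorbed by the centering, treated as an unpenalized
intercept, and restored at refit):

* **LASSO / randomized LASSO** — cyclical coordinate descent on
  `½‖Ut−Θξ‖² + λ Σ|ξk|/Wk`, with `Wk ~ Uniform[α,1]` i.i.d. per column for
  the randomized variant (default weakness `α = 0.2`).
* **IHT** — hard-thresholded Landweber iteration
  `ξ ← H_λ(ξ + Θᵀ(Ut − Θξ))` from zero, after jointly rescaling `Θ` and
  `Ut` so `‖Θ‖₂ < 1` (the regime with descent guarantees; joint rescaling
  leaves coefficients unchanged). `λ` is the direct magnitude threshold of
  `H_λ`; a penalty-weight mode (threshold `√(2λ)`) is available.
* **IHT-d** — the method of record: each iteration extracts a candidate
  support by one thresholded gradient step, then *debiases* the
  coefficients by solving the least-squares problem restricted to that
  support. The debias stage is skipped when the residual already satisfies
  the loose confidence bound `‖r‖² ≤ (λ²/2)|S|` (the penalty-consistent
  form of the bound for the direct-threshold convention). Because `λ` then
  thresholds *debiased* coefficient magnitudes, the iteration cold-starts
  from the hard-thresholded full least-squares estimate whenever the
  subproblem is overdetermined, and `λmax` is the largest magnitude of the
  full least-squares solution. Restricted solves are done by QR-based least
  squares — normal equations would square the condition number and smear
  coefficients across nearly collinear column families. Two-cycles of the
  support sequence are resolved by the lower ℓ0 objective.
* **STRidge** — sequential thresholding of ridge solutions
  (`λR = 10⁻⁵` by default), iterated to a fixed support.
* **OMP** — greedy orthogonal matching pursuit (scikit-learn
  implementation), with the path position mapped to the sparsity level.

Design notes that were genuinely open and how they were settled:

* Warm starts down the λ-path are used only for the convex solvers. The
  ℓ0 iterations are cold-started at every λ: warm starts lock the
  non-convex iteration into large-λ local minima and measurably destroy
  support recovery on half-subsamples.
* The debias stage is run to numerical optimality (restricted least
  squares) rather than a fixed number of gradient steps; with
  gradient-step debiasing the iteration inherits the slow Landweber rate
  on ill-conditioned supports and transient spurious components never
  decay below threshold.

## Stability selection

Given a design of `N` rows, `B = 250` random half-subsamples (rows drawn
without replacement, independently across subsamples) are each
re-standardized and solved along a shared geometric λ-grid of `M = 20`
values from `λmax` down to `ε·λmax` with `ε = 0.1`. `λmax` is fixed once
from the standardized full system so all subsample paths share the grid.
The importance of component `k` at `λ` is the fraction of subsamples whose
support contains `k`; the stable support is every component whose
importance at `λmin` reaches `πth = 0.8` (inclusive). Coefficients are
refit by ordinary least squares of the response on the supported raw
columns of the full system, so they carry physical units. For IHT-d the
`B × M` subsample solves run through a vectorized batch kernel (per-slice
Gram matrices, batched masked restricted solves) that is tested
element-for-element against the single-system solver.

## Benchmark generators and study conditions

* **1-D Burgers** (`u_t + u u_x = D u_xx`, `D = 0.1`): Gaussian bump
  `exp(−(x+2)²)` on the periodic interval `[−8, 8]`, 256 grid points,
  1000 frames at `dt = 0.01`, explicit Euler. The advective term is
  discretized in conservative flux form `∂x(u²/2)`, which conserves
  discrete mass exactly and differs from the dictionary's `u·u_x` column
  by a second-order truncation term — the refit coefficients on clean data
  are `(−1.000, 0.1001)` rather than exactly `(−1, 0.1)`.
* **2-D lid-driven cavity** (vorticity transport, `μ = 0.025`):
  streamfunction–vorticity formulation on a 128² unit square, no-slip
  walls, lid velocity 2.0, Thom wall-vorticity closure, prefactorized
  sparse Poisson solve per step; the stored window is the transient around
  `t = 1` (nine consecutive frames at `dt = 5·10⁻⁴`), where `ω_t ≠ 0`.
  Sampling uses the rectangle `[0,1]×[0.6,1]` and excludes a three-point
  wall ring: Thom's closure is first-order and the lid-corner vorticity
  singularity otherwise dominates the column statistics.
* **3-D Gray–Scott** (`f = 0.014`, `k = 0.053`, `Du = 2·10⁻⁵`,
  `Dv = 10⁻⁵`): periodic cube `[0, 2.5]³` at 64³ resolution (a
  scaled-down grid; the dynamics in the sampled subcube `[1, 1.5]³` are
  equally active), `dt = 0.01` to `t = 5`, last 8 frames stored. Initial
  condition: the trivial state `u=1, v=0` with a centered cube
  perturbation (`u=0.5, v=0.25`) carrying 1% seeded uniform jitter.
* **PAR reaction network** (pointwise kinetics of the anterior/posterior
  polarity proteins, rate constants of the inferred zygote model):
  opposing sigmoid plateaus of ~10 µm⁻² with smooth long-wavelength
  modulation on a 256-pixel, 60 µm cortex line; 40 frames at `dt = 8 s`.
  The modulation plays the role of the uneven cortical fluorescence of a
  real embryo and decorrelates the mass-action monomials.

Noise is additive Gaussian per variable, `σ·N(0, Var(u))` with `Var(u)`
the empirical variance of that variable's full clean data vector, always
behind an explicit seed. Noisy data are denoised before differentiation by
truncated SVD of each variable's (time × space) matrix; the automatic
cut-off keeps every singular value above the optimal hard-threshold
multiple of the median singular value, which finds the bend into the noise
floor robustly where a naive max-curvature rule truncates after the first
large spectral drop. A fixed rank can be forced (e.g. the rank-1
"first SVD mode" convention used for real fluorescence data).

## What the generators do and do not emulate

The generators produce data whose discrete dynamics are *exactly*
representable in the dictionary (up to the deliberate Burgers flux
mismatch). Passing clean-data tests therefore demonstrates correct
assembly, solver, and aggregation logic — not robustness to model error,
unresolved scales, or non-Gaussian noise in real measurements. The noise
model is i.i.d. Gaussian per grid point; real microscopy noise is
correlated, signal-dependent and accompanied by optical blur.

## Known limitations

* **Fine-time-resolution noise.** At the Burgers benchmark's native frame
  spacing (`dt = 0.01`), the forward-difference response amplifies additive
  noise by `√2/dt ≈ 141`; at σ = 1–4% the response SNR drops to ~0.06 and
  the full-model t-statistic of the true advection term at `N = 250` is
  ≈ 1, i.e. the support is statistically unidentifiable for *any* selection
  method. SVD denoising does not rescue this: the temporal derivative
  signal lives in the same trailing singular modes as the noise, and the
  truncated field systematically violates the PDE, so denoising trades
  white noise for structured model error. In addition, the forward-time
  stencil shares its center point with even-order spatial stencils, making
  raw `u_xx`/`u_xxxx` column noise 50–58% correlated with the response
  noise. Noisy support recovery on this benchmark is accordingly out of
  reach at these settings; slower systems with coarser frame spacing (the
  PAR benchmark, `dt = 8 s`) recover cleanly at the same noise level.
* **Tiny intercepts under noise.** The field-mean of an additive noise
  realization propagates through quadratic dictionary terms into the refit
  intercept. For the PAR P-equation this floor is ≈ 2–8·10⁻⁵ µm⁻²s⁻¹ —
  independent of `N` — which exceeds 10% of the small source constant
  `cP = −1.98·10⁻⁴`; the kinetic rate constants, which sit well above this
  floor, recover to a few percent.
* **Sharp clean-data phase transition.** Because IHT-d debiases by
  restricted least squares, any half-subsample with `N/2 ≥ p` of exactly
  representable data recovers the support exactly; the achievability
  transition on clean data collapses to the determinacy limit `N ≈ 2p+2`
  (≈ 40 for the 1-D dictionary, ≈ 140 for the 3-D one) and is sharper than
  what partially-converged debiasing schemes exhibit.
* The cavity solver's wall closure is first-order; vorticity values in the
  three-point wall ring are excluded from sampling rather than corrected.
* Dictionary presets are product families (monomials × derivative
  operators) chosen to contain the true models at the standard column
  counts (19/48/69/20); they are one reconstruction of that term family,
  and all presets are overridable by explicit term lists.
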