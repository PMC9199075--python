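# pdestride

Robust, data-driven identification of governing differential equations from
noisy, limited spatio-temporal data, using stability selection over
sparsity-promoting regression.

Many systems in physics and cell biology are observed as space-time fields
(concentrations, velocities, vorticity) whose governing PDE or reaction
network is unknown or hypothesized. Sparse-regression equation discovery
casts the problem as a linear model

```
Ut = Θ ξ,        Θ ∈ R^{N×p},
```

where `Ut` holds finite-difference time derivatives at `N` sampled
space-time points and the columns of the dictionary `Θ` are candidate model
terms (monomials such as `u, u², uv²`, spatial derivatives such as
`u_x, u_xx`, and their products), so that a sparse coefficient vector `ξ`
*is* the governing equation. The catch is the regularization parameter: a
wrong `λ` silently yields a wrong model. This package removes that knob by
**stability selection**: the rows of `(Θ, Ut)` are subsampled `B = 250`
times into random halves, each half is solved along a whole λ-path, and a
component enters the model only if its selection frequency

```
Π̂ₖ(λ) = (1/B) Σᵢ 1{ k ∈ Ŝ_λ[Iᵢ] }
```

at the smallest penalty `λmin = 0.1·λmax` reaches the threshold
`πth = 0.8`. Coefficients are then refit by ordinary least squares on the
stable support, in physical units. The default workhorse solver is
**iterative hard thresholding with debiasing (IHT-d)** — a thresholded
Landweber iteration whose candidate supports are refit by restricted least
squares each step; randomized LASSO, plain IHT, STRidge and OMP are
available behind the same interface.

The package ships the standard benchmark generators (1-D viscous Burgers,
2-D lid-driven-cavity vorticity transport, 3-D Gray–Scott
reaction-diffusion, and the PAR polarity-protein reaction kinetics of the
*C. elegans* zygote), the preprocessing stack (seeded noise injection,
truncated-SVD denoising, finite-difference differentiation, stencil-safe
sampling), dictionary presets with the standard column counts
(p = 19 / 48 / 69 / 20), and an achievability harness that measures exact
support-recovery frequency versus sample size.

## Worked example

Recover the Burgers equation `u_t = −u u_x + 0.1 u_xx` from 250 points
sampled out of a 1000×256 simulation:

```python
from pdestride import SolverConfig, StabilityConfig
from pdestride.experiments import benchmark_selection

res = benchmark_selection(
    "burgers", 250, sigma=0.0, seed=0,
    solver_config=SolverConfig(method="iht_d"),
    stability_config=StabilityConfig(seed=0),
)
print("stable support:", list(res.stable_support))
for k, v in res.coefficients.items():
    print(f"  {k:10s} {v:+.4f}")
```

prints

```
stable support: ['u*u_{x}', 'u_{xx}']
  u*u_{x}    -0.9990
  u_{xx}     +0.1006
```

i.e. out of 19 candidate terms, exactly the advection and diffusion terms
survive the stability threshold (their importance at `λmin` is 1.0; every
other component sits at ≤ 0.02), and the refit coefficients match the
generating values −1 and 0.1 to a tenth of a percent — the residual being
the deliberate flux-form/product-form discretization mismatch of the
simulator. `res.profile` holds the full importance matrix for stability
plots.

The same entry point runs the other benchmarks (`"vorticity"`,
`"grayscott"`, `"par_A"`, `"par_P"`) and noisy variants (`sigma=0.01`
adds 1% seeded Gaussian noise and switches on SVD denoising).

A command-line interface wraps the same machinery:

```bash
stride simulate burgers --out data.h5 --noise 0.02 --seed 0
stride select --problem grayscott --n 400 --method iht_d --out result.json
stride achievability --problem burgers --n-grid 40,60,80,100 --reps 20 --out grid.csv
```

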