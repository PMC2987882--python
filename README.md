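# liouville

Exact probability-density propagation for ODE models by the method of
characteristics.

## The problem

Ordinary-differential-equation models in systems biology are routinely
subject to uncertainty or cell-to-cell variability in their initial
conditions and parameters. Describing that input by a probability density
u₀ on the state (and parameter) space turns the question "how does the
uncertainty propagate?" into a concrete object: the density u(t, ·) of the
state at time t, which solves a first-order transport PDE (the Liouville
equation, i.e. the zero-diffusion Fokker–Planck equation)

    ∂u/∂t = −div(F·u),    u(0, ·) = u₀,

for the autonomous vector field F. Grid-based PDE solvers become
prohibitive beyond a few dimensions, and Monte Carlo sampling resolves
low-probability regions only with enormous sample sizes. The method of
characteristics avoids both: along any trajectory x(t) of the original
ODE, ρ(t) = u(t, x(t)) obeys the scalar ODE

    dρ/dt = −div F(x(t)) · ρ(t),

so the density anywhere is obtained by solving the original system with a
single extra dimension — exact up to the accuracy of the ODE solver.

The package implements, for modellers of low- to moderate-dimensional
biochemical systems:

- **forward propagation** of an initial discretization together with its
  density values (`propagate_initial_grid`, `propagate_pair`);
- the **backward-forward procedure**: integrate chosen final-time query
  points backward to t = 0, evaluate u₀ there, then integrate the extended
  system forward — giving u(T, ·) exactly at the points of interest, with
  no normalization step (`density_at_points`, `region_mass`);
- **parameter uncertainty** by extending the state space with constant
  parameters (`extend_with_parameters`), and **marginalization** of the
  resulting joint densities by midpoint-rule quadrature on cell-centered
  grids (`marginalize`, `midpoint_integrate`);
- **likelihood-based parameter estimation**: the likelihood of data
  D = {ξ₁(T), …, ξ_N(T)} is ∏ᵢ u(T, ξᵢ(T)), computed per data point by the
  backward-forward procedure and profiled over a parameter grid
  (`likelihood_of_data`, `profile_parameter`);
- a **Monte Carlo reference** (sample u₀, integrate, histogram) for
  cross-validation (`monte_carlo_ensemble`, `histogram_density`);
- two built-in gene-expression circuits: a Hill-type **autoregulation**
  model and the genetic **toggle switch**.

Densities are handled in log space throughout; all integration goes
through `scipy.integrate.solve_ivp` with configurable tolerances
(`SolverSettings`, defaults rtol 1e-8 / atol 1e-10).

## Worked example

The autoregulation circuit dx/dt = V_max·x^β/(K^β + x^β) − k_d·x with
V_max = 1, K = 2, k_d = 0.01, β = 4 and x₀ ~ N(2, 0.2): most of the
population is transported to high expression by t = 50, but cells starting
below the unstable threshold stay near the origin and form a heavy tail.

```python
import liouville as lv

field = lv.build_autoregulation(V_max=1.0, K=2.0, k_d=0.01, beta=4.0)
u0 = lv.NormalDensity([2.0], 0.2)

# mass of the low-expression tail [0, 10] at t = 50 (100 backward-forward solves)
grid = lv.build_uniform_grid([(0.0, 10.0, 0.1)])
print(lv.region_mass(field, u0, grid, 50.0))   # 0.0009666849130175125

# ~0.1% of the mass: a 100,000-sample Monte Carlo run puts ~100 points there
ens = lv.monte_carlo_ensemble(field, u0, 100_000, 50.0, seed=7)
print(((ens.points[:, 0] >= 0) & (ens.points[:, 0] <= 10)).sum())   # 96
```

So the interval holds ≈ 0.001 of the probability; resolving it by
sampling needs a thousand times more ODE solves than the 100 used here.

Estimating V_max from one observation ξ(20) = 5:

```python
model = lv.get_model("autoregulation")
obs = lv.ObservationSet(20.0, [[5.0]])
vgrid = lv.NodeGrid([(0.0, 2.0, 0.05)])
fixed = {"K": 2.0, "k_d": 0.01, "beta": 4.0}

prior_a = lv.NormalDensity([2.0, 1.0], [0.2, 0.01])        # tight prior on V_max
print(lv.profile_parameter(model, prior_a, obs, vgrid,
                           ["V_max"], fixed).maximizer_scalar)   # 0.95

prior_b = lv.ProductDensity([lv.NormalDensity([2.0], 0.2),
                             lv.UniformBoxDensity([0.0], [2.0])])  # flat prior
print(lv.profile_parameter(model, prior_b, obs, vgrid,
                           ["V_max"], fixed).maximizer_scalar)   # 0.2
```

With the informative prior the estimate stays at the prior mean (0.95 ≈ 1,
one grid step away); with no prior information on V_max the observation is
explained best by a much smaller expression rate, 0.2.

## Command line

Each analysis is also available as a subcommand driven by a YAML
configuration (see `examples/`):

```sh
liouville region-mass --config examples/example1_tail_mass.yaml --outdir out/
liouville profile     --config examples/example3_profile_flat_prior.yaml --outdir out/
```

Subcommands: `propagate`, `region-mass`, `marginal`, `likelihood`,
`profile`, `mc-compare`. Outputs are CSV files plus a JSON summary and a
run log (settings, seed, versions, wall time).

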