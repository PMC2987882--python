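# Methods

## Model and procedure

The package treats an autonomous ODE dx/dt = F(x) on R^d whose initial
state X₀ is random with probability density u₀. The density u(t, ·) of the
state X_t solves the transport (Liouville) equation ∂u/∂t = −div(F·u) —
the Fokker–Planck equation with zero diffusion. Because the PDE is
first-order and linear, it is solved along characteristics, which here are
the trajectories of the original ODE: ρ(t) = u(t, x(t)) satisfies
dρ/dt = −div F(x(t))·ρ(t), where div F is the trace of the Jacobian of F.
The density value at any state and time therefore comes from integrating
the original system with one extra scalar dimension; no PDE grid is ever
built, and the values are exact up to the ODE-solver tolerance.

Parameter uncertainty reduces to the same setting: constant parameters p
are appended to the state with zero derivative
(`extend_with_parameters`), so a joint prior on (z₀, p) propagates like
any initial density. The divergence of the extended field equals the
divergence of the state dynamics alone, since the parameter block
contributes zero rows.

Two complementary modes are provided:

* **Forward**: discretize a region of interest at t = 0, attach
  log u₀ to each point, and integrate the extended system; this paints the
  density along the flow (`propagate_initial_grid`).
* **Backward-forward**: for query points ξᵢ(T) at the final time,
  integrate the sign-reversed field forward over [0, T] to obtain the
  pre-images ξᵢ(0), evaluate log u₀ there, and integrate the extended
  system forward. This yields u(T, ·) exactly at the chosen points — in
  particular on quadrature grids over arbitrary sub-regions, with no
  renormalization — and is also how the likelihood of observed data points
  and its parameter profiles are computed (Lik = ∏ᵢ u(T, ξᵢ(T)), summed in
  log space).

The Monte Carlo module implements the conventional alternative (sample u₀,
integrate each sample, estimate the density by relative frequency on grid
cells) purely as a cross-check. Only the plain histogram estimator is
offered: kernel estimators need problem-specific bandwidth choices and the
reference must stay assumption-free.

## Assumptions

* F is autonomous and continuously differentiable; uniqueness of solutions
  means characteristics cannot cross, which is assumed, not monitored.
  Time-dependent right-hand sides are rejected at construction.
* u₀ should be continuously differentiable for the PDE derivation to hold
  classically. Exponential and uniform initial densities are nevertheless
  admitted — they are standard modelling choices and the characteristic
  solver never differentiates u₀ — with the caveat that their support
  boundaries carry the non-smoothness. Cell-centered grids keep quadrature
  nodes strictly inside supports, and the uniform box evaluates its
  boundary as interior (closed-interval convention), which matters when a
  profiled parameter's grid includes the endpoints of its flat prior.
* Zero diffusion: stochastic differential equations with noise, delays and
  hybrid dynamics are out of scope.

## Numerical choices

* **Log-space densities.** The density dimension is integrated as
  d(log ρ)/dt = −div F, not as ρ itself: the low-probability tails this
  method exists for span orders of magnitude, and linear-space integration
  loses all relative accuracy there. Exponentiation happens only at output
  time. Zero prior density (log u₀ = −∞) short-circuits the forward solve.
* **Solver.** All integration uses `scipy.integrate.solve_ivp` (RK45 by
  default) with rtol 1e-8, atol 1e-10. The backward solve integrates the
  negated field forward on [0, T] rather than reversing the time span, so
  the adaptive behaviour is identical in both directions.
* **Divergence.** Analytic where supplied (both built-in models); otherwise
  a central finite-difference trace of the Jacobian with per-coordinate
  step h_i = sqrt(machine epsilon)·max(1, |x_i|).
* **Batching.** Batch operations (grid densities, ensembles) integrate all
  points as one stacked ODE system when the field provides vectorized
  callables; a 200×200 grid then costs one solve instead of 40,000. If a
  stacked solve fails, the computation falls back to independent per-point
  solves, so a single stiff trajectory cannot destroy a grid computation;
  per-point outcomes are recorded as statuses ("ok", "zero_density",
  "domain_exit", "ill_conditioned", "failed").
* **Grids.** Quadrature grids are cell-centered (midpoint rule,
  second-order, exact for constants); profile and initial-discretization
  grids are node-inclusive. The flattened point order is the row-major
  Cartesian product in axis declaration order, fixed so CSV outputs are
  byte-identical across runs.
* **Round-trip diagnostics.** Backward-forward computations re-check that
  forward integration returns to the query point (tolerance 1e-6 relative);
  violations raise a `ConditioningWarning` rather than an error.
* **Domain bounds.** The built-in models declare non-negative concentration
  domains, enforced for user-facing point evaluations. Characteristic
  integration does not clip: both built-in right-hand sides extend smoothly
  (even Hill exponents), and excursions are reported per point as
  "domain_exit".
* **Ties and degenerate profiles.** The profile maximizer breaks exact ties
  toward the smallest parameter value; an all-but-flat profile triggers a
  `FlatProfileWarning`; an all-zero profile is an estimation error. Grid
  profiling is the primary procedure (no gradient ascent); an optional
  refinement pass re-grids around the maximizer at a quarter spacing.

## Reference computations and problem sizes

The shipped examples and the acceptance script use the two built-in
circuits at their reference parameter sets: autoregulation with V_max = 1,
K = 2, k_d = 0.01, β = 4 and x₀ ~ N(2, 0.2); the symmetric toggle switch
with α = 5, β = 2, q = 1, k_d = 1 and (x₁, x₂)₀ ~ N((3,3), diag(0.1, 0.1)).
Problem sizes were chosen as the smallest that resolve each quantity:

* heavy-tail mass: 100 cell-centered points on [0, 10] (h = 0.1) at
  T = 50, with convergence checked by halving h;
* likelihood profiles: 41 node-inclusive V_max values on [0, 2]
  (h = 0.05), one observation ξ(20) = 5;
* conservation checks: [0, 60] with h = 0.1 at T = 50 (autoregulation) and
  [0.05, 5.05]² with h = 0.025 at T = 1 (toggle switch);
* Monte Carlo comparisons: 10⁵ samples.

## Synthetic data

The parameter-recovery check generates its own observations: 25 initial
states drawn from the prior N(2, 0.2), integrated forward to T = 20 with
the true V_max = 1, observed without measurement noise. This emulates
cell-to-cell variability read out destructively at one time point — each
datum is an independent draw from u(T, ·) — which is exactly the sampling
model the likelihood assumes. It does not emulate measurement error (no
noise convolution is implemented), partial observation of a state
subspace, or repeated measurements along a single trajectory, so passing
recovery tests demonstrates correctness of the density/likelihood
machinery, not robustness to misspecified noise on real data. Data points
at different times are treated as independent draws from the respective
u(tᵢ, ·), which matches the product likelihood only for observations of
separate trajectories.

## Limitations

* **Ill-conditioned backward solves.** Where the flow contracts strongly —
  chaotic systems, or densities collapsing onto slow manifolds as in the
  toggle switch — the backward pass amplifies solver noise exponentially in
  the horizon. For the toggle switch at t = 10 the transverse contraction
  is ~e^{−15} and pre-images are recoverable in state (the forward flow
  re-contracts the error, so round trips still close to 1e-6) but the
  *density* obtained via backward-forward degrades; forward propagation is
  the reliable mode there, and the forward/backward-forward consistency
  check is run at t = 2 where both modes are well conditioned.
* **Quadrature needs uniform grids.** Marginals, masses and moments require
  a regular discretization of the final-time region, which is the
  computationally limiting step: resolving the toggle-switch manifold at
  t = 10 (width ~1e-4) would need millions of cells, and high-dimensional
  joint grids grow exponentially. The pointwise density itself never
  suffers from this — only integrals do.
* **Histogram comparisons are statistical.** With hundreds of populated
  cells, individual |z| values above 3 occur at the chance level even when
  the method is exact; the Monte Carlo agreement checks therefore bound the
  *fraction* of 3σ exceedances (≤ 1%) and the gross maximum, rather than
  asserting every cell within 3σ.
* **Full-state observation only.** Likelihoods evaluate the joint output
  density at complete state vectors; marginal likelihoods for partially
  observed states are not implemented.
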