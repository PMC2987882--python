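# Maximum-likelihood estimation of V_max from one observation xi(20) = 5,
# profiling V_max over [0, 2] (node-inclusive, spacing 0.05) under a joint
# normal prior on (x0, V_max) with mean (2, 1) and variances (0.2, 0.01).
# The tight prior dominates: the estimate stays near the prior mean 1.
task: profile
model:
  name: autoregulation
  params: {K: 2.0, k_d: 0.01, beta: 4.0}
profiled: [V_max]
initial_density:
  kind: normal
  mean: [2.0, 1.0]
  cov_diag: [0.2, 0.01]
data:
  time: 20.0
  points: [[5.0]]
param_grid:
  axes:
    - {lo: 0.0, hi: 2.0, h: 0.05}
settings: {rel_tol: 1.0e-8, abs_tol: 1.0e-10}
seed: 0
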