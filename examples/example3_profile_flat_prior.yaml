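# Same estimation problem as example3_profile_normal_prior.yaml but with no
# prior information on V_max beyond its range: x0 ~ N(2, 0.2) independent of
# V_max ~ uniform on [0, 2].  The estimate is now driven by the dynamics
# alone and drops to about 0.2 (the observation 5 at t = 20 is unlikely for
# larger expression rates).
task: profile
model:
  name: autoregulation
  params: {K: 2.0, k_d: 0.01, beta: 4.0}
profiled: [V_max]
initial_density:
  components:
    - {kind: normal, mean: [2.0], var: [0.2]}
    - {kind: uniform, lo: [0.0], hi: [2.0]}
data:
  time: 20.0
  points: [[5.0]]
param_grid:
  axes:
    - {lo: 0.0, hi: 2.0, h: 0.05}
settings: {rel_tol: 1.0e-8, abs_tol: 1.0e-10}
seed: 0
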