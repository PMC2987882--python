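# Variability in the maximal expression rate: joint density of
# (x, V_max) at t = 50 on a cell-centered grid, then the marginal
# protein-concentration density by midpoint-rule integration over V_max.
task: marginal
model:
  name: autoregulation
  params: {K: 2.0, k_d: 0.01, beta: 4.0}
extended_by: [V_max]
initial_density:
  components:
    - {kind: normal, mean: [2.0], var: [0.2]}
    - {kind: normal, mean: [1.0], var: [0.025]}
time: 50.0
region:
  axes:
    - {lo: 0.0, hi: 60.0, h: 1.0}
    - {lo: 0.5, hi: 1.5, h: 0.01}
keep_axes: [0]
settings: {rel_tol: 1.0e-8, abs_tol: 1.0e-10}
seed: 0
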