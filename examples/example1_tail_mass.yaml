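# Heavy tail of autoregulated gene expression: probability mass of the
# protein-concentration interval [0, 10] at t = 50, computed by the
# backward-forward procedure on a cell-centered grid with h = 0.1.
task: region-mass
model:
  name: autoregulation
  params: {V_max: 1.0, K: 2.0, k_d: 0.01, beta: 4.0}
initial_density:
  kind: normal
  mean: [2.0]
  var: [0.2]
time: 50.0
region:
  axes:
    - {lo: 0.0, hi: 10.0, h: 0.1}
settings: {rel_tol: 1.0e-8, abs_tol: 1.0e-10}
seed: 0
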