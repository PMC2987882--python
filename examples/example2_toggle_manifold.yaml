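# Genetic toggle switch: forward propagation of a node grid over the
# initial bulk, showing the density contracting onto the slow manifold of
# the vector field (steep, strongly non-normal by t = 10).
task: propagate
model:
  name: toggle_switch
  params: {alpha1: 5.0, alpha2: 5.0, beta1: 2.0, beta2: 2.0, q1: 1.0, q2: 1.0, k_d: 1.0}
initial_density:
  kind: normal
  mean: [3.0, 3.0]
  cov_diag: [0.1, 0.1]
initial_points:
  axes:
    - {lo: 2.0, hi: 4.0, h: 0.1}
    - {lo: 2.0, hi: 4.0, h: 0.1}
times: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
settings: {rel_tol: 1.0e-8, abs_tol: 1.0e-10}
seed: 0
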