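K: 200
cancer:
  b:
    x: 3.0
    y: 3.0
  c:
    x|x: 1.0
    x|y: 0.5
    y|x: 0.5
    y|y: 1.0
  d:
    x: 1.0
    y: 1.0
  kill_burst:
    x|z_x|w: 2
  s_cyt:
    w|x|y: 2.0
  s_nat:
    x|y: 0.01
    y|x: 0.01
  t_kill:
    x|z_x: 4.0
cytokines:
  d_W:
    w: 10.0
init:
  counts:
    x: 200
    y: 10
mu_scaling: constant
run:
  base_seed: 1000
  name: one_tcell_qualitative
  record_dt: 0.1
  replicates: 200
  t_max: 50.0
  t_start: 0.0
  therapy_schedule:
  - - 0.0
    - z_x
    - 10
  thresholds:
    differentiated:
    - x
    relapse_frac: 0.9
    remission_frac: 0.01
space:
  cytokine_types:
  - w
  genotypes:
  - g
  phenotypes_of:
    g:
    - x
    - y
  tcell_types:
  - z_x
tcells:
  b_T:
    z_x: 1.0
  d_T:
    z_x: 3.0
  rep_burst:
    z_x|w: 1
  t_prod:
    z_x|x: 8.0
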