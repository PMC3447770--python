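groups:
- name: mossy_fibers
  count: 24
  role: input
  subgroups: 1
  k_fraction: null
  kwta: true
  act_scale: null
- name: climbing_fibers
  count: 3
  role: input
  subgroups: 1
  k_fraction: null
  kwta: true
  act_scale: null
- name: granule
  count: 3300
  role: hidden
  subgroups: 1
  k_fraction: 0.05
  kwta: true
  act_scale: 0.025
- name: golgi
  count: 300
  role: hidden
  subgroups: 1
  k_fraction: null
  kwta: false
  act_scale: null
- name: basket
  count: 130
  role: hidden
  subgroups: 1
  k_fraction: null
  kwta: false
  act_scale: null
- name: purkinje
  count: 15
  role: hidden
  subgroups: 3
  k_fraction: null
  kwta: false
  act_scale: null
- name: deep_nuclei
  count: 2
  role: output
  subgroups: 1
  k_fraction: null
  kwta: false
  act_scale: null
connections:
- source: mossy_fibers
  target: granule
  sign: excitatory
  strength: 4.0
  subgroup_aligned: false
  fan_in: 4
  plastic: true
- source: granule
  target: golgi
  sign: excitatory
  strength: 1.0
  subgroup_aligned: false
  fan_in: null
  plastic: true
- source: golgi
  target: granule
  sign: inhibitory
  strength: 1.0
  subgroup_aligned: false
  fan_in: 10
  plastic: false
- source: granule
  target: basket
  sign: excitatory
  strength: 1.0
  subgroup_aligned: false
  fan_in: 330
  plastic: true
- source: granule
  target: purkinje
  sign: excitatory
  strength: 1.0
  subgroup_aligned: false
  fan_in: 330
  plastic: true
- source: basket
  target: purkinje
  sign: inhibitory
  strength: 1.0
  subgroup_aligned: false
  fan_in: null
  plastic: false
- source: climbing_fibers
  target: purkinje
  sign: excitatory
  strength: 26000.0
  subgroup_aligned: true
  fan_in: null
  plastic: true
- source: purkinje
  target: deep_nuclei
  sign: inhibitory
  strength: 1.0
  subgroup_aligned: false
  fan_in: null
  plastic: true
- source: climbing_fibers
  target: deep_nuclei
  sign: excitatory
  strength: 1.0
  subgroup_aligned: false
  fan_in: null
  plastic: true
dynamics:
  tau: 0.2
  cycles: 30
  gain: 50.0
  threshold: 0.5
  kwta_pt: 0.25
  update_mode: per_epoch
  abort_activation: 1000.0
  settle_tol: 0.0001
learning:
  lrate: 0.2
  lrate_cap: 10.0
  hebb: 0.01
  cpca_correction: 1.0
  bias_lrate: 0.2
  err_tol: 0.5
  criterion: 5.0e-07
  max_epochs: 2000
  shuffle: false
stimuli:
  n_samples: 140
  slow_change_bound: 0.15
  sample_dt: 0.25
  table_order: false
flags:
  include_nuclear_collaterals: true
weight_init:
- 0.25
- 0.75
dtype: float32
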