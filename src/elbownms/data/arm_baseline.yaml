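# Classic double-muscle elbow arm ("arm_baseline"): one lumped biceps
# and one lumped triceps, both on straight-line (triangle) paths.  The
# straight-line triceps is the known anatomical deviation of this
# model.  All lumping choices are FIXTURE CHOICES, not published
# values: biceps = two heads on the long-head path with summed maximal
# forces; triceps = three heads on a posterior straight line
# (origin on the posterior humerus, insertion at the olecranon) with
# summed maximal forces and l_0 chosen so the lumped fiber sits at its
# optimal length at full extension.
formula:
  gamma: 0.5
  A_s: 0.25
  f_M: 1.8
  v_max_factor: 8.0
  k_PE: 4.0
  eps0_M: 0.5
  k_s: 0.004
  A_nl: -1.0
  tendon_scale: 1.02

muscles:
  - name: biceps
    group: flexor
    l_mopt: 0.116
    l_topt: 0.272
    F_0: 1059.9
    phi0_deg: 0.0
    origin: [0.023, 0.0, 0.115]
    insertion: [0.007, 0.0, -0.047]
    l_0: 0.263
  - name: triceps
    group: extensor
    l_mopt: 0.134
    l_topt: 0.143
    F_0: 2047.1
    phi0_deg: 10.0
    origin: [-0.010, 0.0, 0.120]
    insertion: [-0.020, 0.0, 0.020]
    l_0: 0.1794

options:
  extensor_base: slack
  literal_eq15: false

profiles:
  biceps: {peak: 0.50, t_peak: 0.75, width: 0.28}
  triceps: {peak: 0.10, t_peak: 1.00, width: 0.22}
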