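# Six-muscle elbow arm model ("arm_default").
#
# formula: shared Hill-curve constants.
# muscles: published physiological constants per muscle.  Flexor path
#   points are elbow-centred sagittal coordinates (m) at full extension:
#   x anterior, y medial, z superior; the forearm points along -z.
#   l_0 is the path segment outside the origin/insertion triangle
#   (shoulder-side segment for the biarticular biceps heads).
# r_0 (triceps moment arm at full extension) is a FIXTURE CHOICE, not a
#   published table value: 0.022 m, within the range reported for the
#   elbow extensors.  All three triceps heads share the same olecranon
#   tendon, hence the same r_0.
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
  - name: biceps_long
    group: flexor
    l_mopt: 0.116
    l_topt: 0.272
    F_0: 624.3
    phi0_deg: 0.0
    origin: [0.023, 0.0, 0.115]
    insertion: [0.007, 0.0, -0.047]
    l_0: 0.263
  - name: biceps_short
    group: flexor
    l_mopt: 0.132
    l_topt: 0.192
    F_0: 435.6
    phi0_deg: 0.0
    origin: [0.023, 0.0, 0.115]
    insertion: [0.007, 0.0, -0.047]
    l_0: 0.178
  - name: brachialis
    group: flexor
    l_mopt: 0.086
    l_topt: 0.054
    F_0: 987.3
    phi0_deg: 0.0
    origin: [0.008, 0.0, 0.115]
    insertion: [0.007, 0.0, -0.023]
    l_0: 0.010
  - name: triceps_long
    group: extensor
    l_mopt: 0.134
    l_topt: 0.143
    F_0: 798.5
    phi0_deg: 12.0
    r_0: 0.022
  - name: triceps_lateral
    group: extensor
    l_mopt: 0.114
    l_topt: 0.091
    F_0: 624.3
    phi0_deg: 9.0
    r_0: 0.022
  - name: triceps_medial
    group: extensor
    l_mopt: 0.114
    l_topt: 0.098
    F_0: 624.3
    phi0_deg: 9.0
    r_0: 0.022

options:
  extensor_base: slack
  literal_eq15: false

# Synthetic activation profiles emulating computed-muscle-control
# exports for the 0-90-0 degree flexion-extension task: flexor bumps
# peak during the lift (0.5-0.8 s), triceps bumps are small and centred
# at peak flexion (1 s), stabilising the joint.
profiles:
  biceps_long: {peak: 0.55, t_peak: 0.75, width: 0.28}
  biceps_short: {peak: 0.35, t_peak: 0.75, width: 0.28}
  brachialis: {peak: 0.50, t_peak: 0.80, width: 0.30}
  triceps_long: {peak: 0.15, t_peak: 1.00, width: 0.20}
  triceps_lateral: {peak: 0.08, t_peak: 1.00, width: 0.25}
  triceps_medial: {peak: 0.08, t_peak: 1.00, width: 0.25}
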