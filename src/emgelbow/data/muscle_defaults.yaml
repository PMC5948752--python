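# Elbow muscle model constants.
#
# Fmax pools the major flexor group (biceps short/long head, brachialis,
# brachioradialis, pronator teres) into the "biceps" entry and the extensor
# group (triceps heads, anconeus) into "triceps". lmo_m and lslack_m are
# plausible subject ranges; a concrete subject samples lmo_m inside its range
# and uses ls_policy to set the muscle slack length (lmo: LS = LMo, the
# low-passive-force choice). ldotmmax_per_lmo scales the maximum shortening
# velocity with optimal fibre length (LdotMmax = 10 * LMo per second).
#
# Geometry polynomials are in ascending powers of the joint angle theta in
# radians (0 = full extension, positive flexion, range 0-150 deg):
#   lm_shape_coeffs: LM(theta) / LMo  — dimensionless fibre-length shape
#   lmt_coeffs:      LMT(theta) in metres — musculotendon path length
# The flexor path shortens with flexion and the extensor path lengthens, so
# the tendon-excursion moment arms r = -dLMT/dtheta have opposite signs.
#
# k1/k2 (parallel-elastic stiffness) have no published values for this model;
# the shipped numbers are soft defaults and are configurable.

biceps:
  fmax_n: 2874.67
  lmo_m: [0.1106, 0.1361]
  phi_o_rad: 0.0
  w: 0.56
  a_hill: 0.25
  gmax: 1.5
  lslack_m: [0.1659, 0.2042]
  ls_policy: lmo
  ldotmmax_per_lmo: 10.0
  k1_n_per_m: 10.0
  k2_n_per_m2: 1000.0
  lm_shape_coeffs: [1.08, -0.08, 0.01, -0.002]
  lmt_coeffs: [0.300, -0.025, -0.003, 0.0]

triceps:
  fmax_n: 2397.12
  lmo_m: [0.1236, 0.1681]
  phi_o_rad: 0.2094
  w: 0.56
  a_hill: 0.25
  gmax: 1.5
  lslack_m: [0.1854, 0.2522]
  ls_policy: lmo
  ldotmmax_per_lmo: 10.0
  k1_n_per_m: 10.0
  k2_n_per_m2: 1000.0
  lm_shape_coeffs: [0.93, 0.05, 0.005, 0.0005]
  lmt_coeffs: [0.320, 0.020, 0.002, 0.0]
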