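# Shipped calibrated parameter set (strict SI units).
# Recovered from the documented experimental constraints; see docs/methods.md.
units: si
parameters:
  Lp: 1.0e-12
  A_osm: 1.7474e-11
  eps: 1000000.0
  Pc: 199000.0
  v_ext: 7.8965e-15
  Osm_i: 0.5073561513829458
  osmolyte_dynamic: true
  eta_eq: 25000000.0
  k1: 0.35
  k2a: 2.15e-14
  kOC0: 0.2
  kCO0: 2.721472594499087e-20
  ka: 0.0002
  g_Ca_sa: 8.0
  g_K_sa: 2.0
  stretch_cl_enabled: false
  g_Cl_sa: 0.0
  vg1:
    kind: ghk
    ion: K
    g: 0.3
    vhalf: -0.05
    slope: -0.01
    tau: 0.0
  vg2:
    kind: ghk
    ion: K
    g: 120.0
    vhalf: -0.065
    slope: -0.008
    tau: 60.0
  vg3:
    kind: ghk
    ion: Ca
    g: 80.0
    vhalf: -0.075
    slope: -0.006
    tau: 0.0
  pump:
    imax: 0.0006
    vhalf: -0.15
    slope: 0.02
  symporter:
    g: 0.0024
  vg6:
    kind: ohmic
    ion: Cl
    g: 0.0004
    vhalf: null
    slope: 0.01
    tau: 0.0
  k_relax_Ca: 0.3
  k_relax_H: 0.5
  k_relax_K: 0.02
  k_relax_Cl: 0.02
  setpoint_Ca: 2.0e-07
  setpoint_H: 1.0e-07
  setpoint_K: 0.0503
  setpoint_Cl: 0.0121
  buffer_strength_Ca: 0.0
  buffer_strength_H: 500.0
  Cm: 0.01
  r0: 5.0e-06
  ri0: 4.6e-06
  L0: 0.0002
  h0: 4.0e-07
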