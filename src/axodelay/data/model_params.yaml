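# Printed parameter set of the model axon, key for key.
# Conductances in mS/cm^2, potentials in mV, time constants in ms.
channels:
  Na:   {gbar: 14.0,  erev: dynamic}
  Kd:   {gbar: 3.0,   erev: -70.0}
  Leak: {gbar: 0.125, erev: -65.0}
  A:    {gbar: 5.0,   erev: -70.0}
  h_ctrl: {gbar: 0.05, erev: -32.0}
  h_DA:   {gbar: 0.1,  erev: -25.0}
  Ks:   {gbar: 3.0,   erev: -70.0}
pump:
  i_max_ma_cm2: 2.0        # printed as 2 mA/cm^2
  na_half_mm: 78.0
  na_s_mm: 2.0
  alpha: 7.4
  vol_um3: 7850.0
  faraday_c_mol: 96485.0
gating:
  Na_m:     {p: 3, v_half: -48.0, k: 8.5,
             tau: {kind: cosh_sigmoid, a: 0.132, v0: -27.0, s: 7.5, b: 0.003, v1: -27.0, s1: 5.0}}
  Na_h:     {q: 1, v_half: -47.0, k: -6.0,
             tau: {kind: cosh, a: 10.0, v0: -42.0, s: 15.0}}
  Kd_m:     {p: 4, v_half: -47.0, k: 10.0,
             tau: {kind: cosh, a: 50.0, v0: -73.0, s: 15.0}}
  A_m:      {p: 3, v_half: -63.0, k: 15.0,
             tau: {kind: sigmoid, a: 18.0, b: 58.0, v0: -61.0, s: 20.0}}
  A_h:      {q: 1, v_half: -80.0, k: -8.0, tau: {kind: const, a: 50.0}}
  h_ctrl_m: {p: 1, v_half: -80.0, k: -5.5, tau: {kind: const, a: 3700.0}}
  h_DA_m:   {p: 1, v_half: -75.0, k: -12.5, tau: {kind: const, a: 3800.0}}
  Ks_m:     {p: 1, v_half: -47.0, k: 10.0,
             tau: {kind: cosh, a: 250000.0, v0: -73.0, s: 15.0}}
geometry:
  radius_um: 5.0
  length_cm: 1.0
  n_comp: 101
  ri_ohm_cm: 80.0
  cm_uf_cm2: 1.0
  rm_kohm_cm2: 8.0
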