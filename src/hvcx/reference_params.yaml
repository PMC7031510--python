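# Reference parameterization of the single-compartment HVC_X model.
# All constants are explicit and versioned; the five varied maximal
# conductances (g_Na, g_K, g_SK, g_h, g_CaT) are the reference fitting
# targets, the rest are held fixed.  Units: mV, ms, pA, pF, nS, uM.
#
# Steady-state gates use x_inf(V) = 1 / (1 + exp((half - V) / slope));
# a negative slope makes the gate an inactivation/hyperpolarization-
# activated gate.  Voltage-dependent time constants are Gaussian bumps:
# tau(V) = base + amp * exp(-((V - mid) / width)^2).
version: hvcx-reference-1
capacitance_pF: 50.0            # adult somatic capacitance; juveniles use 75 pF
conductances_nS:
  g_Na: 800.0
  g_K: 250.0
  g_SK: 3.0
  g_h: 4.0
  g_CaT: 3.0
  g_CaL: 1.2                    # fixed: indistinguishable from g_SK in fits
  g_A: 2.0                      # fixed: very small conductance in HVC_X
  g_L: 1.8
reversals_mV:
  E_Na: 55.0
  E_K: -90.0
  E_h: -35.0
  E_Ca: 120.0                   # fixed ohmic driving force, no GHK
  E_L: -80.0
sodium:                          # I_Na = g_Na * m_inf(V)^3 * h * (V - E_Na)
  m_half: -42.0
  m_slope: 6.0
  h_half: -45.0
  h_slope: -7.0
  tau_h_base: 0.1
  tau_h_amp: 1.2
  tau_h_mid: -50.0
  tau_h_width: 15.0
potassium:                       # I_K = g_K * n^4 * (V - E_K)
  n_half: -33.0
  n_slope: 8.0
  tau_n_base: 0.3
  tau_n_amp: 1.5
  tau_n_mid: -50.0
  tau_n_width: 20.0
ca_t:                            # I_CaT = g_CaT * a_inf(V)^2 * b * (V - E_Ca)
  a_half: -56.0
  a_slope: 5.5
  b_half: -70.0
  b_slope: -4.0
  tau_b: 80.0                    # slow deinactivation -> rebound firing
h_current:                       # I_h = g_h * r * (V - E_h)
  r_half: -80.0
  r_slope: -5.0
  tau_r: 100.0
ca_l:                            # I_CaL = g_CaL * s_inf(V)^2 * (V - E_Ca)
  s_half: -20.0
  s_slope: 8.0
a_current:                       # I_A = g_A * e_inf(V) * f * (V - E_K)
  e_half: -45.0
  e_slope: 10.0
  f_half: -70.0
  f_slope: -6.0
  tau_f: 20.0
calcium_pool:                    # dCa/dt = -influx*(I_CaT + I_CaL) - (Ca - base)/tau
  influx: 0.0015                  # uM per pA*ms of inward Ca current
  tau_ca: 50.0                   # ms
  ca_base: 0.05                  # uM
  k_s: 0.5                       # uM, SK half-activation: Ca^2/(Ca^2 + k_s^2)
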