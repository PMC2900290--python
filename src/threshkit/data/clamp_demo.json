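{
  "name": "clamp_demo",
  "comment": "Na-only membrane for the simulated voltage-clamp protocol. The Boltzmann (V_half, k) pairs describe the steady-state conductance activation/inactivation curves; the activation transient follows the m^3 h convention (gate equilibrium = cube root of the activation curve).",
  "g_max_nS": 100.0,
  "E_Na_mV": 55.0,
  "activation": {"V_half_mV": -30.0, "k_mV": 6.0, "tau_ms": 0.3, "exponent": 3, "curve": "conductance"},
  "inactivation": {"V_half_mV": -65.0, "k_mV": 6.0, "tau_ms": 0.3, "exponent": 1},
  "protocol": {"V0_mV": -70.0, "V_step_min_mV": -100.0, "V_step_max_mV": 50.0, "V_step_increment_mV": 1.0, "duration_ms": 20.0, "dt_ms": 0.01, "fit_window_mV": [-100.0, -40.5]}
}
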