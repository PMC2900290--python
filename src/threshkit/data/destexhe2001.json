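{
  "name": "destexhe2001_point_conductance",
  "comment": "Single-compartment cortical neuron with fluctuating synaptic conductances (point-conductance model). Densities per membrane area; Traub-Miles kinetics for Na (m^3 h) and delayed-rectifier K (n^4), slow non-inactivating K current (p).",
  "area_um2": 34636.0,
  "C_uF_cm2": 1.0,
  "g_L_mS_cm2": 0.045,
  "E_L_mV": -80.0,
  "Na": {
    "G_mS_cm2": 48.0,
    "E_mV": 50.0,
    "m": {"rates": "traub_m", "exponent": 3},
    "h": {"rates": "traub_h", "exponent": 1}
  },
  "Kd": {
    "G_mS_cm2": 10.0,
    "E_mV": -90.0,
    "n": {"rates": "traub_n", "exponent": 4}
  },
  "M": {
    "G_mS_cm2": 0.5,
    "E_mV": -90.0,
    "p": {"rates": "im_p", "exponent": 1}
  },
  "background": {
    "g_e0_nS": 12.1,
    "sigma_e_nS": 12.0,
    "tau_e_ms": 2.728,
    "E_e_mV": 0.0,
    "g_i0_nS": 57.3,
    "sigma_i_nS": 26.4,
    "tau_i_ms": 10.49,
    "E_i_mV": -75.0
  }
}
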