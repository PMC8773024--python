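{
  "vehicle": "water",
  "log_k_vehicle_water": {"CAF": 0.0, "CHA": 0.0, "FA": 0.0},
  "shunt_conductance_m_per_s": 2e-11,
  "offset_log10_cm_per_s": -1.12,
  "log_kd_m_per_s": -9.0,
  "references_log10_cm_per_s": {
    "caco2": {"CAF": -5.84, "CHA": -5.60, "FA": -4.98},
    "epidermis_calc": {"CAF": -6.85, "FA": -7.15}
  }
}
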