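{
  "comment": "Values as printed in the original Calendula officinalis SAF + skin-permeability study; used by the reproduce report to display published value, recomputed value and |delta|.",
  "quadratic_fits": {
    "y_pv_pct": {
      "terms": "no_flow_sq",
      "coefficients": {"intercept": 284.3, "P": -3.594, "Q": -2.204, "P2": 0.01215, "PQ": 0.01620},
      "p_values": {"intercept": 0.000, "P": 0.075, "Q": 0.019, "P2": 0.000, "PQ": 0.006},
      "r_squared_pct": 88.28,
      "residual_sd": 4.42
    },
    "y_dv_pct": {
      "terms": "full",
      "coefficients": {"intercept": -40.3, "P": 1.241, "Q": -1.691, "P2": -0.00493, "Q2": 0.00898, "PQ": 0.00900},
      "p_values": {"intercept": 0.000, "P": 0.000, "Q": 0.833, "P2": 0.035, "Q2": 0.105, "PQ": 0.058},
      "r_squared_pct": 91.26,
      "residual_sd": 4.00
    },
    "y_saf_pct": {
      "terms": "full",
      "coefficients": {"intercept": 242.6, "P": -2.343, "Q": -3.835, "P2": 0.00717, "Q2": 0.00812, "PQ": 0.02520},
      "p_values": {"intercept": 0.000, "P": 0.000, "Q": 0.003, "P2": 0.001, "Q2": 0.040, "PQ": 0.000},
      "r_squared_pct": 96.74,
      "residual_sd": 2.66
    },
    "e_cha_pv": {
      "terms": "no_interaction",
      "coefficients": {"intercept": -3.889, "P": 0.0796, "Q": 0.0253, "P2": -0.000314, "Q2": -0.000395},
      "p_values": {"intercept": 0.000, "P": 0.026, "Q": 0.381, "P2": 0.001, "Q2": 0.034},
      "r_squared_pct": 83.00,
      "residual_sd": 0.13
    },
    "e_fa_pv": {
      "terms": "no_interaction",
      "coefficients": {"intercept": -4.11, "P": 0.0835, "Q": 0.0160, "P2": -0.000315, "Q2": -0.000262},
      "p_values": {"intercept": 0.000, "P": 0.003, "Q": 0.454, "P2": 0.002, "Q2": 0.189},
      "r_squared_pct": 82.91,
      "residual_sd": 0.15
    },
    "e_all_pv": {
      "terms": "no_interaction",
      "coefficients": {"intercept": -3.840, "P": 0.0802, "Q": 0.0166, "P2": -0.000308, "Q2": -0.000264},
      "p_values": {"intercept": 0.000, "P": 0.004, "Q": 0.479, "P2": 0.001, "Q2": 0.125},
      "r_squared_pct": 84.54,
      "residual_sd": 0.13
    }
  },
  "optimum": {"pressure_bar": 153.0, "co2_flow_g_min": 42.0, "composite_desirability": 0.673},
  "e_all_pv_maximum_region": {"pressure_bar": [118.0, 142.0], "co2_flow_g_min": [18.0, 44.0]},
  "skin": {
    "CAF": {
      "R_SC": 4.07e7, "R_SG": 1.22e7, "R_SS": 2.09e7, "R_SB": 3.72e6,
      "R_cells": 7.75e7, "R_skin": 7.74e7,
      "log_kp_pred": -5.89, "log_kp_corrected": -7.01,
      "rate_limiting": "SC", "deviation_caco2": 1.17, "deviation_epidermis_calc": 0.16
    },
    "CHA": {
      "R_SC": 1.76e8, "R_SG": 5.13e8, "R_SS": 1.16e9, "R_SB": 8.06e7,
      "R_cells": 1.93e9, "R_skin": 1.86e9,
      "log_kp_pred": -7.27, "log_kp_corrected": -8.39,
      "rate_limiting": "SS", "deviation_caco2": 2.79
    },
    "FA": {
      "R_SC": 3.23e7, "R_SG": 1.61e6, "R_SS": 2.88e6, "R_SB": 6.29e5,
      "R_cells": 3.74e7, "R_skin": 3.74e7,
      "log_kp_pred": -5.57, "log_kp_corrected": -6.69,
      "rate_limiting": "SC", "deviation_caco2": 1.71, "deviation_epidermis_calc": -0.46
    }
  }
}
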