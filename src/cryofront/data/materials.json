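{
  "_schema": {
    "description": "Built-in thermophysical property library. Each material carries piecewise temperature-dependent models for density [kg/m^3], thermal conductivity [W/(m K)] and sensible heat capacity [J/(kg K)], plus phase-change constants. Temperatures are in degrees Celsius throughout.",
    "branch": "A branch is {'range': [T_lo, T_hi], 'terms': [[kind, params], ...], 'scale': optional multiplier}. Branches are evaluated half-open on the low side, [T_lo, T_hi); the topmost branch is closed at its upper end. The branch value is scale * sum(terms).",
    "term_kinds": {
      "poly": "params [c0, c1, c2, ...] -> c0 + c1*T + c2*T^2 + ...",
      "lin_shift": "params [a, T0] -> a*(T - T0)",
      "inv_diff": "params [a, Tref] -> a*(1/T - 1/Tref)",
      "pow_negT": "params [a, p] -> a*(-T)^p  (frozen side only, T < 0)",
      "inv_sq_shift": "params [a, c] -> a/(c - T)^2",
      "t_inv_sq_shift": "params [a, c] -> a*T/(c - T)^2"
    },
    "phase_change": "{'T_f': cryoscopic temperature (upper bound of the mushy range), 'T_m': initial melting temperature (lower bound), 'L_eff': effective latent heat J/kg, 'embedded': true if the latent heat is already folded into the sensible-capacity branches (muscle)}. null for media without phase change.",
    "valid_range": "temperature span of the source data; outside it properties are clamped to the boundary value (a warning is issued once)."
  },
  "hydrogel_5pct": {
    "valid_range": [-160.0, 40.0],
    "phase_change": {"T_f": -0.1, "T_m": -14.0, "L_eff": 295089.0, "embedded": false},
    "density": [
      {"range": [-160.0, -14.0], "terms": [["poly", [935.79, 0.08715, 0.00017428]]]},
      {"range": [-14.0, -0.1], "terms": [["poly", [1018.2, 16.927, 1.2044, 0.02925]]]},
      {"range": [-0.1, 40.0], "terms": [["poly", [935.79, 0.08715, 0.00017428]]]}
    ],
    "conductivity": [
      {"range": [-160.0, -2.8], "terms": [["poly", [2.191, -0.0118, -6.57e-05]]]},
      {"range": [-2.8, 40.0], "terms": [["poly", [0.615, 0.00181]]]}
    ],
    "sensible_cp": [
      {"range": [-160.0, -0.1], "terms": [["poly", [2.1, 0.0079, 7.1e-06]]], "scale": 1000.0},
      {"range": [-0.1, 40.0], "terms": [["poly", [3.95, 0.00125]]], "scale": 1000.0}
    ]
  },
  "skin": {
    "valid_range": [-50.0, 40.0],
    "phase_change": {"T_f": -0.53, "T_m": -9.15, "L_eff": 230000.0, "embedded": false},
    "density": [
      {"range": [-50.0, -0.53], "terms": [["poly", [1039.0]]]},
      {"range": [-0.53, 40.0], "terms": [["poly", [1100.0]]]}
    ],
    "conductivity": [
      {"range": [-50.0, -0.53], "terms": [["poly", [1.72]], ["pow_negT", [0.0046, 1.156]]]},
      {"range": [-0.53, 40.0], "terms": [["poly", [0.424]]]}
    ],
    "sensible_cp": [
      {"range": [-50.0, -0.53], "terms": [["lin_shift", [5.51, -273.0]], ["poly", [143.0]]]},
      {"range": [-0.53, 40.0], "terms": [["poly", [2742.87, 13.166]]]}
    ]
  },
  "subcutaneous_fat": {
    "valid_range": [-50.0, 40.0],
    "phase_change": {"T_f": -5.0, "T_m": -10.0, "L_eff": 100000.0, "embedded": false},
    "density": [
      {"range": [-50.0, -5.0], "terms": [["poly", [978.6]]]},
      {"range": [-5.0, 40.0], "terms": [["poly", [986.47, -0.44503]]]}
    ],
    "conductivity": [
      {"range": [-50.0, -5.0], "terms": [["poly", [0.223]], ["lin_shift", [-0.000306, -5.0]], ["inv_diff", [0.051, -5.0]]]},
      {"range": [-5.0, 40.0], "terms": [["poly", [0.223]], ["lin_shift", [-5.1e-05, -5.0]]]}
    ],
    "sensible_cp": [
      {"range": [-50.0, -5.0], "terms": [["lin_shift", [6.51, -273.0]], ["poly", [153.0]]]},
      {"range": [-5.0, 40.0], "terms": [["poly", [2100.0, 4.0]]]}
    ]
  },
  "muscle": {
    "valid_range": [-50.0, 40.0],
    "phase_change": {"T_f": -0.91, "T_m": -10.0, "L_eff": 250000.0, "embedded": true},
    "density": [
      {"range": [-50.0, -0.91], "terms": [["poly", [988.3]]]},
      {"range": [-0.91, 40.0], "terms": [["poly", [1047.0]]]}
    ],
    "conductivity": [
      {"range": [-50.0, -0.91], "terms": [["poly", [0.46791]], ["lin_shift", [-0.00655, 0.91]], ["inv_diff", [0.71175, -0.91]]]},
      {"range": [-0.91, 40.0], "terms": [["poly", [0.4838, 0.000924]]]}
    ],
    "sensible_cp": [
      {"range": [-50.0, -10.0], "terms": [["t_inv_sq_shift", [-47624.4, 0.46]]]},
      {"range": [-10.0, -0.91], "terms": [["inv_sq_shift", [380402.7, 0.46]]]},
      {"range": [-0.91, 40.0], "terms": [["poly", [3347.8, 4.1124]]]}
    ]
  },
  "air_effective": {
    "valid_range": [-200.0, 45.0],
    "phase_change": null,
    "density": [
      {"range": [-200.0, 45.0], "terms": [["poly", [1.2]]]}
    ],
    "conductivity": [
      {"range": [-200.0, 45.0], "terms": [["poly", [0.026]]]}
    ],
    "sensible_cp": [
      {"range": [-200.0, 45.0], "terms": [["poly", [1005.0]]]}
    ]
  }
}
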