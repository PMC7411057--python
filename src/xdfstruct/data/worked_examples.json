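{
  "comment": "Published reference measurements used by reproduce_worked_examples: interferometer geometry, per-bin weighted energies/wavelengths, and per-material -ln D values for both detector energy bins, with the published normalized values -lnD/lambda_w^2 for comparison.",
  "geometry": {"d_S_G2_m": 0.571, "p_G2_um": 10.0, "design_energy_keV": 45.0},
  "bins": {
    "low": {"E1_keV": 23.0, "E2_keV": 64.0, "E_w_keV": 43.0, "lambda_w_A": 0.29, "xi_w_um": 1.65},
    "high": {"E1_keV": 64.0, "E2_keV": 120.0, "E_w_keV": 80.9, "lambda_w_A": 0.15, "xi_w_um": 0.88}
  },
  "neg_log_D": {
    "CR-L": {"low": 1.07, "high": 0.36},
    "PU": {"low": 0.50, "high": 0.13},
    "K1": {"low": 0.65, "high": 0.24},
    "S60": {"low": 2.05, "high": 0.93}
  },
  "published_normalized": {
    "CR-L": {"low": 12.72, "high": 16.00},
    "PU": {"low": 5.95, "high": 5.78},
    "K1": {"low": 7.73, "high": 10.67},
    "S60": {"low": 24.38, "high": 41.33}
  }
}
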