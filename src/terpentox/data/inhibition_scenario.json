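{
  "description": "Per-compound bioluminescence-inhibition plateau levels (fractions of the control signal) at the four assay concentrations (uM), transcribed from the study's reported 20-min inhibition percentages; compounds without an individually reported value carry the stated class-level bound for that concentration.",
  "plateaus": {
    "nerol":                  {"1": 0.03, "10": 0.15, "50": 0.40, "100": 0.55},
    "geraniol":               {"1": 0.06, "10": 0.15, "50": 0.40, "100": 0.55},
    "p_cymene":               {"1": 0.03, "10": 0.15, "50": 0.40, "100": 0.55},
    "limonene":               {"1": 0.03, "10": 0.28, "50": 0.40, "100": 0.55},
    "borneol":                {"1": 0.03, "10": 0.10, "50": 0.15, "100": 0.16},
    "eucalyptol":             {"1": 0.03, "10": 0.10, "50": 0.15, "100": 0.15},
    "linalool":               {"1": 0.03, "10": 0.15, "50": 0.40, "100": 0.55},
    "alpha_terpineol":        {"1": 0.03, "10": 0.15, "50": 0.40, "100": 0.55},
    "beta_citronellol":       {"1": 0.04, "10": 0.52, "50": 0.55, "100": 0.60},
    "menthol":                {"1": 0.03, "10": 0.12, "50": 0.25, "100": 0.29},
    "carvone":                {"1": 0.03, "10": 0.12, "50": 0.32, "100": 0.39},
    "citral":                 {"1": 0.09, "10": 0.18, "50": 0.45, "100": 0.55},
    "citronellal":            {"1": 0.08, "10": 0.25, "50": 0.45, "100": 0.55},
    "geranic_acid":           {"1": 0.20, "10": 0.26, "50": 0.45, "100": 0.55},
    "linalool_oxide":         {"1": 0.03, "10": 0.10, "50": 0.15, "100": 0.20},
    "alpha_terpinyl_acetate": {"1": 0.11, "10": 0.32, "50": 0.45, "100": 0.55},
    "beta_caryophyllene":     {"1": 0.02, "10": 0.08, "50": 0.15, "100": 0.19},
    "alpha_cedrene":          {"1": 0.02, "10": 0.12, "50": 0.35, "100": 0.50},
    "alpha_neoclovene":       {"1": 0.02, "10": 0.12, "50": 0.35, "100": 0.46},
    "valencene":              {"1": 0.02, "10": 0.08, "50": 0.12, "100": 0.14},
    "z_nerolidol":            {"1": 0.04, "10": 0.28, "50": 0.45, "100": 0.55},
    "alpha_bisabolol":        {"1": 0.04, "10": 0.26, "50": 0.42, "100": 0.55},
    "guaiazulene":            {"1": 0.02, "10": 0.08, "50": 0.14, "100": 0.16},
    "farnesol":               {"1": 0.04, "10": 0.20, "50": 0.45, "100": 0.58},
    "beta_ionone":            {"1": 0.04, "10": 0.31, "50": 0.45, "100": 0.55},
    "geranyl_acetone":        {"1": 0.06, "10": 0.28, "50": 0.42, "100": 0.52},
    "theaspirane":            {"1": 0.02, "10": 0.10, "50": 0.25, "100": 0.30}
  }
}
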