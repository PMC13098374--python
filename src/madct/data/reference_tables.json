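{
  "description": "Published cohort summary statistics (demographics, per-phase annular geometry, volumetric and hemodynamic comparisons) stored verbatim as printed; p-values kept as strings.",
  "table1": {
    "n": 20,
    "age_years": {"mean": 10.38, "range": [6, 14]},
    "sex": {"male": 13, "female": 7},
    "body_weight_kg": {"mean": 9.84, "range": [4.3, 19.6]},
    "lviddn": {"mean": 1.84, "range": [1.7, 2.05]},
    "la_ao": {"mean": 1.83, "range": [1.61, 2.5]},
    "pimobendan_mg_kg_day": {"mean": 0.57, "range": [0.5, 0.64]}
  },
  "table2": {
    "units": {"MAA": "cm2/m2", "APD": "mm/kg^1/3", "ICD": "mm/kg^1/3", "TTD": "mm/kg^1/3", "SI": ""},
    "MAA": {
      "MD": {"pre": {"mean": 10.28, "sd": 1.39}, "post": {"mean": 10.09, "sd": 1.61}, "mean_difference": 0.19, "ci": [-0.26, 0.64], "p": ".4"},
      "LD": {"pre": {"mean": 10.45, "sd": 1.47}, "post": {"mean": 10.23, "sd": 1.78}, "mean_difference": 0.22, "ci": [-0.28, 0.72], "p": ".4"},
      "ED": {"pre": {"mean": 8.72, "sd": 1.43}, "post": {"mean": 8.39, "sd": 1.26}, "mean_difference": 0.33, "ci": [-0.02, 0.69], "p": ".06"},
      "MS": {"pre": {"mean": 9.69, "sd": 1.81}, "post": {"mean": 9.32, "sd": 1.97}, "mean_difference": 0.37, "ci": [-0.15, 0.88], "p": ".2"},
      "ES": {"pre": {"mean": 9.56, "sd": 2.08}, "post": {"mean": 8.19, "sd": 1.67}, "mean_difference": 1.38, "ci": [0.79, 1.97], "p": "<.001"}
    },
    "APD": {
      "MD": {"pre": {"mean": 10.68, "sd": 0.93}, "post": {"mean": 10.59, "sd": 1.23}, "mean_difference": 0.09, "ci": [-0.29, 0.46], "p": ".6"},
      "LD": {"pre": {"mean": 10.85, "sd": 0.99}, "post": {"mean": 10.69, "sd": 1.30}, "mean_difference": 0.17, "ci": [-0.24, 0.57], "p": ".4"},
      "ED": {"pre": {"mean": 9.75, "sd": 0.93}, "post": {"mean": 9.54, "sd": 0.99}, "mean_difference": 0.21, "ci": [-0.12, 0.55], "p": ".2"},
      "MS": {"pre": {"mean": 10.52, "sd": 1.39}, "post": {"mean": 10.56, "sd": 1.43}, "mean_difference": -0.04, "ci": [-0.45, 0.38], "p": ".9"},
      "ES": {"pre": {"mean": 10.96, "sd": 1.49}, "post": {"mean": 9.93, "sd": 1.30}, "mean_difference": 1.03, "ci": [0.54, 1.53], "p": "<.001"}
    },
    "ICD": {
      "MD": {"pre": {"mean": 12.10, "sd": 0.94}, "post": {"mean": 11.87, "sd": 0.94}, "mean_difference": 0.23, "ci": [-0.15, 0.6], "p": ".2"},
      "LD": {"pre": {"mean": 12.17, "sd": 0.87}, "post": {"mean": 12.00, "sd": 1.10}, "mean_difference": 0.16, "ci": [-0.17, 0.49], "p": ".3"},
      "ED": {"pre": {"mean": 11.18, "sd": 0.97}, "post": {"mean": 10.86, "sd": 0.99}, "mean_difference": 0.31, "ci": [-0.03, 0.65], "p": ".07"},
      "MS": {"pre": {"mean": 11.57, "sd": 0.96}, "post": {"mean": 11.29, "sd": 1.08}, "mean_difference": 0.28, "ci": [0.01, 0.56], "p": ".04"},
      "ES": {"pre": {"mean": 11.32, "sd": 1.19}, "post": {"mean": 10.57, "sd": 0.99}, "mean_difference": 0.75, "ci": [0.44, 1.06], "p": "<.001"}
    },
    "TTD": {
      "MD": {"pre": {"mean": 6.21, "sd": 0.58}, "post": {"mean": 6.40, "sd": 0.61}, "mean_difference": -0.19, "ci": [-0.41, 0.03], "p": ".09"},
      "LD": {"pre": {"mean": 6.36, "sd": 0.53}, "post": {"mean": 6.35, "sd": 0.65}, "mean_difference": 0.01, "ci": [-0.23, 0.25], "p": ".9"},
      "ED": {"pre": {"mean": 6.17, "sd": 0.56}, "post": {"mean": 6.19, "sd": 0.64}, "mean_difference": 0.02, "ci": [-0.20, 0.17], "p": ".9"},
      "MS": {"pre": {"mean": 6.28, "sd": 0.61}, "post": {"mean": 6.09, "sd": 0.67}, "mean_difference": 0.19, "ci": [-0.02, 0.4], "p": ".07"},
      "ES": {"pre": {"mean": 6.28, "sd": 0.78}, "post": {"mean": 6.02, "sd": 0.64}, "mean_difference": 0.27, "ci": [-0.002, 0.5], "p": ".05"}
    },
    "SI": {
      "MD": {"pre": {"mean": 0.88, "sd": 0.07}, "post": {"mean": 0.89, "sd": 0.09}, "mean_difference": -0.01, "ci": [-0.05, 0.03], "p": ".6"},
      "LD": {"pre": {"mean": 0.89, "sd": 0.07}, "post": {"mean": 0.89, "sd": 0.09}, "mean_difference": 0.002, "ci": [-0.03, 0.04], "p": ".9"},
      "ED": {"pre": {"mean": 0.87, "sd": 0.06}, "post": {"mean": 0.88, "sd": 0.08}, "mean_difference": -0.01, "ci": [-0.04, 0.03], "p": ".7"},
      "MS": {"pre": {"mean": 0.91, "sd": 0.07}, "post": {"mean": 0.94, "sd": 0.09}, "mean_difference": -0.03, "ci": [-0.06, 0.004], "p": ".08"},
      "ES": {"pre": {"mean": 0.97, "sd": 0.08}, "post": {"mean": 0.94, "sd": 0.09}, "mean_difference": 0.03, "ci": [-0.003, 0.06], "p": ".08"}
    }
  },
  "table3": {
    "LAI": {"unit": "", "pre": {"mean": 1.21, "sd": 0.10}, "post": {"mean": 1.26, "sd": 0.08}, "mean_difference": -0.06, "ci": [-0.09, -0.02], "p": ".002"},
    "LVEDV": {"unit": "mL/kg", "pre": {"mean": 4.21, "sd": 0.80}, "post": {"mean": 3.69, "sd": 0.86}, "mean_difference": 0.52, "ci": [0.22, 0.81], "p": ".002"},
    "LVESV": {"unit": "mL/kg", "pre": {"mean": 1.52, "sd": 0.35}, "post": {"mean": 1.24, "sd": 0.38}, "mean_difference": 0.28, "ci": [0.12, 0.44], "p": ".002"},
    "LVEF": {"unit": "%", "pre": {"mean": 64.01, "sd": 5.24}, "post": {"mean": 66.44, "sd": 6.92}, "mean_difference": -2.43, "ci": [-5.82, 0.96], "p": ".1"},
    "LVSV": {"unit": "mL/kg", "pre": {"mean": 2.7, "sd": 0.58}, "post": {"mean": 2.45, "sd": 0.61}, "mean_difference": 0.24, "ci": [0.01, 0.48], "p": ".04"},
    "RVol": {"unit": "mL/kg", "pre": {"mean": 1.04, "sd": 0.52}, "post": {"mean": 0.73, "sd": 0.50}, "mean_difference": 0.31, "ci": [0.12, 0.5], "p": ".003"},
    "RF": {"unit": "%", "pre": {"mean": 37.1, "sd": 11.04}, "post": {"mean": 27.35, "sd": 12.22}, "mean_difference": 9.75, "ci": [5.16, 14.34], "p": "<.001"},
    "LAESV": {"unit": "mL/kg", "pre": {"mean": 1.94, "sd": 0.69}, "post": {"median": 1.51, "iqr": [1.125, 1.833]}, "mean_difference": 0.37, "ci": [0.17, 0.57], "p": "<.001"},
    "LAEDV": {"unit": "mL/kg", "pre": {"mean": 0.96, "sd": 0.30}, "post": {"mean": 0.78, "sd": 0.24}, "mean_difference": 0.18, "ci": [0.08, 0.28], "p": ".001"},
    "Ea": {"unit": "mmHg/mL/kg", "pre": {"mean": 64.55, "sd": 18.94}, "post": {"mean": 60.81, "sd": 20.01}, "mean_difference": 3.74, "ci": [-4.7, 12.18], "p": ".4"},
    "ADI": {"unit": "mmHg^-1 x 10^3", "pre": {"median": 5.379, "iqr": [4.456, 6.616]}, "post": {"mean": 5.15, "sd": 1.48}, "mean_difference": "N/A", "ci": null, "p": ".6"},
    "MBP": {"unit": "mmHg", "pre": {"mean": 89.50, "sd": 22.76}, "post": {"mean": 93.25, "sd": 11.82}, "mean_difference": -3.75, "ci": [-15.27, 7.77], "p": ".5"}
  }
}
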