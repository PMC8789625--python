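{
  "schema_version": 1,
  "description": "Published WoMAB demographic adjustment equations and Equivalent-Score normative thresholds (Italian adult normative sample, N=168). Coefficients are stored exactly as printed; the cubic-age coefficients are printed rounded, so regenerated adjustment grids agree with the printed ones to within 0.01.",
  "centering_constants": {
    "ln100minusAge": 3.862482,
    "ageCubed": 166465.803571,
    "reciprocalEducation": 0.101788,
    "rawAge": 48.41071,
    "lnAge": 3.791483,
    "reciprocalAge": 0.024893
  },
  "equations": {
    "DOT_T":   {"terms": [["ln100minusAge", -1.590625], ["reciprocalEducation", 16.07802]], "sex_offset": 0.0},
    "DOT_WM":  {"terms": [["ageCubed", 0.000002], ["reciprocalEducation", 8.9739]], "sex_offset": 0.0},
    "ICT_T":   {"terms": [["ln100minusAge", -2.087459], ["reciprocalEducation", 15.88892]], "sex_offset": 0.0},
    "ICT_WM":  {"terms": [["ageCubed", 0.000003], ["reciprocalEducation", 8.691697]], "sex_offset": 0.0},
    "FDS_T":   {"terms": [["ln100minusAge", -2.082331], ["reciprocalEducation", 12.71517]], "sex_offset": 0.0},
    "FDS_S":   {"terms": [["ageCubed", 0.000003], ["reciprocalEducation", 6.09889]], "sex_offset": 0.0},
    "BDS_T":   {"terms": [["rawAge", 0.065689], ["reciprocalEducation", 10.95221]], "sex_offset": 0.587136},
    "BDS_WM":  {"terms": [["rawAge", 0.035249], ["reciprocalEducation", 5.473036]], "sex_offset": 0.278456},
    "DSR_T":   {"terms": [["lnAge", 0.156681]], "sex_offset": 0.037286},
    "DSR_WMS": {"terms": [["reciprocalAge", -4.081518]], "sex_offset": 0.0}
  },
  "norm_table": {
    "DOT_T":   {"oTL": 3.27,  "iTL": 4.72,  "es_upper_bounds": [3.27, 4.72, 5.76, 7.35]},
    "DOT_WM":  {"oTL": 4.05,  "iTL": 4.5,   "es_upper_bounds": [4.05, 4.57, 5.42, 6.31]},
    "ICT_T":   {"oTL": 2.48,  "iTL": 3.7,   "es_upper_bounds": [2.48, 4.14, 5.7, 7.03]},
    "ICT_WM":  {"oTL": 3.69,  "iTL": 4.17,  "es_upper_bounds": [3.69, 4.22, 5.19, 6.19]},
    "FDS_T":   {"oTL": 6.42,  "iTL": 7.35,  "es_upper_bounds": [6.42, 7.4, 8.49, 9.88]},
    "FDS_S":   {"oTL": 4.45,  "iTL": 5.17,  "es_upper_bounds": [4.45, 5.22, 5.58, 6.31]},
    "BDS_T":   {"oTL": 3.35,  "iTL": 4.26,  "es_upper_bounds": [3.35, 4.38, 5.67, 7.16]},
    "BDS_WM":  {"oTL": 2.77,  "iTL": 3.41,  "es_upper_bounds": [2.77, 3.45, 4.26, 4.88]},
    "DSR_T":   {"oTL": 0.393, "iTL": 0.486, "es_upper_bounds": [0.393, 0.502, 0.638, 0.735]},
    "DSR_WMS": {"oTL": 0.461, "iTL": 0.541, "es_upper_bounds": [0.461, 0.55, 0.659, 0.786]},
    "AES_T":   {"oTL": 1.4,   "iTL": 2.2,   "es_upper_bounds": null},
    "AES_WMS": {"oTL": 1.2,   "iTL": 2.2,   "es_upper_bounds": null}
  },
  "grid_lattice": {
    "ages": [35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85],
    "educations": [5, 8, 11, 13, 16, 18]
  }
}
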