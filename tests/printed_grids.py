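"""Hand-transcribed published adjustment grids (age 35..85 step 5 columns).

Values are the adjustment factors as printed in the normative tables, keyed
by grid (outcome, sex where applicable) and education row ("adjustment" for
the ratio outcomes, which do not use education).  ``None`` marks cells that
are unreadable in the source text extraction; they are excluded from the
fidelity check.  Regenerated grids must agree with every transcribed cell
within +-0.01 (the print rounds some coefficients).
"""

AGES = (35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85)

PRINTED_GRIDS = {
    "DOT_T": {
        5:  [1.08, 1.21, 1.35, 1.5, 1.67, 1.86, 2.07, 2.31, 2.6, 2.96, 3.42],
        8:  [-0.13, None, 0.14, 0.29, 0.46, 0.65, 0.86, 1.11, 1.4, 1.75, 2.21],
        11: [-0.67, -0.54, -0.41, -0.25, -0.09, 0.1, 0.31, 0.56, 0.85, 1.2, 1.66],
        13: [-0.9, -0.77, -0.63, -0.48, -0.31, -0.12, 0.09, 0.33, 0.62, 0.98, 1.44],
        16: [-1.13, -1.0, -0.86, -0.71, -0.54, -0.36, -0.14, 0.1, 0.39, 0.75, 1.2],
        18: [-1.24, -1.11, -0.97, -0.82, -0.65, -0.47, -0.25, -0.01, 0.28, 0.64, 1.09],
    },
    "DOT_WM": {
        5:  [0.63, 0.68, 0.73, 0.8, 0.88, 0.98, 1.1, 1.23, 1.39, 1.57, 1.78],
        8:  [-0.04, None, 0.06, 0.13, 0.21, 0.31, 0.42, 0.56, 0.72, 0.9, 1.1],
        11: [-0.34, -0.3, -0.25, -0.18, -0.1, None, 0.12, 0.26, 0.41, 0.59, 0.8],
        13: [-0.47, -0.43, -0.37, -0.31, -0.22, -0.12, -0.01, 0.13, 0.29, 0.47, 0.67],
        16: [-0.6, -0.56, -0.5, -0.44, -0.35, -0.25, -0.14, None, 0.16, 0.34, 0.54],
        18: [-0.66, -0.62, -0.57, -0.5, -0.42, -0.32, -0.2, None, 0.1, 0.28, 0.48],
    },
    "ICT_T": {
        5:  [0.91, 1.08, 1.26, 1.46, 1.68, 1.92, 2.2, 2.52, 2.9, 3.37, 3.97],
        8:  [-0.28, -0.12, 0.07, 0.27, 0.49, 0.73, 1.01, 1.33, 1.71, 2.18, 2.78],
        11: [-0.82, -0.66, -0.48, -0.28, -0.06, 0.19, 0.47, 0.79, 1.17, 1.64, 2.24],
        13: [-1.05, -0.88, -0.7, -0.5, -0.28, -0.03, 0.25, 0.57, 0.95, 1.41, 2.01],
        16: [-1.28, -1.11, -0.93, -0.73, -0.51, -0.26, 0.02, 0.34, 0.72, 1.19, 1.79],
        18: [-1.39, -1.22, -1.04, -0.84, -0.62, -0.37, -0.09, 0.23, 0.61, 1.07, 1.68],
    },
    "ICT_WM": {
        5:  [0.48, 0.55, 0.63, 0.73, 0.85, 1.0, 1.18, 1.38, 1.62, 1.89, 2.2],
        8:  [-0.17, -0.11, -0.02, 0.08, 0.2, 0.35, 0.53, 0.73, 0.97, 1.24, 1.54],
        11: [-0.47, -0.4, -0.32, -0.22, -0.09, 0.05, 0.23, 0.44, 0.67, 0.94, 1.25],
        13: [-0.59, -0.52, -0.44, -0.34, -0.22, -0.07, 0.11, 0.31, 0.55, 0.82, 1.13],
        16: [-0.71, -0.65, -0.57, -0.47, -0.34, -0.19, -0.02, 0.19, 0.42, 0.7, 1.0],
        18: [-0.77, -0.71, -0.63, -0.53, -0.4, -0.25, -0.08, 0.13, 0.36, 0.63, 0.94],
    },
    "FDS_T": {
        5:  [0.6, 0.77, 0.95, 1.15, 1.37, 1.61, 1.89, 2.21, 2.59, 3.05, 3.65],
        8:  [-0.35, -0.19, -0.01, 0.19, 0.41, 0.66, 0.93, 1.26, 1.64, 2.1, 2.7],
        11: [-0.79, -0.62, -0.44, -0.24, -0.02, 0.22, 0.5, 0.82, 1.2, 1.67, 2.27],
        13: [-0.97, -0.8, -0.62, -0.42, -0.2, 0.05, 0.32, 0.64, 1.02, 1.49, 2.09],
        16: [-1.15, -0.98, -0.8, -0.6, -0.38, -0.14, 0.14, 0.46, 0.84, 1.31, 1.9],
        18: [-1.24, -1.07, -0.89, -0.69, -0.47, -0.23, 0.05, 0.37, 0.75, 1.22, None],
    },
    "FDS_S": {
        5:  [0.23, 0.29, 0.37, 0.47, 0.6, 0.75, 0.92, 1.13, 1.37, 1.64, 1.94],
        8:  [-0.23, -0.17, -0.08, 0.02, 0.14, 0.29, 0.47, 0.67, 0.91, 1.18, 1.48],
        11: [-0.44, -0.37, -0.29, -0.19, -0.07, 0.08, 0.26, 0.46, 0.7, 0.97, 1.28],
        13: [-0.52, -0.46, -0.38, -0.28, -0.15, None, 0.17, 0.38, 0.61, 0.88, 1.19],
        16: [-0.61, -0.55, -0.47, -0.36, -0.24, -0.09, 0.08, 0.29, 0.53, 0.8, 1.1],
        18: [-0.65, -0.59, -0.51, -0.41, -0.28, -0.13, 0.04, 0.25, 0.48, 0.75, 1.06],
    },
    "BDS_T_M": {
        5:  [-0.39, -0.06, 0.26, 0.59, 0.92, 1.25, 1.58, 1.91, 2.24, 2.56, 2.89],
        8:  [-1.21, -0.89, -0.56, -0.23, 0.1, 0.43, 0.76, 1.09, 1.41, 1.74, 2.07],
        11: [-1.59, -1.26, -0.93, -0.6, -0.27, 0.06, 0.38, 0.71, 1.04, 1.37, 1.7],
        13: [-1.74, -1.41, -1.08, -0.76, -0.43, -0.1, 0.23, 0.56, 0.89, 1.22, 1.54],
        16: [-1.9, -1.57, -1.24, -0.91, -0.58, -0.26, 0.07, 0.4, 0.73, 1.06, 1.39],
        18: [-1.97, -1.65, -1.32, -0.99, -0.66, -0.33, None, 0.32, 0.65, 0.98, 1.31],
    },
    "BDS_T_F": {
        5:  [0.78, 1.11, 1.44, 1.77, 2.1, 2.42, 2.75, 3.08, 3.41, 3.74, 4.07],
        8:  [-0.04, 0.29, 0.62, 0.95, 1.27, 1.6, 1.93, 2.26, 2.59, 2.92, 3.24],
        11: [-0.41, -0.08, 0.24, 0.57, 0.9, 1.23, 1.56, 1.89, 2.21, 2.54, 2.87],
        13: [-0.57, -0.24, 0.09, 0.42, 0.75, 1.08, 1.4, 1.73, 2.06, 2.39, 2.72],
        16: [-0.72, -0.4, -0.07, 0.26, 0.59, 0.92, 1.25, 1.58, 1.9, 2.23, 2.56],
        18: [-0.8, -0.47, -0.14, 0.19, 0.51, 0.84, 1.17, 1.5, 1.83, 2.16, 2.48],
    },
    "BDS_WM_M": {
        5:  [-0.21, -0.04, 0.14, 0.32, 0.49, 0.67, 0.84, 1.02, 1.2, 1.37, 1.55],
        8:  [-0.62, -0.45, -0.27, -0.1, 0.08, 0.26, 0.43, 0.61, 0.79, 0.96, 1.14],
        11: [-0.81, -0.63, -0.46, -0.28, -0.11, 0.07, 0.25, 0.42, 0.6, 0.78, 0.95],
        13: [-0.89, -0.71, -0.53, -0.36, -0.18, -0.01, 0.17, 0.35, 0.52, 0.7, 0.88],
        16: [-0.97, -0.79, -0.61, -0.44, -0.26, -0.08, 0.09, 0.27, 0.44, 0.62, 0.8],
        18: [-1.0, -0.83, -0.65, -0.48, -0.3, -0.12, 0.05, 0.23, 0.41, 0.58, 0.76],
    },
    "BDS_WM_F": {
        5:  [0.34, 0.52, 0.7, 0.87, 1.05, 1.22, 1.4, 1.58, 1.75, 1.93, 2.11],
        8:  [-0.07, 0.11, 0.29, 0.46, 0.64, 0.81, 0.99, 1.17, 1.34, 1.52, 1.7],
        11: [-0.25, -0.08, 0.1, 0.27, 0.45, 0.63, 0.8, 0.98, 1.16, 1.33, 1.51],
        13: [-0.33, -0.15, 0.02, 0.2, 0.37, 0.55, 0.73, 0.9, 1.08, 1.26, 1.43],
        16: [-0.41, -0.23, -0.06, 0.12, 0.3, 0.47, 0.65, 0.82, 1.0, 1.18, 1.35],
        18: [-0.45, -0.27, -0.09, 0.08, 0.26, 0.43, 0.61, 0.79, 0.96, 1.14, 1.32],
    },
    "DSR_T_M": {
        "adjustment": [-0.074, -0.053, -0.035, -0.018, -0.003, 0.01, 0.023,
                       0.034, 0.045, 0.055, 0.065],
    },
    "DSR_T_F": {
        "adjustment": [None, 0.021, 0.04, 0.056, 0.071, 0.085, 0.097,
                       0.109, 0.12, 0.13, 0.139],
    },
    "DSR_WMS": {
        "adjustment": [-0.015, None, 0.011, 0.02, 0.027, 0.034, 0.039,
                       0.043, 0.047, 0.051, 0.054],
    },
}
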