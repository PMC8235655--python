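"""Reference values from the ketoprofen–PLA supercritical impregnation study.

These constants summarize the experimental system this package models: a 3²
pressure × temperature factorial of supercritical-CO₂ impregnation of
ketoprofen into PLA filaments, and the in-vitro release kinetics of four of
the impregnated samples. They serve as anchors for the synthetic-data
generators and as inputs to cross-checks (e.g. completing reported ANOVA
sum-of-squares decompositions to F/p/R²).
"""

from __future__ import annotations

PRESSURE_LEVELS = (100.0, 250.0, 400.0)  # bar
TEMPERATURE_LEVELS = (35.0, 55.0, 75.0)  # °C

NOMINAL_FILAMENT_DIAMETER_MM = 1.75
KETOPROFEN_PBS_SOLUBILITY_MG_PER_ML = 2.2
RELEASE_MEDIUM_VOLUME_ML = 10.0

#: Reported ANOVA decompositions of the four factorial responses.
#: Each entry carries the single-df term sums of squares of the quadratic
#: response-surface model on coded factors (A = pressure, B = temperature),
#: the residual (error) SS/df, and the reported F, p and R² for cross-checks.
REFERENCE_ANOVA: dict[str, dict] = {
    "swelling_scco2": {
        "terms": {
            "A_pressure": {"ss": 144.354, "df": 1, "f": 18.90, "p": 0.0225},
            "B_temperature": {"ss": 138.913, "df": 1, "f": 18.19, "p": 0.0236},
            "AA": {"ss": 15.9989, "df": 1, "f": 2.10, "p": 0.2436},
            "AB": {"ss": 107.33, "df": 1, "f": 14.06, "p": 0.0331},
            "BB": {"ss": 15.9989, "df": 1, "f": 2.10, "p": 0.2436},
        },
        "error_ss": 22.9088,
        "error_df": 3,
        "total_ss": 445.503,
        "r_squared_pct": 94.8578,
    },
    "swelling_impregnated": {
        "terms": {
            "A_pressure": {"ss": 165.585, "df": 1, "f": 51.53, "p": 0.0056},
            "B_temperature": {"ss": 297.229, "df": 1, "f": 92.50, "p": 0.0024},
            "AA": {"ss": 0.00269, "df": 1, "f": 0.00, "p": 0.9787},
            "AB": {"ss": 115.348, "df": 1, "f": 35.90, "p": 0.0093},
            "BB": {"ss": 31.0209, "df": 1, "f": 9.65, "p": 0.0530},
        },
        "error_ss": 9.63964,
        "error_df": 3,
        "total_ss": 618.825,
        "r_squared_pct": 98.4423,
    },
    "loading": {
        "terms": {
            "A_pressure": {"ss": 18.9038, "df": 1, "f": 5.36, "p": 0.1034},
            "B_temperature": {"ss": 54.5414, "df": 1, "f": 15.48, "p": 0.0292},
            "AA": {"ss": 3.65401, "df": 1, "f": 1.04, "p": 0.3835},
            "AB": {"ss": 19.404, "df": 1, "f": 5.51, "p": 0.1006},
            "BB": {"ss": 9.31681, "df": 1, "f": 2.64, "p": 0.2024},
        },
        "error_ss": 10.5708,
        "error_df": 3,
        "total_ss": 116.391,
        "r_squared_pct": 90.9179,
    },
    "superficial": {
        "terms": {
            "A_pressure": {"ss": 19.9838, "df": 1, "f": 2.30, "p": 0.2266},
            "B_temperature": {"ss": 171.521, "df": 1, "f": 19.74, "p": 0.0212},
            "AA": {"ss": 0.166272, "df": 1, "f": 0.02, "p": 0.8987},
            "AB": {"ss": 3.59102, "df": 1, "f": 0.41, "p": 0.5660},
            "BB": {"ss": 6.82036, "df": 1, "f": 0.79, "p": 0.4409},
        },
        "error_ss": 26.0642,
        "error_df": 3,
        "total_ss": 228.147,
        "r_squared_pct": 88.5757,
    },
}

#: Reported monophasic model fits per impregnation condition.
#: Keys are "<temperature>C_<pressure>bar"; values map model -> parameters + R².
MONOPHASIC_REFERENCE: dict[str, dict] = {
    "55C_400bar": {
        "zero_order": {"r2": 0.8780, "k0": 0.0459},
        "first_order": {"r2": 0.8162, "k1": 0.0735},
        "higuchi": {"r2": 0.9747, "kH": 0.2207},
        "korsmeyer_peppas": {"r2": 0.9625, "kKP": 0.3786, "n": 0.3224},
        "peppas_sahlin": {"r2": 0.5533, "kd": 0.4571, "kr": -0.0587},
    },
    "75C_250bar": {
        "zero_order": {"r2": 0.9936, "k0": 0.0287},
        "first_order": {"r2": 0.8484, "k1": 0.1022},
        "higuchi": {"r2": 0.9002, "kH": 0.1640},
        "korsmeyer_peppas": {"r2": 0.9757, "kKP": 0.0591, "n": 0.6219},
        "peppas_sahlin": {"r2": 0.8818, "kd": 0.0123, "kr": 0.0337},
    },
    "75C_200bar": {
        "zero_order": {"r2": 0.9824, "k0": 0.0282},
        "first_order": {"r2": 0.8668, "k1": 0.0919},
        "higuchi": {"r2": 0.8781, "kH": 0.1610},
        "korsmeyer_peppas": {"r2": 0.9737, "kKP": 0.0737, "n": 0.5367},
        "peppas_sahlin": {"r2": 0.7674, "kd": 0.0317, "kr": 0.0282},
    },
    "55C_250bar": {
        "zero_order": {"r2": 0.9452, "k0": 0.0149},
        "first_order": {"r2": 0.9536, "k1": 0.0551},
        "higuchi": {"r2": 0.7775, "kH": 0.1089},
        "korsmeyer_peppas": {"r2": 0.8012, "kKP": 0.0449, "n": 0.5571},
        "peppas_sahlin": {"r2": 0.4846, "kd": 0.0158, "kr": 0.0147},
    },
}

#: Reported multiphasic (piecewise power-law) fits per impregnation condition:
#: ordered segments of (k, n, t_end days, q_end fraction, R²).
MULTIPHASIC_REFERENCE: dict[str, list[dict]] = {
    "55C_400bar": [
        {"k": 0.3590, "n": 0.2348, "t_end": 5.0, "q_end": 0.55, "r2": 0.9970},
        {"k": 0.1682, "n": 0.7328, "t_end": 14.0, "q_end": 0.97, "r2": 0.9991},
        {"k": 0.7807, "n": 0.0829, "t_end": 20.0, "q_end": 1.00, "r2": 0.9917},
    ],
    "75C_250bar": [
        {"k": 0.0526, "n": 0.4491, "t_end": 5.0, "q_end": 0.11, "r2": 0.9949},
        {"k": 0.0231, "n": 1.0659, "t_end": 34.0, "q_end": 1.00, "r2": 0.9943},
    ],
    "75C_200bar": [
        {"k": 0.0696, "n": 0.4424, "t_end": 5.0, "q_end": 0.14, "r2": 0.9933},
        {"k": 0.0214, "n": 1.0856, "t_end": 35.0, "q_end": 1.00, "r2": 0.9904},
    ],
    "55C_250bar": [
        {"k": 0.0503, "n": 0.2501, "t_end": 12.0, "q_end": 0.09, "r2": 0.9885},
        {"k": 0.0016, "n": 1.5587, "t_end": 63.0, "q_end": 1.00, "r2": 0.9938},
    ],
}

#: Cell-mean anchor tables for the three impregnation responses, used to derive
#: the synthetic factorial generators. Rows are pressure levels (100/250/400
#: bar), columns temperature levels (35/55/75 °C). The values interpolate the
#: point values and trends reported for the study: drug loading rising with
#: both factors (max ≈ 9% at 250 bar/75 °C, predicted 8.48% at 200 bar/75 °C,
#: < 0.1% at 100 bar/35 °C); permanent swelling ≈ 11% at 400 bar/55 °C, ≈ 9%
#: at 75 °C/200–250 bar, ≈ 7% at 250 bar/55 °C, foaming at 400 bar/75 °C, and
#: a dip from 35 to 55 °C at 100 bar; superficial drug fraction decreasing
#: strongly with temperature (1.45% predicted at 200 bar/75 °C) and highest at
#: 400 bar among the 55 °C samples.
FACTORIAL_ANCHORS: dict[str, list[list[float]]] = {
    "loading": [
        [0.1, 1.0, 4.5],
        [0.5, 4.5, 9.0],
        [1.0, 6.0, 9.4],
    ],
    "swelling": [
        [2.0, 1.0, 4.0],
        [3.0, 7.0, 9.3],
        [6.0, 11.0, 20.0],
    ],
    "superficial": [
        [14.0, 8.0, 2.2],
        [12.0, 5.0, 1.3],
        [13.0, 8.0, 1.0],
    ],
}

#: Replicate standard deviations reported for the optimum-condition responses,
#: used as the measurement-noise scale of the factorial generators.
FACTORIAL_NOISE_SD: dict[str, float] = {
    "loading": 0.39,
    "swelling": 0.38,
    "superficial": 0.15,
}
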