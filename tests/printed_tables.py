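"""Frozen expected values: the study's printed result tables.

These are the published renderings (4-5 decimals) that the pipeline must
reproduce from the raw inputs; tests compare recomputed values against
them at the stated tolerances.
"""

import numpy as np

# Normalized values, runs 1-18 x responses Y1-Y5.
NORMALIZED = np.array([
    [1.0000, 0.8806, 0.9429, 0.7500, 0.5636],
    [0.9727, 0.9104, 0.4571, 0.8500, 0.3455],
    [0.3812, 0.0000, 0.0000, 0.6000, 0.8182],
    [0.7361, 0.9403, 0.4857, 0.5500, 0.8545],
    [0.3650, 0.9254, 0.4857, 0.5500, 0.7273],
    [0.3003, 0.8507, 0.3143, 0.4500, 0.5091],
    [0.9626, 0.8060, 1.0000, 0.8000, 1.0000],
    [0.9717, 0.7910, 0.7714, 0.9500, 0.8364],
    [0.4712, 0.9552, 0.8571, 0.5000, 0.8000],
    [0.9141, 0.2985, 0.2286, 1.0000, 0.0000],
    [0.6552, 0.3881, 0.2857, 0.8000, 0.3818],
    [0.3428, 0.4478, 0.2857, 0.5500, 0.2000],
    [0.8756, 0.7910, 1.0000, 0.8500, 0.6182],
    [0.5703, 0.6716, 0.4571, 0.6500, 0.5091],
    [0.0000, 0.4030, 0.2286, 0.0000, 0.8000],
    [0.8675, 0.7910, 0.4857, 0.6000, 0.7818],
    [0.8018, 1.0000, 0.5143, 0.5000, 0.7636],
    [0.2781, 0.5224, 0.2000, 0.4000, 0.9636],
])

DEVIATIONS = np.round(1.0 - NORMALIZED, 4)  # the published deviations are exactly 1 - X

# Grey relational coefficients, runs 1-18 x responses Y1-Y5.
GRC = np.array([
    [1.0000, 0.8072, 0.8974, 0.6667, 0.5340],
    [0.9482, 0.8481, 0.4795, 0.7692, 0.4331],
    [0.4469, 0.3333, 0.3333, 0.5556, 0.7333],
    [0.6545, 0.8933, 0.4930, 0.5263, 0.7746],
    [0.4405, 0.8701, 0.4930, 0.5263, 0.6471],
    [0.4168, 0.7701, 0.4217, 0.4762, 0.5046],
    [0.9304, 0.7204, 1.0000, 0.7143, 1.0000],
    [0.9464, 0.7053, 0.6863, 0.9091, 0.7534],
    [0.4860, 0.9178, 0.7778, 0.5000, 0.7143],
    [0.8533, 0.4161, 0.3933, 1.0000, 0.3333],
    [0.5919, 0.4497, 0.4118, 0.7143, 0.4472],
    [0.4321, 0.4752, 0.4118, 0.5263, 0.3846],
    [0.8008, 0.7053, 1.0000, 0.7692, 0.5670],
    [0.5378, 0.6036, 0.4795, 0.5882, 0.5046],
    [0.3333, 0.4558, 0.3933, 0.3333, 0.7143],
    [0.7906, 0.7053, 0.4930, 0.5556, 0.6962],
    [0.7161, 1.0000, 0.5072, 0.5000, 0.6790],
    [0.4092, 0.5115, 0.3846, 0.4545, 0.9322],
])

GRG = np.array([
    0.7811, 0.6956, 0.4805, 0.6684, 0.5954, 0.5179, 0.8730, 0.8001, 0.6792,
    0.5992, 0.5229, 0.4460, 0.7685, 0.5427, 0.4460, 0.6481, 0.6805, 0.5384,
])

GRG_SNR = np.array([
    -2.14629, -3.15261, -6.36628, -3.49982, -4.50383, -5.71558, -1.17951,
    -1.93719, -3.36039, -4.44838, -5.63086, -7.01354, -2.28754, -5.30826,
    -7.01333, -3.76703, -3.34368, -5.37790,
])

GRG_RANK = np.array([3, 5, 16, 8, 11, 15, 1, 2, 7, 10, 14, 18, 4, 12, 17, 9, 6, 13])

# ANOVA of the EF S/N ratios: factor -> (df, SS, MS, F, p).
ANOVA_EF_SNR = {
    "A": (2, 3.3618, 1.68088, 7.72, 0.017),
    "B": (2, 15.7743, 7.88714, 36.24, 0.000),
    "C": (2, 0.1697, 0.08483, 0.39, 0.691),
    "D": (2, 0.0064, 0.00318, 0.01, 0.986),
    "E": (2, 1.4295, 0.71477, 3.28, 0.099),
}
ANOVA_EF_ERROR_SS = 1.5234
ANOVA_EF_TOTAL_SS = 22.2650

# ANOVA of the GRG S/N ratios.
ANOVA_GRG_SNR = {
    "A": (2, 10.2073, 5.1037, 3.01, 0.114),
    "B": (2, 26.1180, 13.0590, 7.71, 0.017),
    "C": (2, 1.3837, 0.6918, 0.41, 0.680),
    "D": (2, 0.3583, 0.1791, 0.11, 0.901),
    "E": (2, 3.0274, 1.5137, 0.89, 0.451),
}
ANOVA_GRG_ERROR_SS = 11.8635
ANOVA_GRG_TOTAL_SS = 52.9581

EF_OPTIMUM = (3, 1, 3, 3, 1)
GRG_OPTIMUM = (3, 1, 2, 3, 1)
VALIDATION_GRG = 0.8956
BEST_RUN_GRG = 0.8730
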