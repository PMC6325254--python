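"""Published meta-analytic estimates used for the side-by-side repro report.

These are the printed values from the meta-analysis that the bundled effect
table reproduces.  They are used only for display in the ``repro`` report
(computed vs published, with absolute differences); nothing in the fitting
code reads them.
"""

PUBLISHED = {
    "intercept": {
        "coefficients": {"intercept": -0.167},
        "coef_se": {"intercept": 0.164},
        "I2": 84.7,
        "aic": 28.6,
        "QM": 1.03,
        "egger_z": -1.80,
    },
    "group": {
        "coefficients": {
            "intercept": -0.138,
            "group[addiction]": -0.616,
            "group[other_psychopathology]": 0.793,
        },
        "coef_se": {
            "intercept": 0.110,
            "group[addiction]": 0.202,
            "group[other_psychopathology]": 0.199,
        },
        "I2": 31.8,
        "aic": 14.3,
        "QM": 35.7,
        "egger_z": -2.24,
        "r_by_group": {
            "healthy": (-0.137, -0.339, 0.076),
            "addiction": (-0.638, -0.796, -0.399),
            "other_psychopathology": (0.575, 0.319, 0.753),
        },
    },
    "tracer": {"I2": 83.9, "aic": 28.4, "QM": 2.59},
    "group_x_tracer": {"I2": 37.15, "aic": 19.8, "QM": 35.2, "egger_z": -1.56},
}
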